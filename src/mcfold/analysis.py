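"""Folding-landscape analyses on the fraction-of-native-contacts coordinate.

The reaction coordinate Q counts which residue-pair contacts of a designated
reference ("native") structure are formed in a given conformation. Everything
else here is built on top of it: the potential of mean force
F(Q) = -k_B T ln P(Q), minima and barrier heights, the folding temperature
(equal-depth interpolation), ensemble assignment over Q intervals, contact
frequency and difference maps, per-residue nativeness q_i, Boltzmann-weighted
φ-values, the energy-fluctuation heat capacity, Kabsch RMSD, and minimum
hydrogen-bond distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, InputError

__all__ = [
    "NativeContactSet",
    "EnsembleDefinition",
    "define_native_contacts",
    "compute_q",
    "per_residue_nativeness",
    "pmf",
    "locate_minima_and_barriers",
    "folding_temperature",
    "calibrate_temperature",
    "assign_ensembles",
    "contact_frequency_map",
    "difference_map",
    "phi_values",
    "heat_capacity",
    "kabsch_rmsd",
    "hbond_distance",
]

DEFAULT_KB = 1.9872041e-3  # kcal/mol/K


# ---------------------------------------------------------------------------
# Native contacts and Q
# ---------------------------------------------------------------------------


@dataclass
class NativeContactSet:
    """Reference residue-pair contacts driving Q and the landscape analyses.

    ``pairs[k] = (i, j)`` are positional residue indices (0-based along the
    chain); ``native_dists[k]`` is the native minimum heavy-atom distance (Å).
    ``residue_heavy`` maps each positional residue index to its heavy-atom
    indices, and ``residue_labels`` keeps the file's 1-based numbering for
    reports.
    """

    reference_id: str
    pairs: list
    native_dists: np.ndarray
    cutoff: float
    min_separation: int
    lam: float
    residue_heavy: list
    residue_labels: list = field(default_factory=list)

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _residue_heavy_atoms(system) -> tuple[list, list]:
    """Heavy-atom index lists per residue, in chain order."""
    reskeys = system.residue_keys()
    resmap = system.residue_atom_indices()
    heavy, labels = [], []
    for key in reskeys:
        idx = [a for a in resmap[key] if system.elements[a] != "H"]
        heavy.append(np.array(idx, dtype=int))
        labels.append(key[1])
    return heavy, labels


def define_native_contacts(
    system,
    coords=None,
    cutoff: float = 4.5,
    min_separation: int = 3,
    lam: float = 1.2,
    reference_id: str = "reference",
) -> NativeContactSet:
    """Residue pairs (|i-j| ≥ min_separation) whose minimum heavy-atom
    distance in the reference coordinates is below ``cutoff`` (Å).

    The native distance of each pair is stored; at analysis time a contact
    counts as formed when the current distance is below λ × native distance.
    """
    if coords is None:
        coords = system.coords
    heavy, labels = _residue_heavy_atoms(system)
    if not heavy or all(len(h) == 0 for h in heavy):
        raise InputError("reference structure has no heavy atoms")
    pairs, dists = [], []
    nres = len(heavy)
    for i in range(nres):
        if len(heavy[i]) == 0:
            continue
        for j in range(i + min_separation, nres):
            if len(heavy[j]) == 0:
                continue
            dmin = cdist(coords[heavy[i]], coords[heavy[j]]).min()
            if dmin < cutoff:
                pairs.append((i, j))
                dists.append(dmin)
    return NativeContactSet(
        reference_id=reference_id,
        pairs=pairs,
        native_dists=np.asarray(dists, dtype=float),
        cutoff=cutoff,
        min_separation=min_separation,
        lam=lam,
        residue_heavy=heavy,
        residue_labels=labels,
    )


def _pair_distances(coords, contacts: NativeContactSet) -> np.ndarray:
    out = np.empty(len(contacts))
    for k, (i, j) in enumerate(contacts.pairs):
        out[k] = cdist(
            coords[contacts.residue_heavy[i]], coords[contacts.residue_heavy[j]]
        ).min()
    return out


def compute_q(coords, contacts: NativeContactSet) -> float:
    """Fraction of native contacts formed: pair (i, j) counts as formed iff
    its current minimum heavy-atom distance < λ × native distance."""
    if len(contacts) == 0:
        raise InputError("empty native contact set: Q is undefined")
    d = _pair_distances(coords, contacts)
    return float(np.count_nonzero(d < contacts.lam * contacts.native_dists) / len(contacts))


def per_residue_nativeness(coords, contacts: NativeContactSet) -> np.ndarray:
    """q_i = fraction of residue i's native contacts currently formed.

    Residues without native contacts get NaN (flagged undefined) — these are
    the blank rows in per-residue stability maps.
    """
    if len(contacts) == 0:
        raise InputError("empty native contact set")
    d = _pair_distances(coords, contacts)
    formed = d < contacts.lam * contacts.native_dists
    nres = len(contacts.residue_heavy)
    count = np.zeros(nres)
    total = np.zeros(nres)
    for k, (i, j) in enumerate(contacts.pairs):
        total[i] += 1
        total[j] += 1
        if formed[k]:
            count[i] += 1
            count[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        q = count / total
    q[total == 0] = np.nan
    return q


# ---------------------------------------------------------------------------
# PMF, minima, barriers, folding temperature
# ---------------------------------------------------------------------------


def pmf(q_samples, T: float, n_bins: int = 50, k_B: float = DEFAULT_KB):
    """Potential of mean force F(Q) = -k_B T ln P(Q) over [0, 1].

    Returns (bin_centers, F) with F shifted so the minimum is 0 and empty
    bins masked as NaN (never treated as minima).
    """
    q = np.asarray(q_samples, dtype=float)
    if q.size == 0:
        raise InputError("no Q samples")
    if np.any((q < 0) | (q > 1)):
        raise InputError("Q samples outside [0, 1]")
    counts, edges = np.histogram(q, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) <= 1:
        warnings.warn("all Q samples fall in a single bin; PMF is degenerate")
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        F = np.where(counts > 0, -k_B * T * np.log(np.where(counts > 0, p, 1.0)), np.nan)
    F = F - np.nanmin(F)
    return centers, F


@dataclass
class BarrierReport:
    """Barrier between two adjacent minima, measured from each side."""

    left_min_pos: float
    right_min_pos: float
    peak_pos: float
    dG_from_left: float
    dG_from_right: float


def locate_minima_and_barriers(F, centers=None):
    """Local minima of a binned profile and the barriers between them.

    Masked (NaN) bins are dropped before scanning. A bin is a minimum when it
    is strictly lower than both neighbors (endpoints compare against their one
    neighbor). Each adjacent minima pair reports the intervening maximum as a
    barrier measured from each minimum (the ΔG_{N,I} / ΔG_{I,N} convention).
    Returns (minima_positions, list_of_BarrierReport).
    """
    F = np.asarray(F, dtype=float)
    if centers is None:
        centers = np.arange(len(F), dtype=float)
    centers = np.asarray(centers, dtype=float)
    ok = np.isfinite(F)
    if np.count_nonzero(ok) < 3:
        raise InputError("profile needs at least 3 unmasked bins")
    f = F[ok]
    x = centers[ok]
    n = len(f)
    minima = []
    for k in range(n):
        lo = f[k] < f[k - 1] if k > 0 else True
        hi = f[k] < f[k + 1] if k < n - 1 else True
        if lo and hi:
            minima.append(k)
    barriers = []
    for a, b in zip(minima[:-1], minima[1:]):
        seg = f[a : b + 1]
        p = int(np.argmax(seg)) + a
        barriers.append(
            BarrierReport(
                left_min_pos=float(x[a]),
                right_min_pos=float(x[b]),
                peak_pos=float(x[p]),
                dG_from_left=float(f[p] - f[a]),
                dG_from_right=float(f[p] - f[b]),
            )
        )
    return [float(x[k]) for k in minima], barriers


def folding_temperature(profiles: dict):
    """Interpolated temperature at which folded and unfolded minima are
    equally probable (ΔF = 0).

    ``profiles`` maps temperature (K) to (bin_centers, F). The folded minimum
    is the local minimum at highest Q, the unfolded one at lowest Q. Returns
    the interpolated temperature, or None when ΔF never changes sign over the
    series ("outside range").
    """
    temps = sorted(profiles)
    if not temps:
        raise InputError("no profiles")
    dF = []
    for T in temps:
        centers, F = profiles[T]
        minima, _ = locate_minima_and_barriers(F, centers)
        if len(minima) < 2:
            raise InputError(
                f"profile at {T} K has fewer than two minima; cannot measure ΔF"
            )
        Fv = np.asarray(F, dtype=float)
        cv = np.asarray(centers, dtype=float)
        folded = minima[-1]
        unfolded = minima[0]
        f_at = lambda pos: float(Fv[np.nanargmin(np.abs(cv - pos))])
        dF.append(f_at(folded) - f_at(unfolded))
    for k, d in enumerate(dF):
        if d == 0.0:
            return float(temps[k])
    for k in range(len(temps) - 1):
        if dF[k] * dF[k + 1] < 0:
            t0, t1 = temps[k], temps[k + 1]
            d0, d1 = dF[k], dF[k + 1]
            return float(t0 + (t1 - t0) * (-d0) / (d1 - d0))
    return None


def calibrate_temperature(t_sim, shift: float):
    """Uniform temperature calibration: T_reported = T_sim - shift.

    Raw simulation temperatures are kept in outputs; only reported axes are
    shifted."""
    return np.asarray(t_sim, dtype=float) - shift if np.ndim(t_sim) else float(t_sim) - shift


# ---------------------------------------------------------------------------
# Ensembles, contact maps, φ-values
# ---------------------------------------------------------------------------


@dataclass
class EnsembleDefinition:
    """Labeled Q intervals, e.g. D=[0.1, 0.3), I=[0.35, 0.55), N=[0.7, 1.0].

    Intervals are closed on the left and open on the right, except that an
    upper bound of exactly 1.0 is included (so the native frame Q = 1 is
    assignable)."""

    intervals: dict  # label -> (lo, hi)

    def __post_init__(self):
        ivs = sorted(self.intervals.values())
        for (lo, hi) in ivs:
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigError(f"invalid Q interval ({lo}, {hi})")
        for (a, b), (c, d) in zip(ivs[:-1], ivs[1:]):
            if c < b:
                raise ConfigError("ensemble Q intervals overlap")

    def label_of(self, q: float):
        for label, (lo, hi) in self.intervals.items():
            if lo <= q < hi or (hi == 1.0 and q == 1.0):
                return label
        return None


def assign_ensembles(q_values, definition: EnsembleDefinition) -> list:
    """Label each frame by the Q interval containing it ('unassigned' when
    none does)."""
    return [
        definition.label_of(float(q)) or "unassigned" for q in np.asarray(q_values)
    ]


def contact_frequency_map(
    frames,
    system,
    cutoff: float = 4.5,
    min_separation: int = 3,
) -> np.ndarray:
    """Residue×residue contact frequency over an ensemble of coordinate sets.

    Entry (i, j) is the fraction of frames in which residues i and j are in
    contact under the same geometric rule as define_native_contacts (minimum
    heavy-atom distance < cutoff, |i-j| ≥ min_separation). Symmetric, in
    [0, 1]; pairs below the separation cutoff stay 0.
    """
    frames = list(frames)
    if not frames:
        raise InputError("empty ensemble")
    heavy, _ = _residue_heavy_atoms(system)
    nres = len(heavy)
    freq = np.zeros((nres, nres))
    for coords in frames:
        for i in range(nres):
            if len(heavy[i]) == 0:
                continue
            for j in range(i + min_separation, nres):
                if len(heavy[j]) == 0:
                    continue
                if cdist(coords[heavy[i]], coords[heavy[j]]).min() < cutoff:
                    freq[i, j] += 1.0
                    freq[j, i] += 1.0
    return freq / len(frames)


def difference_map(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Signed elementwise difference A - B of two contact frequency maps."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("contact maps have different shapes")
    return a - b


def phi_values(
    frames,
    labels,
    energies,
    contacts: NativeContactSet,
    T: float,
    k_B: float = DEFAULT_KB,
    normalized: bool = True,
    denominator_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-residue φ-values from Boltzmann-weighted ensemble averages of the
    per-residue nativeness q_i.

    Within each ensemble (labels 'N', 'TS', 'D'), frames are weighted by
    w ∝ exp(-E/k_B T) (normalized within the ensemble). The normalized form
    φ_i = (⟨q_i⟩_TS - ⟨q_i⟩_D) / (⟨q_i⟩_N - ⟨q_i⟩_D) is the default; the raw
    variant φ_raw_i = ⟨q_i⟩_TS is always reported alongside. Residues whose
    q_i is undefined or whose denominator magnitude falls below
    ``denominator_floor`` are flagged (φ = NaN, flagged=True), not clipped.
    """
    frames = list(frames)
    labels = list(labels)
    energies = np.asarray(energies, dtype=float)
    if not (len(frames) == len(labels) == len(energies)):
        raise InputError("frames, labels and energies must have equal length")

    means = {}
    for ens in ("N", "TS", "D"):
        idx = [k for k, lab in enumerate(labels) if lab == ens]
        if not idx:
            raise InputError(f"ensemble {ens!r} is empty")
        E = energies[idx]
        w = np.exp(-(E - E.min()) / (k_B * T))  # shift-invariant weights
        w = w / w.sum()
        qmat = np.array([per_residue_nativeness(frames[k], contacts) for k in idx])
        means[ens] = np.einsum("f,fr->r", w, qmat)

    num = means["TS"] - means["D"]
    den = means["N"] - means["D"]
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = num / den
    flagged = ~np.isfinite(phi_norm) | (np.abs(den) < denominator_floor)
    phi_norm = np.where(flagged, np.nan, phi_norm)
    df = pd.DataFrame(
        {
            "residue": contacts.residue_labels,
            "q_N": means["N"],
            "q_TS": means["TS"],
            "q_D": means["D"],
            "phi": phi_norm if normalized else means["TS"],
            "phi_raw": means["TS"],
            "flagged": flagged,
        }
    )
    return df


# ---------------------------------------------------------------------------
# Heat capacity, RMSD, H-bonds
# ---------------------------------------------------------------------------


def heat_capacity(energy_samples_by_T: dict, k_B: float = DEFAULT_KB) -> pd.DataFrame:
    """Cv(T) = (⟨E²⟩ - ⟨E⟩²) / (k_B T²) from post-equilibration energies."""
    rows = []
    for T in sorted(energy_samples_by_T):
        E = np.asarray(energy_samples_by_T[T], dtype=float)
        if E.size < 2:
            raise InputError(f"need at least 2 energy samples at T={T}")
        rows.append((float(T), float(np.var(E) / (k_B * T**2))))
    return pd.DataFrame(rows, columns=["T", "Cv"])


BACKBONE_SELECTION = {"N", "CA", "C", "O"}


def kabsch_rmsd(coords_a, coords_b, system=None, selection: str = "all") -> float:
    """RMSD after optimal proper-rotation superposition (Kabsch).

    ``selection`` is 'all', 'backbone' (N, CA, C, O) or 'ca'; the latter two
    require ``system`` for atom names. Symmetric in its two arguments.
    """
    from scipy.spatial.transform import Rotation

    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if selection != "all":
        if system is None:
            raise InputError("atom-name selection requires a system")
        names = [a.strip() for a in system.atom_names]
        if selection == "backbone":
            idx = [k for k, nm in enumerate(names) if nm in BACKBONE_SELECTION]
        elif selection.lower() in ("ca", "calpha"):
            idx = [k for k, nm in enumerate(names) if nm == "CA"]
        else:
            raise ConfigError(f"unknown selection {selection!r}")
        A, B = A[idx], B[idx]
    if A.shape != B.shape:
        raise InputError(f"coordinate shapes differ: {A.shape} vs {B.shape}")
    if len(A) < 3:
        raise InputError("need at least 3 atoms for superposition")
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    _, rssd = Rotation.align_vectors(A0, B0)
    return float(rssd / np.sqrt(len(A0)))


def hbond_distance(coords, donor_hydrogens, acceptors) -> float:
    """Minimum H⋯acceptor distance (Å) over all (hydrogen, acceptor) pairs."""
    dh = np.asarray(donor_hydrogens, dtype=int)
    ac = np.asarray(acceptors, dtype=int)
    if dh.size == 0 or ac.size == 0:
        raise InputError("empty donor-hydrogen or acceptor selection")
    return float(cdist(coords[dh], coords[ac]).min())
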