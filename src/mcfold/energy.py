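"""Potential energy: AMBER-style bonded terms, δ-regularized LJ/Coulomb,
OBC-II generalized-Born polar solvation, and Shrake-Rupley SASA nonpolar
solvation.

A constant offset δ (default 0.001 Å) is added to every interatomic distance
entering the Coulomb, LJ, and GB terms, which keeps all terms finite even at
exact atomic overlap — the regularization a Monte Carlo sampler needs because
bold moves occasionally propose clashing geometries. The offset is never
applied to GB self (i = j) terms.

No cutoffs or neighbor-list approximations are used anywhere: all pairwise
sums are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "SolventModelParams",
    "EnergyBreakdown",
    "effective_distance",
    "bonded_energy",
    "lj_coulomb_energy",
    "born_radii",
    "gb_polar_energy",
    "sasa_nonpolar",
    "total_energy",
]

#: pairwise-descreening scaling factors by element (HCT convention)
GB_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96}
GB_SCREEN_DEFAULT = 0.80


@dataclass
class SolventModelParams:
    """Physical constants and implicit-solvent knobs.

    eps_p / eps_w are the protein / water dielectric constants; gamma_cal is
    the SASA surface tension in cal/mol/Å² (converted to kcal internally);
    delta is the distance regularization offset in Å.
    """

    eps_p: float = 1.0
    eps_w: float = 80.0
    gamma_cal: float = 5.42  # cal/mol/Å²
    probe_radius: float = 1.4  # Å
    delta: float = 0.001  # Å
    k_e: float = 332.0636  # kcal·Å/mol/e²
    k_B: float = 1.9872041e-3  # kcal/mol/K
    # OBC-II generalized-Born flavor
    gb_radius_offset: float = 0.009  # Å
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    gb_screen: dict = field(default_factory=lambda: dict(GB_SCREEN))
    # nonbonded 1-4 scaling (AMBER convention)
    lj14_scale: float = 0.5
    coul14_scale: float = 1.0 / 1.2
    # SASA quadrature
    n_sphere_points: int = 960

    def __post_init__(self):
        # equality makes the GB prefactor vanish (vacuum reference); allowed
        if not (self.eps_w >= self.eps_p >= 1.0):
            raise ConfigError("require eps_w >= eps_p >= 1")
        if self.gamma_cal < 0:
            raise ConfigError("surface tension must be >= 0")
        if self.delta <= 0:
            raise ConfigError("distance offset delta must be > 0")
        if self.probe_radius < 0:
            raise ConfigError("probe radius must be >= 0")

    @property
    def gamma_kcal(self) -> float:
        return self.gamma_cal / 1000.0


@dataclass
class EnergyBreakdown:
    """Per-term energies in kcal/mol; E_total is their exact sum."""

    E_bond: float = 0.0
    E_angle: float = 0.0
    E_torsion: float = 0.0
    E_improper: float = 0.0
    E_LJ: float = 0.0
    E_Coulomb: float = 0.0
    E_GB: float = 0.0
    E_nonpolar: float = 0.0
    E_restraint: float = 0.0

    @property
    def E_total(self) -> float:
        return (
            self.E_bond + self.E_angle + self.E_torsion + self.E_improper
            + self.E_LJ + self.E_Coulomb + self.E_GB + self.E_nonpolar
            + self.E_restraint
        )

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "E_bond", "E_angle", "E_torsion", "E_improper", "E_LJ",
            "E_Coulomb", "E_GB", "E_nonpolar", "E_restraint")}
        d["E_total"] = self.E_total
        return d


def effective_distance(r, params: SolventModelParams):
    """r + δ; the regularized distance used by Coulomb, LJ, and GB."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InputError("negative distance")
    out = r + params.delta
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


try:  # optional acceleration; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=False)
    def _bonded_kernel(coords, bonds, bond_params, angles, angle_params,
                       torsions, torsion_params, impropers, improper_params):
        e_bond = 0.0
        for m in range(bonds.shape[0]):
            i, j = bonds[m, 0], bonds[m, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            e_bond += bond_params[m, 0] * (r - bond_params[m, 1]) ** 2
        e_angle = 0.0
        for m in range(angles.shape[0]):
            i, j, k = angles[m, 0], angles[m, 1], angles[m, 2]
            ux = coords[i, 0] - coords[j, 0]
            uy = coords[i, 1] - coords[j, 1]
            uz = coords[i, 2] - coords[j, 2]
            vx = coords[k, 0] - coords[j, 0]
            vy = coords[k, 1] - coords[j, 1]
            vz = coords[k, 2] - coords[j, 2]
            cosang = (ux * vx + uy * vy + uz * vz) / (
                ((ux * ux + uy * uy + uz * uz) * (vx * vx + vy * vy + vz * vz)) ** 0.5
            )
            if cosang > 1.0:
                cosang = 1.0
            elif cosang < -1.0:
                cosang = -1.0
            theta = np.arccos(cosang)
            e_angle += angle_params[m, 0] * (theta - angle_params[m, 1]) ** 2
        e_torsion = 0.0
        e_improper = 0.0
        for which in range(2):
            quads = torsions if which == 0 else impropers
            pars = torsion_params if which == 0 else improper_params
            acc = 0.0
            for m in range(quads.shape[0]):
                a, b, c, d = quads[m, 0], quads[m, 1], quads[m, 2], quads[m, 3]
                b1x = coords[b, 0] - coords[a, 0]
                b1y = coords[b, 1] - coords[a, 1]
                b1z = coords[b, 2] - coords[a, 2]
                b2x = coords[c, 0] - coords[b, 0]
                b2y = coords[c, 1] - coords[b, 1]
                b2z = coords[c, 2] - coords[b, 2]
                b3x = coords[d, 0] - coords[c, 0]
                b3y = coords[d, 1] - coords[c, 1]
                b3z = coords[d, 2] - coords[c, 2]
                n1x = b1y * b2z - b1z * b2y
                n1y = b1z * b2x - b1x * b2z
                n1z = b1x * b2y - b1y * b2x
                n2x = b2y * b3z - b2z * b3y
                n2y = b2z * b3x - b2x * b3z
                n2z = b2x * b3y - b2y * b3x
                b2n = (b2x * b2x + b2y * b2y + b2z * b2z) ** 0.5
                m1x = (n1y * b2z - n1z * b2y) / b2n
                m1y = (n1z * b2x - n1x * b2z) / b2n
                m1z = (n1x * b2y - n1y * b2x) / b2n
                x = n1x * n2x + n1y * n2y + n1z * n2z
                y = m1x * n2x + m1y * n2y + m1z * n2z
                phi = np.arctan2(y, x)
                acc += pars[m, 0] * (1.0 + np.cos(pars[m, 1] * phi - pars[m, 2]))
            if which == 0:
                e_torsion = acc
            else:
                e_improper = acc
        return e_bond, e_angle, e_torsion, e_improper

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional dependency
    _HAVE_NUMBA = False


def bonded_energy(system, coords):
    """(E_bond, E_angle, E_torsion, E_improper) in kcal/mol."""
    from .geometry import dihedral_angles

    if _HAVE_NUMBA:
        out = _bonded_kernel(
            coords, system.bonds, system.bond_params,
            system.angles, system.angle_params,
            system.torsions, system.torsion_params,
            system.impropers, system.improper_params,
        )
        return tuple(float(v) for v in out)

    e_bond = e_angle = e_torsion = e_improper = 0.0
    if len(system.bonds):
        d = coords[system.bonds[:, 0]] - coords[system.bonds[:, 1]]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        kb, r0 = system.bond_params[:, 0], system.bond_params[:, 1]
        e_bond = float(np.sum(kb * (r - r0) ** 2))
    if len(system.angles):
        a = coords[system.angles[:, 0]]
        b = coords[system.angles[:, 1]]
        c = coords[system.angles[:, 2]]
        u, v = a - b, c - b
        cosang = np.einsum("ij,ij->i", u, v) / np.sqrt(
            np.einsum("ij,ij->i", u, u) * np.einsum("ij,ij->i", v, v)
        )
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        kt, t0 = system.angle_params[:, 0], system.angle_params[:, 1]
        e_angle = float(np.sum(kt * (theta - t0) ** 2))
    if len(system.torsions):
        phi = dihedral_angles(coords, system.torsions)
        k, n, ph = (system.torsion_params[:, i] for i in range(3))
        e_torsion = float(np.sum(k * (1.0 + np.cos(n * phi - ph))))
    if len(system.impropers):
        phi = dihedral_angles(coords, system.impropers)
        k, n, ph = (system.improper_params[:, i] for i in range(3))
        e_improper = float(np.sum(k * (1.0 + np.cos(n * phi - ph))))
    return e_bond, e_angle, e_torsion, e_improper


# ---------------------------------------------------------------------------
# Nonbonded pair terms
# ---------------------------------------------------------------------------


def _nb_pairs(system):
    """Cached flattened non-excluded pair arrays with combining rules and
    1-4 scale flags."""
    if system._nb_cache is not None:
        return system._nb_cache
    n = system.n_atoms
    ii, jj = np.triu_indices(n, k=1)
    keep = np.ones(len(ii), dtype=bool)
    is14 = np.zeros(len(ii), dtype=bool)
    pairmap = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(ii, jj))}
    for p in system.exclusions:
        k = pairmap.get((min(p), max(p)))
        if k is not None:
            keep[k] = False
    for p in system.pairs14:
        k = pairmap.get((min(p), max(p)))
        if k is not None:
            is14[k] = True
    ii, jj, is14 = ii[keep], jj[keep], is14[keep]
    sigma = 0.5 * (system.lj_sigma[ii] + system.lj_sigma[jj])  # Lorentz
    eps = np.sqrt(system.lj_epsilon[ii] * system.lj_epsilon[jj])  # Berthelot
    qq = system.charges[ii] * system.charges[jj]
    cache = {"i": ii, "j": jj, "is14": is14, "sigma": sigma, "eps": eps, "qq": qq}
    system._nb_cache = cache
    return cache


def lj_coulomb_energy(system, coords, params: SolventModelParams):
    """(E_LJ, E_Coulomb): exact pair sums over non-excluded pairs, with 1-4
    pairs scaled (LJ × lj14_scale, Coulomb × coul14_scale) and δ-offset
    distances."""
    if not system.parameterized:
        raise InputError("system has no nonbonded parameters")
    pc = _nb_pairs(system)
    if len(pc["i"]) == 0:
        return 0.0, 0.0
    d = coords[pc["i"]] - coords[pc["j"]]
    r = np.sqrt(np.einsum("ij,ij->i", d, d)) + params.delta
    lj_scale = np.where(pc["is14"], params.lj14_scale, 1.0)
    c_scale = np.where(pc["is14"], params.coul14_scale, 1.0)
    sr6 = (pc["sigma"] / r) ** 6
    e_lj = float(np.sum(4.0 * pc["eps"] * lj_scale * (sr6 * sr6 - sr6)))
    e_coul = float(params.k_e / params.eps_p * np.sum(c_scale * pc["qq"] / r))
    return e_lj, e_coul


# ---------------------------------------------------------------------------
# Generalized Born (OBC-II with HCT pairwise descreening)
# ---------------------------------------------------------------------------


def born_radii(system, coords, params: SolventModelParams) -> np.ndarray:
    """Per-atom effective Born radii (Å) via HCT pairwise descreening with
    the OBC-II tanh rescaling (α=1, β=0.8, γ=4.85 by default).

    An isolated atom's Born radius equals its offset intrinsic radius
    ρ = R − offset; burial only increases the radius.
    """
    R = system.gb_radius
    if R is None or np.any(R <= 0):
        raise InputError("nonpositive intrinsic GB radius")
    rho = R - params.gb_radius_offset
    if np.any(rho <= 0):
        raise InputError("intrinsic GB radius smaller than the radius offset")
    n = len(R)
    screen = np.array(
        [params.gb_screen.get(el, GB_SCREEN_DEFAULT) for el in system.elements]
    )
    sr = screen * rho  # scaled descreening radii

    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(r, np.inf)
    r = r + params.delta  # offset interatomic distances (spec of the model)

    rho_i = rho[:, None]
    sr_j = sr[None, :]
    U = r + sr_j
    mask = U > rho_i  # atom j contributes only if it pokes out of atom i
    L = np.maximum(rho_i, np.abs(r - sr_j))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = 0.5 * (
            1.0 / L
            - 1.0 / U
            + 0.25 * (r - sr_j**2 / r) * (1.0 / U**2 - 1.0 / L**2)
            + 0.5 / r * np.log(L / U)
        )
        # atom i entirely inside atom j's descreening sphere
        inside = rho_i < (sr_j - r)
        term = term + np.where(inside, 1.0 / rho_i - 1.0 / L, 0.0)
    term = np.where(mask, term, 0.0)
    np.fill_diagonal(term, 0.0)
    I = term.sum(axis=1)

    psi = I * rho
    tanh_arg = params.obc_alpha * psi - params.obc_beta * psi**2 + params.obc_gamma * psi**3
    B = 1.0 / (1.0 / rho - np.tanh(tanh_arg) / R)
    return B


def gb_polar_energy(charges, coords, radii, params: SolventModelParams) -> float:
    """Still-style GB polar solvation energy (kcal/mol):

    ΔG = -(k_e/2)(1/ε_p - 1/ε_w) Σ_ij q_i q_j / f_GB,
    f_GB = sqrt(r'² + B_i B_j exp(-r'²/(4 B_i B_j))), f_GB(i=i) = B_i.

    Always ≤ 0 for nonzero charges when ε_w > ε_p. Self terms use the bare
    Born radius (no δ offset).
    """
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise InputError("nonpositive Born radius")
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    r = np.sqrt(r2)
    np.fill_diagonal(r, 0.0)
    roff = r + params.delta
    BB = radii[:, None] * radii[None, :]
    f = np.sqrt(roff**2 + BB * np.exp(-(roff**2) / (4.0 * BB)))
    np.fill_diagonal(f, radii)  # self terms: f_GB = B_i, no offset
    qq = charges[:, None] * charges[None, :]
    pref = -0.5 * params.k_e * (1.0 / params.eps_p - 1.0 / params.eps_w)
    return float(pref * np.sum(qq / f))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley on a Fibonacci sphere)
# ---------------------------------------------------------------------------

_sphere_cache: dict = {}


def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    pts = _sphere_cache.get(n)
    if pts is None:
        k = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)
        theta = np.pi * (1.0 + 5.0**0.5) * k
        pts = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        _sphere_cache[n] = pts
    return pts


def _molecule_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation-equivariant orthonormal frame from the coordinate cloud.

    The quadrature directions are expressed in this frame so that SASA is
    exactly invariant under rigid rotations of the molecule (a lab-fixed
    point grid would jitter by ~0.1 Å² under rotation). Axes are the
    principal axes of the centered coordinates; signs follow the first atoms
    with a non-negligible projection, and the third axis is their cross
    product (right-handed by construction).
    """
    n = len(coords)
    if n < 3:
        return np.eye(3)
    c = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    v1, v2 = vecs[:, 2], vecs[:, 1]  # two largest principal axes
    for v in (v1, v2):
        for row in c:
            d = float(row @ v)
            if abs(d) > 1e-8:
                if d < 0:
                    v *= -1.0
                break
    v3 = np.cross(v1, v2)
    return np.column_stack([v1, v2, v3])


def sasa_radii(system, params: SolventModelParams) -> np.ndarray:
    """Atomic radii used for SASA: LJ minimum-distance radii r = 2^(1/6) σ/2."""
    if system.lj_sigma is None:
        raise InputError("system has no LJ parameters for SASA radii")
    return 2.0 ** (1.0 / 6.0) * system.lj_sigma / 2.0


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _sasa_kernel(coords, R, sphere):
        n = coords.shape[0]
        P = sphere.shape[0]
        per_atom = np.zeros(n)
        nbr = np.empty(n, dtype=np.int64)
        for i in range(n):
            n_nbr = 0
            for j in range(n):
                if j == i:
                    continue
                dx = coords[i, 0] - coords[j, 0]
                dy = coords[i, 1] - coords[j, 1]
                dz = coords[i, 2] - coords[j, 2]
                reach = R[i] + R[j]
                if dx * dx + dy * dy + dz * dz < reach * reach:
                    nbr[n_nbr] = j
                    n_nbr += 1
            n_acc = 0
            for p in range(P):
                px = coords[i, 0] + R[i] * sphere[p, 0]
                py = coords[i, 1] + R[i] * sphere[p, 1]
                pz = coords[i, 2] + R[i] * sphere[p, 2]
                buried = False
                for m in range(n_nbr):
                    j = nbr[m]
                    dx = px - coords[j, 0]
                    dy = py - coords[j, 1]
                    dz = pz - coords[j, 2]
                    if dx * dx + dy * dy + dz * dz < R[j] * R[j]:
                        buried = True
                        break
                if not buried:
                    n_acc += 1
            per_atom[i] = 4.0 * np.pi * R[i] * R[i] * n_acc / P
        return per_atom


def sasa_nonpolar(system, coords, params: SolventModelParams, radii=None):
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-atom SASA Å², total SASA Å², E_nonpolar kcal/mol) with
    E_nonpolar = γ · SASA_total. Quadrature error scales as 1/n_sphere_points;
    an isolated sphere is exact by construction.
    """
    if radii is None:
        radii = sasa_radii(system, params)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise InputError("nonpositive SASA radius")
    n = len(radii)
    R = radii + params.probe_radius
    sphere = _unit_sphere(params.n_sphere_points) @ _molecule_frame(coords).T

    if _HAVE_NUMBA:
        per_atom = _sasa_kernel(coords, R, sphere)
        total = float(per_atom.sum())
        return per_atom, total, params.gamma_kcal * total

    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    per_atom = np.zeros(n)
    for i in range(n):
        # neighbors whose inflated sphere can intersect atom i's surface
        reach = (R[i] + R) ** 2
        nbr = np.flatnonzero((d2[i] < reach) & (np.arange(n) != i))
        area_i = 4.0 * np.pi * R[i] ** 2
        if len(nbr) == 0:
            per_atom[i] = area_i
            continue
        pts = coords[i] + R[i] * sphere  # (P, 3)
        dp = pts[:, None, :] - coords[nbr][None, :, :]
        buried = np.any(
            np.einsum("pjk,pjk->pj", dp, dp) < (R[nbr] ** 2)[None, :], axis=1
        )
        per_atom[i] = area_i * np.count_nonzero(~buried) / len(sphere)
    total = float(per_atom.sum())
    return per_atom, total, params.gamma_kcal * total


# ---------------------------------------------------------------------------
# Total energy
# ---------------------------------------------------------------------------


def total_energy(system, coords, params: SolventModelParams, restraint=None) -> EnergyBreakdown:
    """Full potential at the given coordinates.

    ``restraint`` is any object with an ``energy(coords) -> float`` method
    (e.g. the sampler's harmonic wall in Q). Charge-free systems skip the
    Coulomb/GB work and γ = 0 skips the SASA quadrature; the skipped terms
    are exactly zero in those cases.
    """
    if not system.parameterized:
        raise InputError("system is not parameterized")
    eb = EnergyBreakdown()
    eb.E_bond, eb.E_angle, eb.E_torsion, eb.E_improper = bonded_energy(system, coords)

    has_charge = bool(np.any(system.charges))
    has_lj = bool(np.any(system.lj_epsilon))
    if has_charge or has_lj:
        eb.E_LJ, eb.E_Coulomb = lj_coulomb_energy(system, coords, params)
    if has_charge:
        B = born_radii(system, coords, params)
        eb.E_GB = gb_polar_energy(system.charges, coords, B, params)
    if params.gamma_cal > 0.0:
        _, _, eb.E_nonpolar = sasa_nonpolar(system, coords, params)
    if restraint is not None:
        eb.E_restraint = float(restraint.energy(coords))
    if not np.isfinite(eb.E_total):
        warnings.warn("non-finite total energy", RuntimeWarning)
    return eb
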