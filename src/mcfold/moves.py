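"""Symmetric Monte Carlo proposals in torsion space.

Three move kinds, all with symmetric proposal densities (q(x→x') = q(x'→x)),
so plain Metropolis acceptance needs no Hastings correction:

* ``dihedral``  — rotate one uniformly chosen rotatable torsion by a Gaussian
  angle; only the downstream subtree moves, so no bond stretches.
* ``concerted`` — crankshaft rotation of the atoms strictly between two
  backbone anchors (N of the first and C of the last residue of a 4-residue
  window) about the anchor-anchor axis; endpoints stay exactly fixed.
* ``rigid``     — small whole-molecule rotation about a random axis through
  the geometric center (uniform angle up to 5°); an exact isometry.

Because every move is a rigid rotation of a subset of atoms about an axis
whose endpoints are fixed, no move ever changes a bond length — this is the
mechanism that frees the sampler from the femtosecond integration constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError
from .geometry import rotate_about_axis
from .model_io import MolecularSystem, RotatableDihedralSet, _component

__all__ = [
    "MoveProposal",
    "dihedral_move",
    "concerted_move",
    "rigid_rotation_move",
    "select_move",
]

MOVE_KINDS = ("dihedral", "concerted", "rigid")


@dataclass
class MoveProposal:
    coords: np.ndarray  # full proposed coordinate set
    kind: str
    changed: np.ndarray  # indices of atoms that may have moved
    meta: dict  # axis/angle bookkeeping, enough to reconstruct the inverse

    def apply_inverse(self) -> np.ndarray:
        """Undo the recorded transform (round-trip check for symmetry)."""
        out = self.coords.copy()
        out[self.changed] = rotate_about_axis(
            self.coords[self.changed],
            self.meta["origin"],
            self.meta["axis"],
            -self.meta["angle_rad"],
        )
        return out


def _rotated(coords, idx, origin, axis, angle):
    new = coords.copy()
    new[idx] = rotate_about_axis(coords[idx], origin, axis, angle)
    return new


def dihedral_move(
    system: MolecularSystem,
    dihedrals: RotatableDihedralSet,
    coords: np.ndarray,
    rng: np.random.Generator,
    width_deg: float = 20.0,
) -> MoveProposal:
    """Rotate one uniformly chosen rotatable dihedral by Δθ ~ N(0, width²)."""
    if len(dihedrals) == 0:
        raise InputError("no rotatable dihedrals")
    k = int(rng.integers(len(dihedrals)))
    dih = dihedrals[k]
    dtheta = np.deg2rad(rng.normal(0.0, width_deg))
    _, b, c, _ = dih.atoms
    origin = coords[b]
    axis = coords[c] - coords[b]
    idx = dih.downstream_idx
    new = _rotated(coords, idx, origin, axis, dtheta)
    return MoveProposal(
        coords=new,
        kind="dihedral",
        changed=idx,
        meta={
            "dihedral_index": k,
            "dihedral_kind": dih.kind,
            "angle_deg": float(np.rad2deg(dtheta)),
            "angle_rad": float(dtheta),
            "origin": origin.copy(),
            "axis": axis.copy(),
        },
    )


def concerted_windows(system: MolecularSystem, window_residues: int = 4) -> list:
    """Interior windows of ``window_residues`` consecutive residues, each with
    (anchor_N, anchor_C, moved-atom indices). Cached on the system."""
    key = ("windows", window_residues)
    cached = system._window_cache.get(key)
    if cached is not None:
        return cached

    reskeys = system.residue_keys()
    if len(reskeys) < window_residues + 2:
        raise InputError(
            f"chain has {len(reskeys)} residues; concerted moves need at least "
            f"{window_residues + 2}"
        )
    resmap = system.residue_atom_indices()
    names = [a.strip() for a in system.atom_names]

    def find(reskey, nm):
        for a in resmap[reskey]:
            if names[a] == nm:
                return a
        return None

    adj = system.bond_adjacency()
    windows = []
    # interior windows only: never include the first or last residue
    for s in range(1, len(reskeys) - window_residues):
        first, last = reskeys[s], reskeys[s + window_residues - 1]
        a1 = find(first, "N")
        a2 = find(last, "C")
        ca = find(first, "CA")
        if a1 is None or a2 is None or ca is None:
            continue
        comp = _component(adj, ca, banned_nodes=(a1, a2))
        windows.append((a1, a2, np.array(sorted(comp), dtype=int)))
    if not windows:
        raise InputError("no valid concerted-move windows (missing backbone atoms?)")
    system._window_cache[key] = windows
    return windows


def concerted_move(
    system: MolecularSystem,
    coords: np.ndarray,
    rng: np.random.Generator,
    window_residues: int = 4,
    width_deg: float = 20.0,
) -> MoveProposal:
    """Endpoint-constrained crankshaft move over a 4-residue window.

    A uniformly chosen window's interior block rotates rigidly about the axis
    through the two anchors (window-start N, window-end C) by Δθ ~ N(0, width²).
    Anchors and everything outside the window do not move; all bond lengths
    are preserved because every bond crossing the block boundary ends on an
    axis atom.
    """
    windows = concerted_windows(system, window_residues)
    k = int(rng.integers(len(windows)))
    a1, a2, idx = windows[k]
    dtheta = np.deg2rad(rng.normal(0.0, width_deg))
    origin = coords[a1]
    axis = coords[a2] - coords[a1]
    new = _rotated(coords, idx, origin, axis, dtheta)
    return MoveProposal(
        coords=new,
        kind="concerted",
        changed=idx,
        meta={
            "window_index": k,
            "anchors": (int(a1), int(a2)),
            "angle_deg": float(np.rad2deg(dtheta)),
            "angle_rad": float(dtheta),
            "origin": origin.copy(),
            "axis": axis.copy(),
        },
    )


def rigid_rotation_move(
    coords: np.ndarray,
    rng: np.random.Generator,
    max_deg: float = 5.0,
) -> MoveProposal:
    """Whole-molecule rotation about a random axis through the geometric
    center, with rotation angle uniform on [0, max_deg]."""
    if len(coords) < 2:
        raise InputError("rigid rotation needs at least 2 atoms")
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    center = coords.mean(axis=0)
    idx = np.arange(len(coords))
    new = rotate_about_axis(coords, center, axis, angle)
    return MoveProposal(
        coords=new,
        kind="rigid",
        changed=idx,
        meta={
            "angle_deg": float(np.rad2deg(angle)),
            "angle_rad": float(angle),
            "origin": center,
            "axis": axis,
        },
    )


def select_move(rng: np.random.Generator, move_weights) -> str:
    """Categorical draw over (dihedral, concerted, rigid) weights."""
    if len(move_weights) != 3 or any(w < 0 for w in move_weights):
        raise ConfigError("move_weights must be 3 nonnegative numbers")
    s = move_weights[0] + move_weights[1] + move_weights[2]
    if s <= 0:
        raise ConfigError("move_weights must not all be zero")
    r = rng.random() * s
    acc = 0.0
    for kind, wk in zip(MOVE_KINDS, move_weights):
        acc += wk
        if r < acc:
            return kind
    return MOVE_KINDS[-1]
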