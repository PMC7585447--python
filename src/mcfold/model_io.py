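"""Structures, topologies, rotatable-dihedral trees, and synthetic test systems.

A :class:`MolecularSystem` bundles everything the energy function needs: atom
records, coordinates (Å), partial charges (e), Lennard-Jones parameters
(σ in Å, ε in kcal/mol), intrinsic generalized-Born radii (Å), and the bonded
force-field terms in the internal kcal/mol/Å/rad convention

    E_bond    = Σ k_b (r - r0)^2
    E_angle   = Σ k_θ (θ - θ0)^2
    E_torsion = Σ k (1 + cos(nφ - φ0))

Parameter assignment itself (the pdb2gmx step) is out of scope: topologies
arrive pre-assigned in a documented GROMACS-ASCII subset and are converted
from GROMACS units (nm, kJ/mol, half-factor harmonics) on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError, ParseError
from .geometry import bond_angle, dihedral_angle, nerf_place

KJ_PER_KCAL = 4.184

#: Bondi van der Waals radii (Å) used as intrinsic GB radii when a topology
#: does not supply its own.
BONDI_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}

#: Default per-element LJ parameters (σ Å, ε kcal/mol) for synthetic systems.
#: Hydrogens bonded to nitrogen get the much smaller polar-H radius (see
#: DEFAULT_LJ_POLAR_H), as in AMBER-family force fields.
DEFAULT_LJ = {
    "H": (2.47, 0.0157),
    "C": (3.40, 0.0860),
    "N": (3.25, 0.1700),
    "O": (2.96, 0.2100),
    "S": (3.56, 0.2500),
}
DEFAULT_LJ_POLAR_H = (1.07, 0.0157)


def element_from_name(name: str) -> str:
    """Guess the element from a PDB atom name (first alphabetic character)."""
    for ch in name.strip():
        if ch.isalpha():
            return ch.upper()
    raise InputError(f"cannot infer element from atom name {name!r}")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class MolecularSystem:
    """All-atom system with coordinates and (optionally) force-field terms."""

    atom_names: list[str]
    elements: list[str]
    res_names: list[str]
    res_ids: np.ndarray  # 1-based residue numbering as in the source file
    chain_ids: list[str]
    coords: np.ndarray  # (N, 3) Å

    charges: np.ndarray | None = None  # (N,) e
    lj_sigma: np.ndarray | None = None  # (N,) Å
    lj_epsilon: np.ndarray | None = None  # (N,) kcal/mol
    gb_radius: np.ndarray | None = None  # (N,) Å

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    angle_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    torsions: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    torsion_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    impropers: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    improper_params: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    exclusions: set = field(default_factory=set)  # {(i, j), i < j}: 1-2 and 1-3
    pairs14: set = field(default_factory=set)  # {(i, j), i < j}

    # lazily built caches (not part of the logical state)
    _nb_cache: dict | None = field(default=None, repr=False, compare=False)
    _window_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def parameterized(self) -> bool:
        return self.charges is not None

    def validate(self) -> None:
        n = self.n_atoms
        if self.coords.shape != (n, 3):
            raise InputError(
                f"coordinate count {self.coords.shape} does not match {n} atoms"
            )
        for arr, nm in (
            (self.bonds, "bond"),
            (self.angles, "angle"),
            (self.torsions, "torsion"),
            (self.impropers, "improper"),
        ):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise InputError(f"{nm} list references an atom index outside 0..{n-1}")
        for i, j in self.exclusions:
            if not (0 <= i < n and 0 <= j < n):
                raise InputError("exclusion references an invalid atom index")
        if self.exclusions & self.pairs14:
            bad = sorted(self.exclusions & self.pairs14)[0]
            raise InputError(
                f"pair {bad} listed both as a 1-4 pair and as an exclusion"
            )
        for name, arr in (
            ("charges", self.charges),
            ("lj_sigma", self.lj_sigma),
            ("lj_epsilon", self.lj_epsilon),
            ("gb_radius", self.gb_radius),
        ):
            if arr is not None and not np.all(np.isfinite(arr)):
                raise InputError(f"non-finite values in {name}")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")

    # -- graph helpers ------------------------------------------------------

    def bond_adjacency(self) -> list[set]:
        adj: list[set] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        return adj

    def residue_atom_indices(self) -> dict:
        """Map (chain_id, res_id) -> list of atom indices, in file order."""
        out: dict = {}
        for k in range(self.n_atoms):
            out.setdefault((self.chain_ids[k], int(self.res_ids[k])), []).append(k)
        return out

    def residue_keys(self) -> list:
        seen: list = []
        for k in range(self.n_atoms):
            key = (self.chain_ids[k], int(self.res_ids[k]))
            if not seen or seen[-1] != key:
                if key in seen:
                    raise InputError(f"residue {key} is not contiguous in atom order")
                seen.append(key)
        return seen

    def invalidate_caches(self) -> None:
        self._nb_cache = None
        self._window_cache = {}


@dataclass(frozen=True)
class RotatableDihedral:
    """One rotatable torsion: 4 atom indices, a class label, and the set of
    atoms rotated when the central bond turns (the axis atoms stay fixed)."""

    atoms: tuple  # (a, b, c, d); rotation axis is b-c
    kind: str  # "phi" | "psi" | "chi"
    downstream: frozenset  # atoms moved by the rotation
    downstream_idx: np.ndarray = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        idx = np.fromiter(self.downstream, dtype=int)
        idx.sort()
        object.__setattr__(self, "downstream_idx", idx)


@dataclass
class RotatableDihedralSet:
    dihedrals: list

    def __len__(self) -> int:
        return len(self.dihedrals)

    def __iter__(self):
        return iter(self.dihedrals)

    def __getitem__(self, k):
        return self.dihedrals[k]

    def of_kind(self, kind: str) -> list:
        return [d for d in self.dihedrals if d.kind == kind]


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _prescan_pdb(path) -> int:
    """Validate ATOM/HETATM records field-by-field; return the MODEL count.

    Gives line-accurate parse errors before handing the file to biotite.
    """
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated {rec} record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: malformed {rec} record: {exc}"
                    ) from exc
    return max(n_models, 1)


def count_models(path) -> int:
    """Number of MODEL records in a PDB file (1 for single implicit model)."""
    return _prescan_pdb(path)


def read_pdb(path, model_index: int = 1) -> MolecularSystem:
    """Read one model of a PDB file into an unparameterized system.

    Coordinates are in Å; residue numbering is preserved from the file.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        with open(path) as fh:
            pass
    except OSError as exc:
        raise InputError(f"cannot open PDB file {path}: {exc}") from exc

    n_models = _prescan_pdb(path)
    if not (1 <= model_index <= n_models):
        raise InputError(
            f"model_index {model_index} out of range: {path} has {n_models} model(s)"
        )
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model_index)

    elements = [
        e.capitalize().upper() if e else element_from_name(nm)
        for e, nm in zip(arr.element, arr.atom_name)
    ]
    sys_ = MolecularSystem(
        atom_names=list(arr.atom_name),
        elements=[e[:1] if len(e) > 1 and e not in ("CL", "BR") else e for e in elements],
        res_names=list(arr.res_name),
        res_ids=np.asarray(arr.res_id, dtype=int),
        chain_ids=list(arr.chain_id),
        coords=np.asarray(arr.coord, dtype=float),
    )
    sys_.validate()
    return sys_


def write_pdb(system: MolecularSystem, coords_list, path) -> None:
    """Write one or more coordinate sets as a (multi-)MODEL PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords_list = np.asarray(coords_list, dtype=float)
    if coords_list.ndim == 2:
        coords_list = coords_list[None]
    if coords_list.shape[1:] != (system.n_atoms, 3):
        raise InputError(
            f"coordinate sets have shape {coords_list.shape}, "
            f"expected (*, {system.n_atoms}, 3)"
        )
    for nm in system.atom_names:
        if len(nm.strip()) > 4:
            raise InputError(f"atom name {nm!r} exceeds the 4-character PDB column")
    for rn in system.res_names:
        if len(rn.strip()) > 3:
            raise InputError(f"residue name {rn!r} exceeds the 3-character PDB column")

    n = system.n_atoms
    stack = struc.AtomArrayStack(coords_list.shape[0], n)
    stack.coord = coords_list
    stack.atom_name = np.array(system.atom_names)
    stack.element = np.array(system.elements)
    stack.res_name = np.array(system.res_names)
    stack.res_id = np.asarray(system.res_ids)
    stack.chain_id = np.array([c if c.strip() else "A" for c in system.chain_ids])
    stack.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Topology I/O: documented GROMACS-ASCII subset
# ---------------------------------------------------------------------------
#
# Accepted sections (self-contained; no #include force-field database):
#   [ atoms ]       nr type resnr residue atom cgnr charge mass sigma_nm
#                   epsilon_kJ [gb_radius_nm]
#   [ bonds ]       i j funct b0_nm kb_kJ_nm2          (funct 1)
#   [ angles ]      i j k funct th0_deg kth_kJ_rad2    (funct 1)
#   [ dihedrals ]   i j k l funct phase_deg k_kJ mult  (funct 1/4/9; 4 = improper)
#   [ pairs ]       i j [funct]
#   [ exclusions ]  i j1 [j2 ...]                      (extra exclusions)
# Indices are 1-based as in GROMACS. GROMACS harmonics carry a 1/2 factor,
# ours do not, hence the /2 on conversion. 1-2 and 1-3 exclusions are derived
# from the bond graph automatically.


@dataclass
class Topology:
    charges: np.ndarray
    masses: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    gb_radius: np.ndarray
    atom_names: list
    res_ids: np.ndarray
    res_names: list
    bonds: np.ndarray
    bond_params: np.ndarray
    angles: np.ndarray
    angle_params: np.ndarray
    torsions: np.ndarray
    torsion_params: np.ndarray
    impropers: np.ndarray
    improper_params: np.ndarray
    pairs14: set
    extra_exclusions: set

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


def read_topology(path) -> Topology:
    """Parse the documented GROMACS-ASCII topology subset.

    Units are converted to the internal kcal/mol / Å / rad convention.
    """
    section = None
    atoms_rows, bonds, angles, dihedrals = [], [], [], []
    pairs: set = set()
    extra_excl: set = set()
    known = {"atoms", "bonds", "angles", "dihedrals", "pairs", "exclusions"}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] \t").lower()
                if section not in known:
                    raise ParseError(
                        f"{path}:{lineno}: unknown directive [ {section} ]"
                    )
                continue
            if section is None:
                raise ParseError(f"{path}:{lineno}: data before any [ section ]")
            tok = line.split()
            try:
                if section == "atoms":
                    if len(tok) not in (10, 11):
                        raise ValueError(f"expected 10 or 11 fields, got {len(tok)}")
                    atoms_rows.append(tok)
                elif section == "bonds":
                    i, j, funct = int(tok[0]), int(tok[1]), int(tok[2])
                    if funct != 1:
                        raise ValueError(f"unsupported bond funct {funct}")
                    b0, kb = float(tok[3]), float(tok[4])
                    bonds.append((i - 1, j - 1, kb / KJ_PER_KCAL / 100.0 / 2.0, b0 * 10.0))
                elif section == "angles":
                    i, j, k, funct = (int(t) for t in tok[:4])
                    if funct != 1:
                        raise ValueError(f"unsupported angle funct {funct}")
                    th0, kth = float(tok[4]), float(tok[5])
                    angles.append(
                        (i - 1, j - 1, k - 1, kth / KJ_PER_KCAL / 2.0, np.deg2rad(th0))
                    )
                elif section == "dihedrals":
                    i, j, k, l, funct = (int(t) for t in tok[:5])
                    if funct not in (1, 4, 9):
                        raise ValueError(f"unsupported dihedral funct {funct}")
                    phase, kd, mult = float(tok[5]), float(tok[6]), int(tok[7])
                    row = (
                        i - 1, j - 1, k - 1, l - 1,
                        kd / KJ_PER_KCAL, float(mult), np.deg2rad(phase),
                        funct == 4,
                    )
                    dihedrals.append(row)
                elif section == "pairs":
                    i, j = int(tok[0]), int(tok[1])
                    pairs.add((min(i, j) - 1, max(i, j) - 1))
                elif section == "exclusions":
                    i = int(tok[0])
                    for j in tok[1:]:
                        j = int(j)
                        extra_excl.add((min(i, j) - 1, max(i, j) - 1))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc

    if not atoms_rows:
        raise ParseError(f"{path}: no [ atoms ] section")

    n = len(atoms_rows)
    charges = np.array([float(r[6]) for r in atoms_rows])
    masses = np.array([float(r[7]) for r in atoms_rows])
    sigma = np.array([float(r[8]) * 10.0 for r in atoms_rows])
    eps = np.array([float(r[9]) / KJ_PER_KCAL for r in atoms_rows])
    names = [r[4] for r in atoms_rows]
    if all(len(r) == 11 for r in atoms_rows):
        gbr = np.array([float(r[10]) * 10.0 for r in atoms_rows])
    else:
        gbr = np.array([BONDI_RADII.get(element_from_name(nm), 1.5) for nm in names])

    proper = [r for r in dihedrals if not r[7]]
    improper = [r for r in dihedrals if r[7]]

    top = Topology(
        charges=charges,
        masses=masses,
        lj_sigma=sigma,
        lj_epsilon=eps,
        gb_radius=gbr,
        atom_names=names,
        res_ids=np.array([int(r[2]) for r in atoms_rows]),
        res_names=[r[3] for r in atoms_rows],
        bonds=np.array([r[:2] for r in bonds], dtype=int).reshape(-1, 2),
        bond_params=np.array([r[2:] for r in bonds]).reshape(-1, 2),
        angles=np.array([r[:3] for r in angles], dtype=int).reshape(-1, 3),
        angle_params=np.array([r[3:] for r in angles]).reshape(-1, 2),
        torsions=np.array([r[:4] for r in proper], dtype=int).reshape(-1, 4),
        torsion_params=np.array([r[4:7] for r in proper]).reshape(-1, 3),
        impropers=np.array([r[:4] for r in improper], dtype=int).reshape(-1, 4),
        improper_params=np.array([r[4:7] for r in improper]).reshape(-1, 3),
        pairs14=pairs,
        extra_exclusions=extra_excl,
    )

    # derived 1-2/1-3 exclusions must not collide with declared 1-4 pairs
    excl = _derive_exclusions(top.bonds, n) | extra_excl
    bad = excl & pairs
    if bad:
        raise ParseError(
            f"{path}: pair(s) {sorted(bad)[:3]} listed under [ pairs ] are also "
            "1-2/1-3 exclusions"
        )
    return top


def _derive_exclusions(bonds: np.ndarray, n_atoms: int) -> set:
    """1-2 and 1-3 exclusions from the bond graph."""
    adj: list[set] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    excl = set()
    for i in range(n_atoms):
        for j in adj[i]:
            if i < j:
                excl.add((i, j))
            for k in adj[j]:
                if k != i and i < k:
                    excl.add((i, k))
    return excl


def derive_pairs14(bonds: np.ndarray, n_atoms: int) -> set:
    """Atom pairs at bond-graph distance exactly 3 (the scaled 1-4 set)."""
    adj: list[set] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    excl = _derive_exclusions(bonds, n_atoms)
    pairs = set()
    for i in range(n_atoms):
        for j in adj[i]:
            for k in adj[j]:
                if k == i:
                    continue
                for l in adj[k]:
                    if l in (i, j):
                        continue
                    p = (min(i, l), max(i, l))
                    if p not in excl and p[0] != p[1]:
                        pairs.add(p)
    return pairs


def apply_topology(system: MolecularSystem, top: Topology) -> MolecularSystem:
    """Attach parsed topology parameters to a structure.

    The topology's atom order must match the structure atom-for-atom.
    """
    if top.n_atoms != system.n_atoms:
        raise InputError(
            f"topology has {top.n_atoms} atoms but structure has {system.n_atoms}"
        )
    for k, (a, b) in enumerate(zip(system.atom_names, top.atom_names)):
        if a.strip() != b.strip():
            raise InputError(
                f"atom {k} name mismatch: structure {a!r} vs topology {b!r}"
            )
    out = replace(
        system,
        charges=top.charges.copy(),
        lj_sigma=top.lj_sigma.copy(),
        lj_epsilon=top.lj_epsilon.copy(),
        gb_radius=top.gb_radius.copy(),
        bonds=top.bonds.copy(),
        bond_params=top.bond_params.copy(),
        angles=top.angles.copy(),
        angle_params=top.angle_params.copy(),
        torsions=top.torsions.copy(),
        torsion_params=top.torsion_params.copy(),
        impropers=top.impropers.copy(),
        improper_params=top.improper_params.copy(),
        exclusions=_derive_exclusions(top.bonds, top.n_atoms) | top.extra_exclusions,
        pairs14=set(top.pairs14),
    )
    out.invalidate_caches()
    out.validate()
    return out


def write_topology(system: MolecularSystem, path) -> None:
    """Write a parameterized system in the accepted GROMACS-subset dialect."""
    if not system.parameterized:
        raise InputError("system has no force-field parameters to write")
    with open(path, "w") as fh:
        fh.write("; mcfold topology (GROMACS-ASCII subset, self-contained)\n")
        fh.write("[ atoms ]\n")
        for k in range(system.n_atoms):
            fh.write(
                f"{k+1:6d} {system.elements[k]:>4s} {int(system.res_ids[k]):4d} "
                f"{system.res_names[k]:>4s} {system.atom_names[k]:>4s} {k+1:4d} "
                f"{system.charges[k]: .6f} {12.0:8.3f} "
                f"{system.lj_sigma[k]/10.0:.6f} {system.lj_epsilon[k]*KJ_PER_KCAL:.6f} "
                f"{system.gb_radius[k]/10.0:.6f}\n"
            )
        fh.write("[ bonds ]\n")
        for (i, j), (kb, r0) in zip(system.bonds, system.bond_params):
            fh.write(
                f"{i+1:6d} {j+1:6d} 1 {r0/10.0:.6f} {kb*KJ_PER_KCAL*100.0*2.0:.4f}\n"
            )
        fh.write("[ angles ]\n")
        for (i, j, k), (kt, t0) in zip(system.angles, system.angle_params):
            fh.write(
                f"{i+1:6d} {j+1:6d} {k+1:6d} 1 "
                f"{np.rad2deg(t0):.4f} {kt*KJ_PER_KCAL*2.0:.4f}\n"
            )
        fh.write("[ dihedrals ]\n")
        for (i, j, k, l), (kd, n, ph) in zip(system.torsions, system.torsion_params):
            fh.write(
                f"{i+1:6d} {j+1:6d} {k+1:6d} {l+1:6d} 9 "
                f"{np.rad2deg(ph):.4f} {kd*KJ_PER_KCAL:.4f} {int(n)}\n"
            )
        for (i, j, k, l), (kd, n, ph) in zip(system.impropers, system.improper_params):
            fh.write(
                f"{i+1:6d} {j+1:6d} {k+1:6d} {l+1:6d} 4 "
                f"{np.rad2deg(ph):.4f} {kd*KJ_PER_KCAL:.4f} {int(n)}\n"
            )
        fh.write("[ pairs ]\n")
        for i, j in sorted(system.pairs14):
            fh.write(f"{i+1:6d} {j+1:6d} 1\n")


# ---------------------------------------------------------------------------
# Rotatable dihedral tree
# ---------------------------------------------------------------------------

BACKBONE_NAMES = {"N", "CA", "C"}


def _component(adj, start, banned_edges=(), banned_nodes=()):
    """Connected component containing ``start`` after removing edges/nodes."""
    banned_edges = {frozenset(e) for e in banned_edges}
    banned_nodes = set(banned_nodes)
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v in seen or v in banned_nodes:
                continue
            if frozenset((u, v)) in banned_edges:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def build_rotatable_dihedrals(system: MolecularSystem) -> RotatableDihedralSet:
    """Enumerate rotatable φ/ψ/χ torsions with their downstream atom sets.

    Ring bonds (removal does not disconnect the graph), amide ω bonds, and
    proline φ are never rotatable. The downstream set is the connected
    component on the far side of the axis, excluding the axis atoms, so
    rotating it changes no distance among the remaining atoms.
    """
    adj = system.bond_adjacency()
    n = system.n_atoms
    if n and len(_component(adj, 0)) != n:
        raise InputError("bond graph is disconnected")

    name = [a.strip() for a in system.atom_names]
    rid = system.res_ids
    resmap = system.residue_atom_indices()
    reskeys = system.residue_keys()

    def find_atom(reskey, atom_name):
        for k in resmap.get(reskey, []):
            if name[k] == atom_name:
                return k
        return None

    dihedrals = []
    for bi, bj in system.bonds:
        b, c = int(bi), int(bj)
        if len(adj[b]) < 2 or len(adj[c]) < 2:
            continue  # terminal bond: rotation moves nothing
        comp_c = _component(adj, c, banned_edges=[(b, c)])
        if b in comp_c:
            continue  # ring bond: not rotatable

        nb, nc = name[b], name[c]
        rb, rc = int(rid[b]), int(rid[c])
        # amide ω (C-N between consecutive residues): never rotatable
        if {nb, nc} == {"C", "N"} and rb != rc:
            continue

        kind = None
        if {nb, nc} == {"N", "CA"} and rb == rc:
            kind = "phi"
            if system.res_names[b].strip() == "PRO":
                continue
            # orient axis N -> CA
            if nb != "N":
                b, c = c, b
        elif {nb, nc} == {"CA", "C"} and rb == rc:
            kind = "psi"
            if nb != "CA":
                b, c = c, b
        else:
            kind = "chi"
            # orient so that the backbone-attached atom is b
            if nc in BACKBONE_NAMES and nb not in BACKBONE_NAMES:
                b, c = c, b

        reskey_b = (system.chain_ids[b], int(rid[b]))
        pos = reskeys.index(reskey_b)
        if kind == "phi":
            if pos == 0:
                continue  # no preceding C: φ undefined at N-terminus
            a = find_atom(reskeys[pos - 1], "C")
            d = find_atom(reskey_b, "C")
            if a is None or d is None:
                continue
        elif kind == "psi":
            if pos == len(reskeys) - 1:
                continue  # no following N: ψ undefined at C-terminus
            a = find_atom(reskey_b, "N")
            d = find_atom(reskeys[pos + 1], "N")
            if a is None or d is None:
                continue
        else:
            cand_a = sorted(adj[b] - {c})
            cand_d = sorted(adj[c] - {b})
            if not cand_a or not cand_d:
                continue
            heavy_a = [k for k in cand_a if system.elements[k] != "H"]
            heavy_d = [k for k in cand_d if system.elements[k] != "H"]
            a = (heavy_a or cand_a)[0]
            d = (heavy_d or cand_d)[0]

        comp_c = _component(adj, c, banned_edges=[(b, c)])
        downstream = frozenset(comp_c - {c})
        dihedrals.append(
            RotatableDihedral(atoms=(int(a), int(b), int(c), int(d)),
                              kind=kind, downstream=downstream)
        )

    # deterministic ordering: by axis atom indices
    dihedrals.sort(key=lambda t: (t.atoms[1], t.atoms[2]))
    return RotatableDihedralSet(dihedrals)


# ---------------------------------------------------------------------------
# Synthetic systems
# ---------------------------------------------------------------------------

# per-residue partial charges for the synthetic alanine-like residue; they sum
# to zero exactly so any chain is neutral
_RESIDUE_CHARGES = {
    "N": -0.40, "H": 0.25, "CA": 0.10, "HA": 0.08, "CB": -0.18,
    "HB1": 0.06, "HB2": 0.06, "HB3": 0.06, "C": 0.55, "O": -0.58,
    "H2": 0.0, "OXT": 0.0,
}

_RESIDUE_ATOMS = ["N", "H", "CA", "HA", "CB", "HB1", "HB2", "HB3", "C", "O"]

#: atoms per residue in the synthetic peptide; total = 10·n + 2 (extra
#: N-terminal H2 and C-terminal OXT)
ATOMS_PER_RESIDUE = 10


def generate_fixture_peptide(
    n_residues: int,
    seed: int = 0,
    phi_deg: float = -60.0,
    psi_deg: float = -45.0,
    chi_deg: float = 60.0,
    jitter_deg: float = 6.0,
):
    """Build a synthetic polyalanine-like peptide with hydrogens and a full,
    self-consistent parameter set.

    The chain is grown with ideal internal coordinates in an α-helical
    conformation by default (φ ≈ -60°, ψ ≈ -45°, ω = 180°) with small seeded
    jitter on the torsions. Bond and angle equilibrium values are set to the constructed
    geometry, so the generated structure sits exactly at the minimum of the
    harmonic terms. Charges sum to zero. Atom count is 10·n_residues + 2.

    Returns ``(system, rotatable_dihedral_set)``.
    """
    if n_residues < 1:
        raise InputError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    names, elements, res_ids, res_names = [], [], [], []
    coords = []
    index = {}

    def add(nm, resno, pos):
        index[(resno, nm)] = len(names)
        names.append(nm)
        elements.append(element_from_name(nm))
        res_ids.append(resno)
        res_names.append("ALA")
        coords.append(np.asarray(pos, dtype=float))

    # virtual previous-residue frame for uniform placement of residue 1
    vN = np.array([-3.30, 0.20, 0.0])
    vCA = np.array([-2.40, 0.90, 0.0])
    vC = np.array([-1.329, 0.0, 0.0])

    deg = np.deg2rad
    prevN, prevCA, prevC = vN, vCA, vC
    psi_prev = deg(psi_deg)
    for i in range(1, n_residues + 1):
        phi = deg(phi_deg + rng.normal(0.0, jitter_deg))
        psi = deg(psi_deg + rng.normal(0.0, jitter_deg))
        chi = deg(chi_deg + rng.normal(0.0, jitter_deg))

        N = nerf_place(prevN, prevCA, prevC, 1.329, deg(116.6), psi_prev)
        CA = nerf_place(prevCA, prevC, N, 1.458, deg(121.7), deg(180.0))
        # residue 1 has two amide hydrogens flanking CA; later residues one
        H = nerf_place(prevCA, prevC, N, 1.010, deg(119.0),
                       deg(60.0) if i == 1 else deg(0.0))
        C = nerf_place(prevC, N, CA, 1.525, deg(110.5), phi)
        HA = nerf_place(prevC, N, CA, 1.090, deg(108.5), phi - deg(120.0))
        CB = nerf_place(prevC, N, CA, 1.526, deg(110.4), phi + deg(120.0))
        O = nerf_place(N, CA, C, 1.229, deg(120.9), psi + deg(180.0))
        HBs = [
            nerf_place(N, CA, CB, 1.090, deg(110.0), chi + deg(off))
            for off in (0.0, 120.0, 240.0)
        ]

        add("N", i, N)
        add("H", i, H)
        if i == 1:
            H2 = nerf_place(prevCA, prevC, N, 1.010, deg(119.0), deg(-60.0))
            add("H2", i, H2)
        add("CA", i, CA)
        add("HA", i, HA)
        add("CB", i, CB)
        for k, hb in enumerate(HBs, start=1):
            add(f"HB{k}", i, hb)
        add("C", i, C)
        add("O", i, O)
        if i == n_residues:
            OXT = nerf_place(N, CA, C, 1.249, deg(117.0), psi)
            add("OXT", i, OXT)
        prevN, prevCA, prevC = N, CA, C
        psi_prev = psi

    coords = np.array(coords)
    n_atoms = len(names)

    bonds = []
    for i in range(1, n_residues + 1):
        bonds += [
            (index[(i, "N")], index[(i, "H")]),
            (index[(i, "N")], index[(i, "CA")]),
            (index[(i, "CA")], index[(i, "HA")]),
            (index[(i, "CA")], index[(i, "CB")]),
            (index[(i, "CB")], index[(i, "HB1")]),
            (index[(i, "CB")], index[(i, "HB2")]),
            (index[(i, "CB")], index[(i, "HB3")]),
            (index[(i, "CA")], index[(i, "C")]),
            (index[(i, "C")], index[(i, "O")]),
        ]
        if i > 1:
            bonds.append((index[(i - 1, "C")], index[(i, "N")]))
    bonds.append((index[(1, "N")], index[(1, "H2")]))
    bonds.append((index[(n_residues, "C")], index[(n_residues, "OXT")]))
    bonds = np.array(sorted((min(i, j), max(i, j)) for i, j in bonds), dtype=int)

    # harmonic parameters at the constructed geometry (exact equilibrium)
    bond_params = np.array(
        [
            (300.0, float(np.linalg.norm(coords[i] - coords[j])))
            for i, j in bonds
        ]
    )
    adj: list[set] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    angles = []
    for j in range(n_atoms):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    angles = np.array(angles, dtype=int)
    angle_params = np.array(
        [
            (50.0, bond_angle(coords[i], coords[j], coords[k]))
            for i, j, k in angles
        ]
    )

    torsions, torsion_params = [], []
    for i in range(1, n_residues + 1):
        if i > 1:  # φ and ω
            torsions.append(
                (index[(i - 1, "C")], index[(i, "N")], index[(i, "CA")], index[(i, "C")])
            )
            torsion_params.append((0.4, 3.0, 0.0))
            torsions.append(
                (index[(i - 1, "CA")], index[(i - 1, "C")], index[(i, "N")], index[(i, "CA")])
            )
            torsion_params.append((10.0, 2.0, np.pi))
        if i < n_residues:  # ψ
            torsions.append(
                (index[(i, "N")], index[(i, "CA")], index[(i, "C")], index[(i + 1, "N")])
            )
            torsion_params.append((0.4, 3.0, 0.0))
        torsions.append(
            (index[(i, "N")], index[(i, "CA")], index[(i, "CB")], index[(i, "HB1")])
        )
        torsion_params.append((0.3, 3.0, 0.0))
    torsions = np.array(torsions, dtype=int)
    torsion_params = np.array(torsion_params)

    charges = np.array([_RESIDUE_CHARGES[nm] for nm in names])
    polar_h = {"H", "H2"}  # nitrogen-bound hydrogens
    sigma = np.array(
        [
            DEFAULT_LJ_POLAR_H[0] if nm in polar_h else DEFAULT_LJ[el][0]
            for nm, el in zip(names, elements)
        ]
    )
    eps = np.array([DEFAULT_LJ[el][1] for el in elements])
    gbr = np.array([BONDI_RADII[el] for el in elements])

    system = MolecularSystem(
        atom_names=names,
        elements=elements,
        res_names=res_names,
        res_ids=np.array(res_ids, dtype=int),
        chain_ids=["A"] * n_atoms,
        coords=coords,
        charges=charges,
        lj_sigma=sigma,
        lj_epsilon=eps,
        gb_radius=gbr,
        bonds=bonds,
        bond_params=bond_params,
        angles=angles,
        angle_params=angle_params,
        torsions=torsions,
        torsion_params=torsion_params,
        exclusions=_derive_exclusions(bonds, n_atoms),
        pairs14=derive_pairs14(bonds, n_atoms),
    )
    system.validate()
    return system, build_rotatable_dihedrals(system)


def make_single_dihedral_system(k: float = 1.0, n: float = 1.0, phase: float = 0.0):
    """Four-atom chain whose only non-constant energy term is one torsion
    V(φ) = k (1 + cos(nφ - phase)).

    Charges and LJ ε are zero, so the Boltzmann distribution of φ is known in
    closed form — the canonical correctness oracle for the sampler.
    Returns ``(system, rotatable_dihedral_set)``.
    """
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.25, 1.3, 0.0],
            [3.75, 1.3, 0.3],
        ]
    )
    bonds = np.array([[0, 1], [1, 2], [2, 3]], dtype=int)
    bond_params = np.array(
        [(300.0, float(np.linalg.norm(coords[i] - coords[j]))) for i, j in bonds]
    )
    angles = np.array([[0, 1, 2], [1, 2, 3]], dtype=int)
    angle_params = np.array(
        [(50.0, bond_angle(coords[i], coords[j], coords[k])) for i, j, k in angles]
    )
    system = MolecularSystem(
        atom_names=["C1", "C2", "C3", "C4"],
        elements=["C"] * 4,
        res_names=["TOY"] * 4,
        res_ids=np.array([1, 1, 1, 1]),
        chain_ids=["A"] * 4,
        coords=coords,
        charges=np.zeros(4),
        lj_sigma=np.full(4, 3.4),
        lj_epsilon=np.zeros(4),
        gb_radius=np.full(4, 1.7),
        bonds=bonds,
        bond_params=bond_params,
        angles=angles,
        angle_params=angle_params,
        torsions=np.array([[0, 1, 2, 3]], dtype=int),
        torsion_params=np.array([[k, n, phase]]),
        exclusions=_derive_exclusions(bonds, 4),
        pairs14=derive_pairs14(bonds, 4),
    )
    system.validate()
    dih = RotatableDihedral(atoms=(0, 1, 2, 3), kind="chi", downstream=frozenset({3}))
    return system, RotatableDihedralSet([dih])


# ---------------------------------------------------------------------------
# Serialization (CLI bundles)
# ---------------------------------------------------------------------------


def system_to_dict(system: MolecularSystem) -> dict:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    return {
        "atom_names": system.atom_names,
        "elements": system.elements,
        "res_names": system.res_names,
        "res_ids": arr(system.res_ids),
        "chain_ids": system.chain_ids,
        "coords": arr(system.coords),
        "charges": arr(system.charges),
        "lj_sigma": arr(system.lj_sigma),
        "lj_epsilon": arr(system.lj_epsilon),
        "gb_radius": arr(system.gb_radius),
        "bonds": arr(system.bonds),
        "bond_params": arr(system.bond_params),
        "angles": arr(system.angles),
        "angle_params": arr(system.angle_params),
        "torsions": arr(system.torsions),
        "torsion_params": arr(system.torsion_params),
        "impropers": arr(system.impropers),
        "improper_params": arr(system.improper_params),
        "exclusions": sorted(map(list, system.exclusions)),
        "pairs14": sorted(map(list, system.pairs14)),
    }


def system_from_dict(d: dict) -> MolecularSystem:
    def arr(x, dtype=float, shape=None):
        a = np.asarray(x, dtype=dtype) if x is not None else None
        if a is not None and shape is not None and a.size == 0:
            a = a.reshape(shape)
        return a

    sys_ = MolecularSystem(
        atom_names=list(d["atom_names"]),
        elements=list(d["elements"]),
        res_names=list(d["res_names"]),
        res_ids=arr(d["res_ids"], int),
        chain_ids=list(d["chain_ids"]),
        coords=arr(d["coords"]),
        charges=arr(d["charges"]),
        lj_sigma=arr(d["lj_sigma"]),
        lj_epsilon=arr(d["lj_epsilon"]),
        gb_radius=arr(d["gb_radius"]),
        bonds=arr(d["bonds"], int, (0, 2)),
        bond_params=arr(d["bond_params"], float, (0, 2)),
        angles=arr(d["angles"], int, (0, 3)),
        angle_params=arr(d["angle_params"], float, (0, 2)),
        torsions=arr(d["torsions"], int, (0, 4)),
        torsion_params=arr(d["torsion_params"], float, (0, 3)),
        impropers=arr(d["impropers"], int, (0, 4)),
        improper_params=arr(d["improper_params"], float, (0, 3)),
        exclusions={tuple(p) for p in d["exclusions"]},
        pairs14={tuple(p) for p in d["pairs14"]},
    )
    sys_.validate()
    return sys_


def system_checksum(system: MolecularSystem) -> str:
    blob = json.dumps(system_to_dict(system), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
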