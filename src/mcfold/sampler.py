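"""Metropolis Monte Carlo driver: propose, score, accept/reject, record.

Each step draws one move (dihedral / concerted / rigid per the configured
weights), scores the proposal with the full potential (optionally plus a
harmonic wall in Q), and applies the Metropolis criterion
accept with probability min(1, exp(-ΔE / k_B T)). All proposal kernels are
symmetric, so this samples the Boltzmann distribution. Energies are fully
recomputed for every proposal — correct by construction, since the GB and
SASA terms are global and make incremental locality unsafe.

A rejected step restores the previous state exactly (bit-level): the proposal
never mutates the current coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import NativeContactSet, compute_q
from .energy import EnergyBreakdown, SolventModelParams, total_energy
from .errors import ConfigError, InputError
from .model_io import build_rotatable_dihedrals
from .moves import (
    MOVE_KINDS,
    concerted_move,
    dihedral_move,
    rigid_rotation_move,
    select_move,
)

__all__ = [
    "MCConfig",
    "QRestraint",
    "Trajectory",
    "metropolis_accept",
    "q_restraint_energy",
    "mc_step",
    "run_simulation",
    "temperature_series",
]


def metropolis_accept(delta_E: float, T: float, rng: np.random.Generator,
                      params: SolventModelParams | None = None) -> bool:
    """Accept with probability min(1, exp(-ΔE/(k_B T))); ΔE ≤ 0 always."""
    if T <= 0:
        raise ConfigError("temperature must be > 0")
    if delta_E <= 0.0:
        return True
    k_B = params.k_B if params is not None else 1.9872041e-3
    return rng.random() < math.exp(-delta_E / (k_B * T))


def q_restraint_energy(Q: float, Q0: float, k_Q: float) -> float:
    """One-sided harmonic wall in Q: 0 for Q ≥ Q0, k_Q (Q0 - Q)² below.

    Continuous with continuous first derivative at the wall; used to keep
    simulations out of regions they cannot escape on the available budget
    (e.g. fully melted β-sheets)."""
    if Q >= Q0:
        return 0.0
    return k_Q * (Q0 - Q) ** 2


@dataclass
class QRestraint:
    """Repulsive wall in Q bound to a native contact set."""

    contacts: NativeContactSet
    Q0: float = 0.4
    k_Q: float = 100.0  # kcal/mol per unit Q²

    def energy(self, coords) -> float:
        return q_restraint_energy(compute_q(coords, self.contacts), self.Q0, self.k_Q)


@dataclass
class MCConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    temperature: float = 300.0  # K
    n_steps: int = 10_000
    seed: int = 0
    move_weights: tuple = (0.45, 0.45, 0.10)  # dihedral / concerted / rigid
    dihedral_width_deg: float = 20.0
    concerted_width_deg: float = 20.0
    rigid_max_deg: float = 5.0
    concerted_window: int = 4
    record_stride: int = 100
    equilibration_fraction: float = 0.10
    record_coords: bool = False
    q_restraint_enabled: bool = False
    q0: float = 0.4
    k_q: float = 100.0
    native_contacts: NativeContactSet | None = None

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ConfigError("equilibration_fraction must be in [0, 1)")
        if self.record_stride < 1:
            raise ConfigError("record_stride must be >= 1")
        w = np.asarray(self.move_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
            raise ConfigError("move_weights must be 3 nonnegative numbers, sum > 0")
        if self.q_restraint_enabled and self.native_contacts is None:
            raise ConfigError("Q restraint enabled but no native contacts given")


@dataclass
class SamplerState:
    coords: np.ndarray
    energy: EnergyBreakdown
    q: float = float("nan")
    proposed: dict = field(default_factory=lambda: {k: 0 for k in MOVE_KINDS})
    accepted: dict = field(default_factory=lambda: {k: 0 for k in MOVE_KINDS})

    @property
    def n_proposed(self) -> int:
        return sum(self.proposed.values())

    @property
    def n_accepted(self) -> int:
        return sum(self.accepted.values())

    @property
    def acceptance_ratio(self) -> float:
        n = self.n_proposed
        return self.n_accepted / n if n else float("nan")


@dataclass
class Trajectory:
    """Recorded samples plus acceptance bookkeeping and the config echo."""

    records: pd.DataFrame  # step, per-term energies, Q, equilibration flag
    proposed: dict
    accepted: dict
    config: MCConfig
    coords_frames: list = field(default_factory=list)  # optional snapshots
    record_steps: list = field(default_factory=list)

    @property
    def acceptance_ratio(self) -> float:
        n = sum(self.proposed.values())
        return sum(self.accepted.values()) / n if n else float("nan")

    def production(self) -> pd.DataFrame:
        """Records after the equilibration discard."""
        return self.records[~self.records["equilibration"]]

    def summary(self) -> dict:
        prod = self.production()
        return {
            "temperature": self.config.temperature,
            "mean_E_total": float(prod["E_total"].mean()),
            "var_E_total": float(prod["E_total"].var(ddof=0)),
            "acceptance_ratio": self.acceptance_ratio,
            "n_records": int(len(self.records)),
        }


def _propose(system, dihedrals, coords, cfg: MCConfig, rng):
    kind = select_move(rng, cfg.move_weights)
    if kind == "dihedral":
        return dihedral_move(system, dihedrals, coords, rng, cfg.dihedral_width_deg)
    if kind == "concerted":
        return concerted_move(
            system, coords, rng, cfg.concerted_window, cfg.concerted_width_deg
        )
    return rigid_rotation_move(coords, rng, cfg.rigid_max_deg)


def mc_step(
    state: SamplerState,
    system,
    config: MCConfig,
    rng: np.random.Generator,
    dihedrals=None,
    params: SolventModelParams | None = None,
    restraint: QRestraint | None = None,
) -> SamplerState:
    """One Metropolis step, mutating and returning ``state``.

    On rejection the coordinates and energy are left untouched (the proposal
    works on a copy), so a rejected step changes nothing observable."""
    if params is None:
        params = SolventModelParams()
    if dihedrals is None:
        dihedrals = build_rotatable_dihedrals(system)
    prop = _propose(system, dihedrals, state.coords, config, rng)
    new_energy = total_energy(system, prop.coords, params, restraint=restraint)
    delta = new_energy.E_total - state.energy.E_total
    state.proposed[prop.kind] += 1
    if metropolis_accept(delta, config.temperature, rng, params):
        state.accepted[prop.kind] += 1
        state.coords = prop.coords
        state.energy = new_energy
    return state


def run_simulation(
    system,
    config: MCConfig,
    params: SolventModelParams | None = None,
    dihedrals=None,
) -> Trajectory:
    """Run ``config.n_steps`` Metropolis steps from the system's coordinates.

    Samples are recorded every ``record_stride`` steps; the first
    ``equilibration_fraction`` of the records is flagged (kept in the raw
    output, excluded from ensemble statistics by ``Trajectory.production``).
    Fully reproducible from (seed, config, inputs).
    """
    config.validate()
    if params is None:
        params = SolventModelParams()
    if dihedrals is None:
        dihedrals = build_rotatable_dihedrals(system)
    rng = np.random.default_rng(config.seed)
    restraint = None
    if config.q_restraint_enabled:
        restraint = QRestraint(config.native_contacts, config.q0, config.k_q)

    coords = system.coords.copy()
    state = SamplerState(
        coords=coords,
        energy=total_energy(system, coords, params, restraint=restraint),
    )
    track_q = config.native_contacts is not None

    rows = []
    steps = []
    frames = []

    def record(step):
        q = compute_q(state.coords, config.native_contacts) if track_q else float("nan")
        state.q = q
        row = state.energy.as_dict()
        row["step"] = step
        row["Q"] = q
        row["acceptance_ratio"] = state.acceptance_ratio
        rows.append(row)
        steps.append(step)
        if config.record_coords:
            frames.append(state.coords.copy())

    for step in range(1, config.n_steps + 1):
        mc_step(state, system, config, rng, dihedrals, params, restraint)
        if step % config.record_stride == 0:
            record(step)

    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["step", "E_total", "Q", "acceptance_ratio"]
    )
    n_eq = int(np.ceil(config.equilibration_fraction * len(df)))
    df["equilibration"] = np.arange(len(df)) < n_eq
    return Trajectory(
        records=df,
        proposed=dict(state.proposed),
        accepted=dict(state.accepted),
        config=config,
        coords_frames=frames,
        record_steps=steps,
    )


def temperature_series(
    system,
    temperatures,
    config: MCConfig,
    params: SolventModelParams | None = None,
) -> list:
    """Independent seeded runs, one per temperature (seed = base seed + index).

    Returns the list of trajectories; per-temperature summaries for Cv and
    PMF analysis come from ``Trajectory.summary`` / ``Trajectory.production``.
    """
    temperatures = list(temperatures)
    if not temperatures:
        raise ConfigError("temperature list must be nonempty")
    out = []
    for k, T in enumerate(temperatures):
        cfg = replace(config, temperature=float(T), seed=config.seed + k)
        out.append(run_simulation(system, cfg, params))
    return out
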