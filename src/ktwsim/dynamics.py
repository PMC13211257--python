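"""Stochastic per-step update and the simulation run loop.

Each step applies, in order:

1. **Mortality** — every occupied cell is independently vacated with
   probability ``mortality_prob``.  Death frees space; without it a
   full lattice freezes and neither collapse nor surveillance-maintained
   diversity can manifest.
2. **Replication** — surviving cells are visited in a uniformly random
   order; each replicates with its species' ``replication_prob`` into
   one empty neighbor chosen uniformly.  The sequential order resolves
   conflicts over shared empty sites; cells born this step do not
   replicate until the next step, so per-step growth is bounded by the
   current population.
3. **Surveillance** (when the schedule is active) — the two-threshold
   trigger is evaluated once, and at most one penalization event fires.

Abundances, Hill numbers and the fired flag are recorded *after* the
surveillance check, so penalization effects are visible in the same
step's record.  All randomness flows from one master seed expanded into
named substreams (init, mortality, replication order, replication
target, penalization sampling), so adding draws to one phase never
shifts another phase's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernel import replication_pass
from .config import RunConfig
from .diversity import hill_profile
from .hexlattice import (
    HexLattice,
    SpeciesParams,
    count_abundances,
    initialize,
    neighbor_table,
    validate_roster,
)
from .surveillance import (
    SurveillanceRule,
    is_active,
    penalize,
    penalize_community,
    trigger,
)

_STREAM_NAMES = (
    "init",
    "mortality",
    "replication_order",
    "replication_target",
    "penalization",
)


@dataclass
class RngStreams:
    """Named independent substreams derived from one master seed."""

    init: np.random.Generator
    mortality: np.random.Generator
    replication_order: np.random.Generator
    replication_target: np.random.Generator
    penalization: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "RngStreams":
        children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
        return cls(
            **{
                name: np.random.default_rng(child)
                for name, child in zip(_STREAM_NAMES, children)
            }
        )


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the stochastic update."""

    species: list[SpeciesParams]
    mortality_prob: float = 0.05
    n_steps: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality_prob < 1.0:
            raise ValueError(
                f"mortality_prob must be in [0, 1), got {self.mortality_prob}"
            )
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        validate_roster(self.species)

    @property
    def replication_probs(self) -> np.ndarray:
        probs = np.empty(len(self.species))
        for sp in self.species:
            probs[sp.species_id - 1] = sp.replication_prob
        return probs


@dataclass
class RunResult:
    """Trajectory table, final lattice state, and the resolved config."""

    trajectory: pd.DataFrame
    final_lattice: HexLattice
    config: RunConfig
    n_penalizations: int = field(default=0)


def step(
    lattice: HexLattice,
    params: DynamicsParams,
    streams: RngStreams,
    nbr: np.ndarray | None = None,
) -> HexLattice:
    """One mortality + replication update; returns a new lattice.

    ``nbr`` is the precomputed neighbor table; pass it in loops to avoid
    rebuilding it every step.
    """
    if nbr is None:
        nbr = neighbor_table(lattice)
    occ = lattice.occ.copy()

    occupied = np.flatnonzero(occ)
    if params.mortality_prob > 0.0 and occupied.size > 0:
        dies = streams.mortality.random(occupied.size) < params.mortality_prob
        occ[occupied[dies]] = 0
        survivors = occupied[~dies]
    else:
        survivors = occupied

    if survivors.size > 0:
        order = streams.replication_order.permutation(survivors)
        u_repl = streams.replication_target.random(order.size)
        u_choice = streams.replication_target.random(order.size)
        replication_pass(
            occ, nbr, params.replication_probs, order, u_repl, u_choice
        )
    return HexLattice(lattice.width, lattice.height, occ)


def run(
    config: RunConfig, initial_lattice: HexLattice | None = None
) -> RunResult:
    """Run the full simulation loop and record one row per completed step.

    Each of the ``n_steps`` iterations performs the stochastic update,
    then the surveillance check (per the schedule), then records species
    counts, total occupancy, Hill numbers at q = 0, 1, 2 and whether a
    penalization event fired.  Fully reproducible from config + seed.
    """
    params = DynamicsParams(
        species=config.species,
        mortality_prob=config.mortality_prob,
        n_steps=config.n_steps,
        rng_seed=config.seed,
    )
    streams = RngStreams.from_seed(config.seed)
    if initial_lattice is not None:
        lattice = initial_lattice.copy()
    else:
        lattice = initialize(
            config.species,
            width=config.width,
            height=config.height,
            fraction=config.initial_occupancy,
            rng=streams.init,
        )
    nbr = neighbor_table(lattice)
    n = config.n_species

    records: list[dict] = []
    n_events = 0
    for t in range(config.n_steps):
        lattice = step(lattice, params, streams, nbr)
        fired = False
        if is_active(config.schedule, t):
            ab = count_abundances(lattice, n)
            target = trigger(ab, config.rule)
            if target is not None:
                if config.rule.target_policy == "whole_community":
                    lattice = penalize_community(
                        lattice, config.rule, streams.penalization
                    )
                else:
                    lattice = penalize(
                        lattice, target, config.rule, streams.penalization
                    )
                fired = True
                n_events += 1
        ab = count_abundances(lattice, n)
        assert ab.n_occupied == lattice.n_occupied  # conservation
        d0, d1, d2 = hill_profile(ab)
        row: dict = {"step": t}
        for i in range(n):
            row[f"count_{i + 1}"] = int(ab.counts[i])
        row.update(
            total=ab.n_occupied,
            hill_q0=d0,
            hill_q1=d1,
            hill_q2=d2,
            penalized=fired,
        )
        records.append(row)

    trajectory = pd.DataFrame.from_records(records)
    return RunResult(
        trajectory=trajectory,
        final_lattice=lattice,
        config=config,
        n_penalizations=n_events,
    )
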