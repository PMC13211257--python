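"""Constructed lattice states with prescribed occupancy and dominance.

Operator-level tests (and the ``fixture`` CLI subcommand) need lattice
states sitting at known positions relative to the surveillance
thresholds.  :func:`make_fixture` builds one: total occupancy and the
dominant species' share match the request to within one cell, with the
remaining cells split evenly among the other species and all cells
placed uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hexlattice import HexLattice


@dataclass(frozen=True)
class FixtureSpec:
    """Requested occupancy fraction, dominant species and share."""

    occupancy: float
    dominant_share: float
    width: int = 20
    height: int = 20
    n_species: int = 4
    dominant_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy fraction must be in (0, 1], got {self.occupancy}"
            )
        if not 0.0 < self.dominant_share <= 1.0:
            raise ValueError(
                f"dominant_share must be in (0, 1], got {self.dominant_share}"
            )
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if not 1 <= self.dominant_id <= self.n_species:
            raise ValueError(
                f"dominant_id {self.dominant_id} outside 1..{self.n_species}"
            )


def make_fixture(spec: FixtureSpec) -> HexLattice:
    """Build a lattice matching ``spec`` to within +/-1 cell; deterministic."""
    lattice = HexLattice.empty(spec.width, spec.height)
    n_occ = int(np.floor(spec.occupancy * lattice.n_sites + 0.5))
    if n_occ > lattice.n_sites or n_occ < 1:
        raise ValueError(
            f"infeasible occupancy: {n_occ} cells on {lattice.n_sites} sites"
        )
    n_dom = int(np.floor(spec.dominant_share * n_occ + 0.5))
    n_rest = n_occ - n_dom
    others = [i for i in range(1, spec.n_species + 1) if i != spec.dominant_id]
    if n_rest > 0 and not others:
        raise ValueError(
            "infeasible: dominant_share < 1 requires more than one species"
        )

    rng = np.random.default_rng(spec.seed)
    sites = rng.choice(lattice.n_sites, size=n_occ, replace=False)
    lattice.occ[sites[:n_dom]] = spec.dominant_id
    if others and n_rest:
        base, extra = divmod(n_rest, len(others))
        start = n_dom
        for i, sp in enumerate(others):
            count = base + (1 if i < extra else 0)
            lattice.occ[sites[start : start + count]] = sp
            start += count
    return lattice
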