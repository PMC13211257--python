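"""Hexagonal-lattice geometry and community state.

Sites live on a ``width x height`` rhombus addressed by axial coordinates
``(col, row)`` with toroidal (wrap-around) boundaries, so every site is
statistically equivalent and has exactly six neighbors.  A site holds at
most one cell; occupancy is stored as a flat integer array where ``0``
marks an empty site and values ``1..n`` are species ids.

The six axial neighbor offsets are fixed (east, west, south-east,
north-west, north-east, south-west) so that snapshots written by one
version of the package remain portable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Empty-site marker in occupancy arrays.
EMPTY = 0

#: The six axial-coordinate neighbor offsets (dcol, drow).
AXIAL_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0),   # east
    (-1, 0),  # west
    (0, 1),   # south-east
    (0, -1),  # north-west
    (1, -1),  # north-east
    (-1, 1),  # south-west
)

MIN_DIM = 3  # below this, wrap-around creates duplicate neighbors


@dataclass(frozen=True)
class SpeciesParams:
    """Identity and per-step replication probability of one species.

    Parameters
    ----------
    species_id
        Integer label in ``1..n``; ``0`` is reserved for empty sites.
    replication_prob
        Probability per step that a cell of this species replicates into
        one empty neighboring site, in ``[0, 1]``.
    """

    species_id: int
    replication_prob: float

    def __post_init__(self) -> None:
        if self.species_id < 1:
            raise ValueError(f"species_id must be >= 1, got {self.species_id}")
        if not 0.0 <= self.replication_prob <= 1.0:
            raise ValueError(
                f"replication_prob must be in [0, 1], got {self.replication_prob}"
            )


def validate_roster(species: list[SpeciesParams]) -> None:
    """Check that species ids are unique and contiguous from 1."""
    ids = sorted(s.species_id for s in species)
    if ids != list(range(1, len(species) + 1)):
        raise ValueError(f"species ids must be contiguous from 1, got {ids}")


@dataclass
class HexLattice:
    """Spatial community state on a toroidal hexagonal lattice.

    ``occ`` is a flat array of length ``width * height``; the site with
    axial coordinates ``(col, row)`` has index ``row * width + col``.
    """

    width: int
    height: int
    occ: np.ndarray

    def __post_init__(self) -> None:
        if self.width < MIN_DIM or self.height < MIN_DIM:
            raise ValueError(
                f"lattice must be at least {MIN_DIM}x{MIN_DIM} "
                f"(wrap-around duplicates neighbors below that), "
                f"got {self.width}x{self.height}"
            )
        self.occ = np.asarray(self.occ, dtype=np.int16).ravel()
        if self.occ.size != self.width * self.height:
            raise ValueError(
                f"occupancy array has {self.occ.size} entries, "
                f"expected {self.width * self.height}"
            )
        if (self.occ < 0).any():
            raise ValueError("occupancy values must be >= 0")

    @classmethod
    def empty(cls, width: int, height: int) -> "HexLattice":
        return cls(width, height, np.zeros(width * height, dtype=np.int16))

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occ))

    def site_index(self, col: int, row: int) -> int:
        return (row % self.height) * self.width + (col % self.width)

    def site_coords(self, site: int) -> tuple[int, int]:
        return site % self.width, site // self.width

    def copy(self) -> "HexLattice":
        return HexLattice(self.width, self.height, self.occ.copy())


@dataclass(frozen=True)
class AbundanceVector:
    """Per-species cell counts on a lattice of ``total_sites`` sites."""

    counts: np.ndarray  # length n_species, counts[i] is species i+1
    total_sites: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64)
        )
        if self.total_sites < 1:
            raise ValueError("total_sites must be positive")
        if self.counts.sum() > self.total_sites:
            raise ValueError("sum of counts exceeds total_sites")

    @property
    def n_occupied(self) -> int:
        return int(self.counts.sum())

    @property
    def load(self) -> float:
        """Occupied fraction of all lattice sites."""
        return self.n_occupied / self.total_sites

    def relative(self) -> np.ndarray:
        """Relative abundances p_i among occupied sites (zeros if empty)."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def dominant(self) -> tuple[int, float]:
        """Species id with maximal share (ties -> lowest id) and its share."""
        rel = self.relative()
        i = int(np.argmax(rel))  # argmax returns the first = lowest id
        return i + 1, float(rel[i])


def neighbors(site: int, lattice: HexLattice) -> np.ndarray:
    """The six distinct neighbor site indices of ``site`` under wrap-around.

    Raises ``IndexError`` for an out-of-range site index.
    """
    if not 0 <= site < lattice.n_sites:
        raise IndexError(
            f"site {site} out of range for lattice with {lattice.n_sites} sites"
        )
    col, row = lattice.site_coords(site)
    return np.array(
        [lattice.site_index(col + dc, row + dr) for dc, dr in AXIAL_OFFSETS],
        dtype=np.int64,
    )


def neighbor_table(lattice: HexLattice) -> np.ndarray:
    """Precomputed ``(n_sites, 6)`` neighbor index table (vectorized)."""
    w, h = lattice.width, lattice.height
    sites = np.arange(w * h, dtype=np.int64)
    col = sites % w
    row = sites // w
    table = np.empty((w * h, 6), dtype=np.int64)
    for j, (dc, dr) in enumerate(AXIAL_OFFSETS):
        table[:, j] = ((row + dr) % h) * w + (col + dc) % w
    return table


def initialize(
    species: list[SpeciesParams],
    width: int = 60,
    height: int = 60,
    fraction: float = 0.10,
    rng: np.random.Generator | int | None = None,
) -> HexLattice:
    """Seed a lattice with equal per-species abundances at random sites.

    ``round(fraction * n_sites)`` sites are drawn uniformly without
    replacement and divided equally among the species (within +/-1 cell
    when the total does not divide evenly; the remainder goes to the
    lowest species ids).  Deterministic given the generator state.
    """
    if not species:
        raise ValueError("need at least one species")
    validate_roster(species)
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"initial occupancy fraction must be in (0, 1], got {fraction}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    lattice = HexLattice.empty(width, height)
    n_occ = int(np.floor(fraction * lattice.n_sites + 0.5))
    if n_occ > lattice.n_sites:
        raise ValueError("requested occupancy exceeds lattice size")

    n = len(species)
    base, extra = divmod(n_occ, n)
    per_species = [base + (1 if i < extra else 0) for i in range(n)]

    sites = rng.choice(lattice.n_sites, size=n_occ, replace=False)
    start = 0
    for sp, count in zip(sorted(species, key=lambda s: s.species_id), per_species):
        lattice.occ[sites[start : start + count]] = sp.species_id
        start += count
    return lattice


def count_abundances(lattice: HexLattice, n_species: int) -> AbundanceVector:
    """Per-species cell counts; ``counts[i]`` is the count of species ``i+1``."""
    counts = np.bincount(lattice.occ, minlength=n_species + 1)[1 : n_species + 1]
    return AbundanceVector(counts=counts, total_sites=lattice.n_sites)
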