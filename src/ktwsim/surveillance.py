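"""The immune penalization rule: two-threshold trigger and fractional cull.

Surveillance fires when *both* thresholds are strictly exceeded in the
same step: total community load (occupied fraction of all lattice
sites) above ``load_threshold``, and the single largest relative
abundance (share of occupied sites) above ``dominance_threshold``.
When it fires, a fixed fraction of the dominant taxon's cells is
removed — the kill-the-winner rule.  "Exceeded" is read strictly, so a
community sitting exactly on a threshold is not penalized.

Activation in time is governed by a :class:`Schedule`: always on, off,
or restricted to half-open step windows ``[start, end)`` (so a window
written ``200-400`` is active at steps 200..399).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexlattice import AbundanceVector, HexLattice

TARGET_POLICIES = ("dominant_taxon", "whole_community")
SCHEDULE_MODES = ("off", "always", "windows")


@dataclass(frozen=True)
class SurveillanceRule:
    """Thresholds, removal fraction and targeting policy of the rule.

    Defaults are the reference parameterization: load 0.70, dominance
    0.30, removal 0.80, targeting the dominant taxon only.  The
    ``whole_community`` policy (remove the fraction from all occupied
    cells indiscriminately) is retained for sensitivity analysis.
    """

    load_threshold: float = 0.70
    dominance_threshold: float = 0.30
    removal_fraction: float = 0.80
    target_policy: str = "dominant_taxon"

    def __post_init__(self) -> None:
        for name in ("load_threshold", "dominance_threshold", "removal_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.target_policy not in TARGET_POLICIES:
            raise ValueError(
                f"target_policy must be one of {TARGET_POLICIES}, "
                f"got {self.target_policy!r}"
            )


@dataclass(frozen=True)
class Schedule:
    """Step intervals during which surveillance is active.

    ``windows`` are half-open ``[start, end)`` intervals in 0-based step
    indices; they must be sorted, non-overlapping, and non-empty.
    """

    mode: str = "always"
    windows: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in SCHEDULE_MODES:
            raise ValueError(
                f"schedule mode must be one of {SCHEDULE_MODES}, got {self.mode!r}"
            )
        windows = tuple(tuple(int(x) for x in w) for w in self.windows)
        object.__setattr__(self, "windows", windows)
        if self.mode == "windows" and not windows:
            raise ValueError("mode 'windows' requires at least one window")
        prev_end = None
        for start, end in windows:
            if start < 0 or end <= start:
                raise ValueError(f"window [{start}, {end}) is empty or negative")
            if prev_end is not None and start < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = end


def is_active(schedule: Schedule, step: int) -> bool:
    """Whether surveillance is active at 0-based step index ``step``."""
    if step < 0:
        raise ValueError(f"step must be >= 0, got {step}")
    if schedule.mode == "off":
        return False
    if schedule.mode == "always":
        return True
    return any(start <= step < end for start, end in schedule.windows)


def trigger(abundances: AbundanceVector, rule: SurveillanceRule) -> int | None:
    """Evaluate the two-threshold trigger.

    Returns the dominant species id (ties broken by lowest id) when
    both the load and dominance thresholds are strictly exceeded, else
    ``None``.
    """
    if abundances.n_occupied == 0:
        return None
    if abundances.load <= rule.load_threshold:
        return None
    dominant_id, share = abundances.dominant()
    if share <= rule.dominance_threshold:
        return None
    return dominant_id


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def penalize(
    lattice: HexLattice,
    target: int,
    rule: SurveillanceRule,
    rng: np.random.Generator,
) -> HexLattice:
    """Remove ``round(removal_fraction * count)`` cells of the target taxon.

    Cells are sampled uniformly without replacement; all other species
    are untouched.  Raises ``ValueError`` if the target is absent (the
    trigger contract should prevent that).
    """
    cells = np.flatnonzero(lattice.occ == target)
    if cells.size == 0:
        raise ValueError(f"target species {target} has no cells on the lattice")
    n_remove = _round_half_away(rule.removal_fraction * cells.size)
    out = lattice.copy()
    if n_remove > 0:
        removed = rng.choice(cells, size=n_remove, replace=False)
        out.occ[removed] = 0
    return out


def penalize_community(
    lattice: HexLattice, rule: SurveillanceRule, rng: np.random.Generator
) -> HexLattice:
    """Alternative policy: cull the fraction from all occupied cells."""
    cells = np.flatnonzero(lattice.occ)
    if cells.size == 0:
        raise ValueError("lattice is empty")
    n_remove = _round_half_away(rule.removal_fraction * cells.size)
    out = lattice.copy()
    if n_remove > 0:
        removed = rng.choice(cells, size=n_remove, replace=False)
        out.occ[removed] = 0
    return out
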