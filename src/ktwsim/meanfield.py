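"""Deterministic mean-field counterpart of the lattice model.

Tracks real-valued abundances ``x_i`` of ``n`` taxa under shared
logistic competition with mortality, updated by a discrete-time Euler
map with step size 1 (matching the lattice's step semantics)::

    x_i <- max(0, x_i + x_i * (r_i * (1 - S / K) - m)),   S = sum_j x_j

followed by the same two-threshold suppression rule as the lattice: if
``S / K`` exceeds the load threshold and the largest share ``x_i / S``
exceeds the dominance threshold, the dominant taxon is multiplied by
``(1 - removal_fraction)``.  The discrete map makes the instantaneous
cull natural, which would be awkward inside an ODE integrator.

Mortality ``m > 0`` is essential: with ``m = 0`` the shared-logistic
equilibrium is neutral (any composition with ``S = K`` is stationary)
and true competitive exclusion never completes.  With ``m > 0`` and
suppression off the taxon with maximal ``r`` excludes all others and
settles at the closed-form equilibrium ``S* = K * (1 - m / r_max)``;
every other taxon then has per-step growth ``r_i (1 - S*/K) - m < 0``
and decays to extinction.  With suppression on, every approach to
dominance is culled and all ``n`` taxa coexist — the deterministic twin
of the lattice collapse/maintenance dichotomy.

Because multiplicative decay never reaches exact zero in floating
point, survivors are counted with an extinction tolerance of
``1e-6 * K``; recorded Hill numbers apply the same tolerance so
richness reflects effectively surviving taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import hill_number
from .surveillance import Schedule, SurveillanceRule, is_active

EXTINCTION_TOL_FACTOR = 1e-6


@dataclass(frozen=True)
class MeanFieldParams:
    """Parameters of the deterministic n-taxon map.

    ``growth_rates`` r_i are per-step intrinsic rates; ``capacity`` K
    sets the abundance scale the load threshold is read against;
    ``mortality`` m must be below every r_i or the corresponding taxon
    cannot persist even alone.
    """

    growth_rates: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    capacity: float = 1000.0
    mortality: float = 0.1
    initial_abundances: tuple[float, ...] | float = 25.0
    n_steps: int = 1000
    rule: SurveillanceRule = field(default_factory=SurveillanceRule)
    schedule: Schedule = field(default_factory=Schedule)
    euler_dt: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.growth_rates, dtype=float)
        if r.size < 1 or (r <= 0).any():
            raise ValueError("growth_rates must be positive")
        if self.capacity <= 0:
            raise ValueError(f"capacity must be positive, got {self.capacity}")
        if not 0.0 <= self.mortality < r.min():
            raise ValueError(
                f"mortality must be in [0, min r) = [0, {r.min()}), "
                f"got {self.mortality}"
            )
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if not 0.0 < self.euler_dt <= 1.0:
            raise ValueError(f"euler_dt must be in (0, 1], got {self.euler_dt}")
        x0 = self.x0
        if (x0 < 0).any():
            raise ValueError("initial abundances must be >= 0")

    @property
    def n(self) -> int:
        return len(self.growth_rates)

    @property
    def x0(self) -> np.ndarray:
        if np.isscalar(self.initial_abundances):
            return np.full(self.n, float(self.initial_abundances))
        x0 = np.asarray(self.initial_abundances, dtype=float)
        if x0.size != self.n:
            raise ValueError(
                f"initial_abundances has {x0.size} entries for {self.n} taxa"
            )
        return x0

    @property
    def extinction_tol(self) -> float:
        return EXTINCTION_TOL_FACTOR * self.capacity


def meanfield_step(
    x: np.ndarray, params: MeanFieldParams, suppression_active: bool = True
) -> tuple[np.ndarray, bool]:
    """One Euler update plus (optionally) the suppression check.

    Returns the new abundance vector and whether the cull fired.
    Abundances are floored at 0, so extinction is absorbing.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(params.growth_rates, dtype=float)
    k, m, dt = params.capacity, params.mortality, params.euler_dt
    s = x.sum()
    x_new = np.maximum(0.0, x + dt * x * (r * (1.0 - s / k) - m))

    fired = False
    s_new = x_new.sum()
    if suppression_active and s_new > 0:
        rule = params.rule
        shares = x_new / s_new
        i = int(np.argmax(shares))
        if s_new / k > rule.load_threshold and shares[i] > rule.dominance_threshold:
            x_new[i] *= 1.0 - rule.removal_fraction
            fired = True
    return x_new, fired


def _thresholded(x: np.ndarray, tol: float) -> np.ndarray:
    return np.where(x > tol, x, 0.0)


def survivors(x: np.ndarray, params: MeanFieldParams) -> int:
    """Number of taxa above the extinction tolerance ``1e-6 * K``."""
    return int(np.count_nonzero(np.asarray(x) > params.extinction_tol))


def meanfield_run(params: MeanFieldParams) -> pd.DataFrame:
    """Iterate the map for ``n_steps``; one trajectory row per step.

    The returned table uses the same schema as the lattice engine
    (``step``, ``count_i``, ``total``, ``hill_q0/1/2``, ``penalized``)
    with real-valued abundances in the count columns.  Hill numbers are
    computed on tolerance-thresholded abundances so that richness counts
    effectively surviving taxa.
    """
    x = params.x0.copy()
    tol = params.extinction_tol
    records = []
    for t in range(params.n_steps):
        active = is_active(params.schedule, t)
        x, fired = meanfield_step(x, params, suppression_active=active)
        xt = _thresholded(x, tol)
        row: dict = {"step": t}
        for i in range(params.n):
            row[f"count_{i + 1}"] = x[i]
        row.update(
            total=x.sum(),
            hill_q0=hill_number(xt, 0.0),
            hill_q1=hill_number(xt, 1.0),
            hill_q2=hill_number(xt, 2.0),
            penalized=fired,
        )
        records.append(row)
    return pd.DataFrame.from_records(records)


def single_taxon_equilibrium(r: float, m: float, k: float) -> float:
    """Closed-form logistic-with-mortality fixed point ``K (1 - m / r)``."""
    if not 0.0 <= m < r:
        raise ValueError("requires 0 <= m < r")
    return k * (1.0 - m / r)
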