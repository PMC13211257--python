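"""Hill-number diversity profiles.

Hill numbers express diversity as an *effective number of equally
abundant species*.  For relative abundances ``p_i`` over species with
nonzero abundance and order ``q >= 0``::

    D_q = (sum_i p_i ** q) ** (1 / (1 - q))     for q != 1
    D_1 = exp(-sum_i p_i * ln(p_i))             (the q -> 1 limit)

``q = 0`` is species richness, ``q = 1`` the exponential of Shannon
entropy, and ``q = 2`` the inverse Simpson index.  Larger ``q`` weights
abundant species more heavily, so ``D_q`` is non-increasing in ``q``.
An empty community has diversity 0 at every order by convention, so
post-collapse trajectories remain representable.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .hexlattice import AbundanceVector

DEFAULT_ORDERS: tuple[float, ...] = (0.0, 1.0, 2.0)


def hill_number(abundances: AbundanceVector | Iterable[float], q: float) -> float:
    """Hill diversity of order ``q`` for an abundance vector.

    Accepts an :class:`~ktwsim.hexlattice.AbundanceVector` or any
    sequence of non-negative abundances (counts or real biomasses; Hill
    numbers are scale invariant).  Zero-abundance species are excluded,
    which also encodes the ``0 * ln 0 = 0`` convention at ``q = 1``.
    """
    if q < 0:
        raise ValueError(f"Hill order q must be >= 0, got {q}")
    counts = (
        abundances.counts
        if isinstance(abundances, AbundanceVector)
        else np.asarray(list(abundances) if not hasattr(abundances, "ndim") else abundances)
    )
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("abundances must be non-negative")
    p = counts[counts > 0]
    if p.size == 0:
        return 0.0
    if q == 0:
        return float(p.size)
    p = p / p.sum()
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_profile(
    abundances: AbundanceVector | Iterable[float],
    orders: Iterable[float] = DEFAULT_ORDERS,
) -> np.ndarray:
    """Hill numbers at each requested order (default q = 0, 1, 2)."""
    return np.array([hill_number(abundances, q) for q in orders])


def shannon_entropy(abundances: AbundanceVector | Iterable[float]) -> float:
    """Raw Shannon entropy (nats); ``ln`` of the q=1 Hill number."""
    d1 = hill_number(abundances, 1.0)
    return float(np.log(d1)) if d1 > 0 else 0.0


def simpson_index(abundances: AbundanceVector | Iterable[float]) -> float:
    """Raw Simpson concentration ``sum p_i**2``; reciprocal of the q=2 Hill number."""
    d2 = hill_number(abundances, 2.0)
    return 1.0 / d2 if d2 > 0 else 0.0


def diversity_trajectory(
    traj: pd.DataFrame, orders: Iterable[float] = DEFAULT_ORDERS
) -> pd.DataFrame:
    """(Re)compute per-step Hill columns from the ``count_*`` columns.

    Returns a copy of ``traj`` with one ``hill_q{q:g}`` column per
    requested order, computed from that row's counts.  Works on any
    table of per-step counts, including mean-field trajectories with
    real-valued abundances.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    count_cols = [c for c in traj.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError("trajectory has no count_* columns")
    counts = traj[count_cols].to_numpy(dtype=float)
    out = traj.copy()
    for q in orders:
        out[f"hill_q{q:g}"] = [hill_number(row, q) for row in counts]
    return out
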