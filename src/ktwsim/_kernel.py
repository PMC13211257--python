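"""Inner replication loop, JIT-compiled with numba when available.

The replication phase visits surviving cells sequentially in a random
order; each replicating cell claims one empty neighbor, so later cells
in the order see earlier births as occupied.  That sequential exclusion
cannot be vectorized, hence a compiled loop.  The pure-Python fallback
is bit-identical and keeps small test lattices usable without numba.
"""

from __future__ import annotations

import numpy as np


def _replication_pass(
    occ: np.ndarray,        # int16[n_sites], mutated in place
    nbr: np.ndarray,        # int64[n_sites, 6] neighbor table
    repl_prob: np.ndarray,  # float64[n_species], index species_id - 1
    order: np.ndarray,      # int64[k] site indices, random visit order
    u_repl: np.ndarray,     # float64[k] uniforms: replicate or not
    u_choice: np.ndarray,   # float64[k] uniforms: which empty neighbor
) -> None:
    for k in range(order.shape[0]):
        s = order[k]
        sp = occ[s]
        if sp == 0:
            continue
        if u_repl[k] >= repl_prob[sp - 1]:
            continue
        n_empty = 0
        for j in range(6):
            if occ[nbr[s, j]] == 0:
                n_empty += 1
        if n_empty == 0:
            continue
        pick = int(u_choice[k] * n_empty)
        if pick == n_empty:  # guard u == 1.0 edge
            pick = n_empty - 1
        seen = 0
        for j in range(6):
            t = nbr[s, j]
            if occ[t] == 0:
                if seen == pick:
                    occ[t] = sp
                    break
                seen += 1


try:  # pragma: no cover - exercised implicitly by every dynamics test
    from numba import njit

    replication_pass = njit(cache=False)(_replication_pass)
except ImportError:  # pragma: no cover
    replication_pass = _replication_pass
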