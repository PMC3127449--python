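"""Compiled inner loop for Metropolis-Hastings double-edge-swap rewiring.

State is carried in flat arrays so the sampler can run millions of proposals
per minute on a single core:

* ``A``      -- dense boolean adjacency (N x N),
* ``sp``     -- shared-partner counts ``|N_i  intersect  N_j|`` for *every*
               node pair (int16, N x N), updated incrementally,
* ``nbr``    -- neighbour lists packed CSR-style (``start``/``cur`` give each
               node's slice; capacities equal the fixed degrees, which double
               edge swaps never change),
* ``eu, ev`` -- the current edge list (length M, constant under swapping),
* ``w``      -- per-shared-partner-count weights of the geometrically
               weighted edgewise-shared-partner statistic, so the statistic
               is ``sum over edges of w[sp[u, v]]``.

Removing edge ``(a, b)`` changes ``sp`` only for pairs involving ``a`` or
``b``: ``sp[a, y]`` drops by one exactly for the neighbours ``y`` of ``b``
(and symmetrically), which is what the two loops in ``_remove_edge`` walk.
The returned deltas are exact, so accept/reject needs no recomputation.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _nbr_remove(nbr, start, cur, x, y):
    s = start[x]
    for t in range(cur[x]):
        if nbr[s + t] == y:
            cur[x] -= 1
            nbr[s + t] = nbr[s + cur[x]]
            return


@njit(cache=False)
def _nbr_append(nbr, start, cur, x, y):
    nbr[start[x] + cur[x]] = y
    cur[x] += 1


@njit(cache=False)
def _remove_edge(a, b, A, sp, nbr, start, cur, w):
    delta = -w[sp[a, b]]
    A[a, b] = False
    A[b, a] = False
    _nbr_remove(nbr, start, cur, a, b)
    _nbr_remove(nbr, start, cur, b, a)
    for t in range(cur[b]):
        y = nbr[start[b] + t]
        sp[a, y] -= 1
        sp[y, a] -= 1
        if A[a, y]:
            delta += w[sp[a, y]] - w[sp[a, y] + 1]
    for t in range(cur[a]):
        y = nbr[start[a] + t]
        sp[b, y] -= 1
        sp[y, b] -= 1
        if A[b, y]:
            delta += w[sp[b, y]] - w[sp[b, y] + 1]
    return delta


@njit(cache=False)
def _add_edge(a, b, A, sp, nbr, start, cur, w):
    delta = 0.0
    for t in range(cur[b]):
        y = nbr[start[b] + t]
        sp[a, y] += 1
        sp[y, a] += 1
        if A[a, y]:
            delta += w[sp[a, y]] - w[sp[a, y] - 1]
    for t in range(cur[a]):
        y = nbr[start[a] + t]
        sp[b, y] += 1
        sp[y, b] += 1
        if A[b, y]:
            delta += w[sp[b, y]] - w[sp[b, y] - 1]
    delta += w[sp[a, b]]
    A[a, b] = True
    A[b, a] = True
    _nbr_append(nbr, start, cur, a, b)
    _nbr_append(nbr, start, cur, b, a)
    return delta


@njit(cache=False)
def mh_sweep(eu, ev, A, sp, nbr, start, cur, w, theta, n_proposals, seed):
    """Run ``n_proposals`` double-edge-swap proposals; mutate state in place.

    ``seed >= 0`` reseeds the stream; ``seed < 0`` continues it (used when a
    burn-in is split into chunks for progress logging).  Returns the number
    of valid proposals, the number accepted, and the cumulative change in
    the clustering statistic.
    """
    if seed >= 0:
        np.random.seed(seed)
    M = eu.shape[0]
    n_valid = 0
    n_accepted = 0
    delta_sum = 0.0
    for _ in range(n_proposals):
        i = np.random.randint(M)
        j = np.random.randint(M)
        if i == j:
            continue
        a = eu[i]
        b = ev[i]
        c = eu[j]
        d = ev[j]
        if np.random.randint(2) == 1:
            c, d = d, c
        # proposed replacement edges: (a, d) and (c, b)
        if a == d or c == b:
            continue  # would create a self-loop
        if A[a, d] or A[c, b]:
            continue  # would duplicate an existing edge
        n_valid += 1
        delta = _remove_edge(a, b, A, sp, nbr, start, cur, w)
        delta += _remove_edge(c, d, A, sp, nbr, start, cur, w)
        delta += _add_edge(a, d, A, sp, nbr, start, cur, w)
        delta += _add_edge(c, b, A, sp, nbr, start, cur, w)
        x = theta * delta
        if x >= 0.0 or np.random.random() < np.exp(x):
            eu[i] = a
            ev[i] = d
            eu[j] = c
            ev[j] = b
            n_accepted += 1
            delta_sum += delta
        else:
            _remove_edge(a, d, A, sp, nbr, start, cur, w)
            _remove_edge(c, b, A, sp, nbr, start, cur, w)
            _add_edge(a, b, A, sp, nbr, start, cur, w)
            _add_edge(c, d, A, sp, nbr, start, cur, w)
    return n_valid, n_accepted, delta_sum
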