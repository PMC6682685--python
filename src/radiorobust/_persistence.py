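"""Union-find kernels for 2-D cubical sublevel-set persistence.

Pixels are treated as top-dimensional cells: the sublevel set at threshold
``t`` is the set of pixels with value <= t, and two pixels in the sublevel
set are connected if they share an edge or a corner (8-connectivity for H0).
H1 is obtained by duality from a second sweep over the negated image with
the complementary 4-connectivity; see :mod:`radiorobust.tda`.

The sweep is the standard elder-rule union-find: pixels enter in order of
value; when two components meet, the younger one (larger birth, later
creation on ties) dies at the current value.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OFFS8 = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
_OFFS4 = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64)


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:  # path compression
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _sweep(values, order, height, width, offsets):
    """Elder-rule sweep over pixels sorted ascending by value.

    Pixels with value +inf never enter the filtration.  Returns
    ``(pairs, n_pairs, ess, n_ess)``: finite (birth, death) pairs from
    component merges and the birth values of surviving (essential)
    components.  Zero-length finite pairs are not emitted.
    """
    n = height * width
    parent = np.full(n, -1, dtype=np.int64)
    birth = np.empty(n, dtype=np.float64)
    created = np.empty(n, dtype=np.int64)
    pairs = np.empty((n, 2), dtype=np.float64)
    n_pairs = 0

    for k in range(order.shape[0]):
        p = order[k]
        v = values[p]
        if v == np.inf:
            break
        parent[p] = p
        birth[p] = v
        created[p] = k
        py = p // width
        px = p % width
        for j in range(offsets.shape[0]):
            qy = py + offsets[j, 0]
            qx = px + offsets[j, 1]
            if qy < 0 or qy >= height or qx < 0 or qx >= width:
                continue
            q = qy * width + qx
            if parent[q] == -1:
                continue
            rp = _find(parent, p)
            rq = _find(parent, q)
            if rp == rq:
                continue
            # elder rule: smaller birth survives; ties -> earlier creation
            if (birth[rq] < birth[rp]) or (
                birth[rq] == birth[rp] and created[rq] < created[rp]
            ):
                elder, young = rq, rp
            else:
                elder, young = rp, rq
            if birth[young] < v:  # zero-length pairs are not topology
                pairs[n_pairs, 0] = birth[young]
                pairs[n_pairs, 1] = v
                n_pairs += 1
            parent[young] = elder

    ess = np.empty(n, dtype=np.float64)
    n_ess = 0
    for i in range(n):
        if parent[i] == i:
            ess[n_ess] = birth[i]
            n_ess += 1
    return pairs, n_pairs, ess, n_ess


def sublevel_sweep(values2d: np.ndarray, connectivity: int):
    """Run the elder-rule sweep on a 2-D float image.

    ``values2d`` may contain ``+inf`` (excluded pixels) and ``-inf``
    (pixels present from the start).  Returns ``(finite_pairs, essential
    births)`` as float arrays.
    """
    vals = np.ascontiguousarray(values2d, dtype=np.float64)
    h, w = vals.shape
    flat = vals.ravel()
    order = np.argsort(flat, kind="stable")
    offs = _OFFS8 if connectivity == 8 else _OFFS4
    pairs, n_pairs, ess, n_ess = _sweep(flat, order, h, w, offs)
    return pairs[:n_pairs].copy(), ess[:n_ess].copy()
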