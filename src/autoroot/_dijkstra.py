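"""Numba kernel: multi-source Dijkstra over the 8-connected pixel graph.

Each pixel is a node; edges join 8-neighbours.  The edge weight between
pixels p and q with normalised intensities ip, iq is

    w(p, q) = 1 - alpha * (ip * iq)

with alpha = 1 for horizontal/vertical steps and sqrt(2) for diagonal steps
(longer centre-to-centre distance).  Bright-to-bright steps are cheap, so
shortest paths hug root material.  The product is grouped as ``(ip * iq)``
so the weight is bitwise identical in both directions of an edge.

Two treatments of the diagonal case where the raw weight goes negative
(ip*iq > 1/sqrt(2)) are supported:

* mode 0 ("clamped", default): negative weights clamp to 0 — zero-cost
  travel through saturated material, preserving Dijkstra's non-negativity.
* mode 1 ("scaled"): w = alpha * (1 - ip*iq), which is non-negative by
  construction and keeps the orthogonal case unchanged.

The priority queue is an explicit array binary heap ordered by
(distance, y, x), so results are reproducible across runs and platforms.
"""

import numpy as np
from numba import njit

SQRT2 = np.sqrt(2.0)

WEIGHT_MODE_CLAMPED = 0
WEIGHT_MODE_SCALED = 1


@njit(cache=True)
def _sift_up(hd, hi, i):
    while i > 0:
        p = (i - 1) // 2
        if hd[p] > hd[i] or (hd[p] == hd[i] and hi[p] > hi[i]):
            hd[p], hd[i] = hd[i], hd[p]
            hi[p], hi[i] = hi[i], hi[p]
            i = p
        else:
            break


@njit(cache=True)
def _sift_down(hd, hi, size):
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < size and (hd[l] < hd[m] or (hd[l] == hd[m] and hi[l] < hi[m])):
            m = l
        if r < size and (hd[r] < hd[m] or (hd[r] == hd[m] and hi[r] < hi[m])):
            m = r
        if m == i:
            break
        hd[m], hd[i] = hd[i], hd[m]
        hi[m], hi[i] = hi[i], hi[m]
        i = m


@njit(cache=True)
def dijkstra_grid(intensities, seed_ys, seed_xs, weight_mode):
    """Shortest-path cost from the nearest of the seed pixels to every pixel.

    Parameters are a (H, W) float64 intensity field in [0, 1], parallel seed
    row/column index arrays, and the weight mode (0 clamped, 1 scaled).
    Returns a (H, W) float64 array of distances (0 at seeds).
    """
    H, W = intensities.shape
    N = H * W
    dist = np.full(N, np.inf)
    # Lazy-deletion heap: every relaxation pushes, stale entries are skipped
    # on pop.  Each node relaxes at most 8 times, so 8N+8 slots suffice.
    cap = 8 * N + 8
    hd = np.empty(cap)
    hi = np.empty(cap, np.int64)
    size = 0
    for k in range(seed_ys.shape[0]):
        idx = seed_ys[k] * W + seed_xs[k]
        if dist[idx] > 0.0:
            dist[idx] = 0.0
            hd[size] = 0.0
            hi[size] = idx
            size += 1
            _sift_up(hd, hi, size - 1)
    while size > 0:
        d = hd[0]
        idx = hi[0]
        size -= 1
        hd[0] = hd[size]
        hi[0] = hi[size]
        _sift_down(hd, hi, size)
        if d > dist[idx]:
            continue
        y = idx // W
        x = idx % W
        ip = intensities[y, x]
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                if dy == 0 and dx == 0:
                    continue
                ny = y + dy
                nx = x + dx
                if ny < 0 or ny >= H or nx < 0 or nx >= W:
                    continue
                diagonal = dy != 0 and dx != 0
                alpha = SQRT2 if diagonal else 1.0
                if weight_mode == WEIGHT_MODE_SCALED:
                    w = alpha * (1.0 - ip * intensities[ny, nx])
                else:
                    w = 1.0 - alpha * (ip * intensities[ny, nx])
                    if w < 0.0:
                        w = 0.0
                nd = d + w
                nidx = ny * W + nx
                if nd < dist[nidx]:
                    dist[nidx] = nd
                    hd[size] = nd
                    hi[size] = nidx
                    size += 1
                    _sift_up(hd, hi, size - 1)
    return dist.reshape(H, W)
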