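"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a quantity by the most literal method
available (exhaustive scan, flood fill, breadth-first search, explicit
normal equations) without touching the package's implementations.
"""

from collections import deque

import numpy as np


def otsu_exhaustive(values, bins=256):
    """Exhaustive Otsu scan: try every interior histogram bin edge,
    compute between-class variance w0*w1*(mu0-mu1)^2 from the actual
    sample values, return the first maximizing edge."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    edges = np.histogram_bin_edges(values, bins=bins, range=(vmin, vmax))
    n = values.size
    best_t, best_var = None, -1.0
    for t in edges[1:-1]:
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            var = 0.0
        else:
            w0, w1 = lo.size / n, hi.size / n
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def _neighbors(connectivity):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def flood_fill_components(mask, connectivity=26):
    """Label connected components by explicit flood fill in scan order.

    Returns (labels, sizes) with labels assigned 1, 2, ... in the order
    the components' first voxels appear in the array scan.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = _neighbors(connectivity)
    shape = mask.shape
    sizes = []
    label = 0
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if labels[idx]:
            continue
        label += 1
        size = 0
        queue = deque([idx])
        labels[idx] = label
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and mask[nx, ny, nz]
                    and not labels[nx, ny, nz]
                ):
                    labels[nx, ny, nz] = label
                    queue.append((nx, ny, nz))
        sizes.append(size)
    return labels, np.array(sizes)


def largest_component_bruteforce(mask, connectivity=26):
    """Largest component via flood fill; size ties pick the component
    whose first voxel comes first in scan order (the smallest label)."""
    labels, sizes = flood_fill_components(mask, connectivity)
    if sizes.size == 0:
        raise ValueError("empty mask")
    winner = 1 + int(np.flatnonzero(sizes == sizes.max())[0])
    return labels == winner


def region_grow_bfs(seed, eligible, connectivity=26):
    """Breadth-first search from the seed voxels over eligible voxels."""
    seed = np.asarray(seed, dtype=bool)
    eligible = np.asarray(eligible, dtype=bool)
    out = seed.copy()
    offsets = _neighbors(connectivity)
    shape = seed.shape
    queue = deque(map(tuple, np.argwhere(seed)))
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if (
                0 <= nx < shape[0]
                and 0 <= ny < shape[1]
                and 0 <= nz < shape[2]
                and eligible[nx, ny, nz]
                and not out[nx, ny, nz]
            ):
                out[nx, ny, nz] = True
                queue.append((nx, ny, nz))
    return out


def ols_normal_equations(b, log_s):
    """Slope/intercept of log_s on b by explicitly solving X'X beta = X'y."""
    X = np.column_stack([np.ones_like(b), b])
    beta = np.linalg.solve(X.T @ X, X.T @ log_s)
    return beta[1], beta[0]


def percentile_sort_interpolate(values, p):
    """Sorted-sample percentile at 1-based position 1 + p*(n-1)."""
    s = np.sort(np.asarray(values, dtype=float))
    pos = p * (s.size - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, s.size - 1)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def rician_mean(nu, sigma):
    """Closed-form mean of a Rice(nu, sigma) variable:
    sigma*sqrt(pi/2) * L_{1/2}(-nu^2 / (2 sigma^2)) with L the Laguerre
    function expressed through modified Bessel functions."""
    from scipy.special import ive

    x = nu**2 / (2 * sigma**2)
    # exp(-x/2)*I_k(x/2) computed stably via ive = I*exp(-|arg|)
    laguerre = (1 + x) * ive(0, x / 2) + x * ive(1, x / 2)
    return sigma * np.sqrt(np.pi / 2) * laguerre


def dice(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / denom if denom else 1.0
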