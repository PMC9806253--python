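"""Independent brute-force oracles for the texture matrices and statistics.

Everything here is deliberately naive — explicit loops over voxel pairs,
runs, zones and neighborhoods — and shares no code with the package's
vectorized implementations.
"""

import numpy as np

ALL_OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
]


def brute_glcm(levels, n_levels, offsets=ALL_OFFSETS_13, distance=1):
    """Pair-by-pair co-occurrence counting, symmetrized and normalized."""
    lev = np.asarray(levels)
    G = n_levels
    P = np.zeros((G, G))
    nx, ny, nz = lev.shape
    for dx, dy, dz in offsets:
        dx, dy, dz = dx * distance, dy * distance, dz * distance
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if lev[x, y, z] == 0:
                        continue
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and lev[u, v, w] > 0:
                        P[lev[x, y, z] - 1, lev[u, v, w] - 1] += 1
    P = P + P.T
    return P / P.sum() if P.sum() else P


def brute_runs(levels, off):
    """All maximal same-level in-mask runs along one direction: (level, length)."""
    lev = np.asarray(levels)
    nx, ny, nz = lev.shape
    dx, dy, dz = off
    runs = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if lev[x, y, z] == 0:
                    continue
                # run start: predecessor missing or different
                px, py, pz = x - dx, y - dy, z - dz
                if (
                    0 <= px < nx
                    and 0 <= py < ny
                    and 0 <= pz < nz
                    and lev[px, py, pz] == lev[x, y, z]
                ):
                    continue
                length = 1
                u, v, w = x + dx, y + dy, z + dz
                while (
                    0 <= u < nx
                    and 0 <= v < ny
                    and 0 <= w < nz
                    and lev[u, v, w] == lev[x, y, z]
                ):
                    length += 1
                    u, v, w = u + dx, v + dy, w + dz
                runs.append((int(lev[x, y, z]), length))
    return runs


def brute_glrlm(levels, n_levels, off):
    runs = brute_runs(levels, off)
    L = max(l for _, l in runs)
    R = np.zeros((n_levels, L))
    for g, l in runs:
        R[g - 1, l - 1] += 1
    return R


def brute_zones(levels):
    """26-connected same-level zones by breadth-first flood fill."""
    lev = np.asarray(levels)
    nx, ny, nz = lev.shape
    seen = np.zeros_like(lev, dtype=bool)
    neigh = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    zones = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if lev[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = lev[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    a, b, c = stack.pop()
                    size += 1
                    for dx, dy, dz in neigh:
                        u, v, w = a + dx, b + dy, c + dz
                        if (
                            0 <= u < nx
                            and 0 <= v < ny
                            and 0 <= w < nz
                            and not seen[u, v, w]
                            and lev[u, v, w] == g
                        ):
                            seen[u, v, w] = True
                            stack.append((u, v, w))
                zones.append((int(g), size))
    return zones


def brute_ngtdm(levels, n_levels):
    """Per-level (p_i, s_i, n_i) by explicit neighborhood loops."""
    lev = np.asarray(levels)
    nx, ny, nz = lev.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if lev[x, y, z] == 0:
                    continue
                vals = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                                if lev[u, v, w] > 0:
                                    vals.append(lev[u, v, w])
                if vals:
                    g = lev[x, y, z]
                    s[g - 1] += abs(g - np.mean(vals))
                    n[g - 1] += 1
    p = n / n.sum() if n.sum() else n
    return p, s, n


def brute_auc(scores, labels):
    """All (positive, negative) pairs with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (pos.size * neg.size)


def anova_icc21(ratings):
    """ICC(2,1) from the explicit two-way ANOVA mean squares."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - grand) ** 2).sum() - k * ((x.mean(axis=1) - grand) ** 2).sum() - n * (
        (x.mean(axis=0) - grand) ** 2
    ).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def random_levels(rng, shape=(6, 6, 6), n_levels=5, mask_p=0.7):
    """A random discretized masked volume for oracle comparisons."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels
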