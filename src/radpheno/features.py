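"""The 64-feature texture roster and the 833-feature radiomic feature group.

Five feature families are computed on a gray-level-discretized masked
volume: 14 first-order statistics, 13 gray level co-occurrence matrix
(GLCM) features, 16 gray level run length matrix (GLRLM) features,
16 gray level size zone matrix (GLSZM) features and 5 neighborhood gray
tone difference matrix (NGTDM) features — the standard
Haralick / Galloway / Thibault / Amadasun–King canon, 64 in total.

Aggregation is fully 3D: co-occurrences and runs use the 13 unique 3D
directions at distance 1 (GLCM accumulated into one symmetric matrix
before normalization, GLRLM features averaged over per-direction
matrices); size zones use 26-connectivity; NGTDM neighborhoods are the
26 surrounding voxels restricted to the mask.

A radiomic feature group (RFG) for one ROI on one DCE phase is the
833-vector: tumor volume (mm^3), the 64 features on the original image,
and the 64 features on each of the 12 wavelet-filtered images (768
wavelet features).  Wavelet-filtered images are re-discretized
independently because their intensity ranges differ from the original.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import DiscretizedVolume, VolumeWithMask, crop_to_mask, discretize
from .wavelets import all_specs, filter_bank

#: Guard for zero denominators in NGTDM-style normalizations.
EPS = 1e-6

#: The 13 unique 3D direction offsets at distance 1.
OFFSETS_13 = np.array(
    [
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
    ],
    dtype=np.int64,
)

FIRST_ORDER_NAMES = (
    "fo_mean",
    "fo_median",
    "fo_min",
    "fo_max",
    "fo_range",
    "fo_variance",
    "fo_skewness",
    "fo_kurtosis",
    "fo_energy",
    "fo_entropy",
    "fo_rms",
    "fo_mad",
    "fo_uniformity",
    "fo_iqr",
)
GLCM_NAMES = (
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_correlation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_max_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_difference_entropy",
    "glcm_idn",
)
GLRLM_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_glnn",
    "glrlm_rln",
    "glrlm_rlnn",
    "glrlm_rp",
    "glrlm_glv",
    "glrlm_rv",
    "glrlm_re",
    "glrlm_lglre",
    "glrlm_hglre",
    "glrlm_srlgle",
    "glrlm_srhgle",
    "glrlm_lrlgle",
    "glrlm_lrhgle",
)
GLSZM_NAMES = (
    "glszm_sae",
    "glszm_lae",
    "glszm_gln",
    "glszm_glnn",
    "glszm_szn",
    "glszm_sznn",
    "glszm_zp",
    "glszm_glv",
    "glszm_zv",
    "glszm_ze",
    "glszm_lglze",
    "glszm_hglze",
    "glszm_salgle",
    "glszm_sahgle",
    "glszm_lalgle",
    "glszm_lahgle",
)
NGTDM_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

TEXTURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES
assert len(TEXTURE_NAMES) == 64


def rfg_feature_names() -> list[str]:
    """The 833 RFG feature names in canonical order."""
    names = ["volume_mm3"]
    names += [f"orig_{n}" for n in TEXTURE_NAMES]
    for spec in all_specs():
        names += [f"wav_{spec.label}_{n}" for n in TEXTURE_NAMES]
    return names


def _offset_slices(off, shape):
    s1, s2 = [], []
    for o, n in zip(off, shape):
        o = int(o)
        if o >= 0:
            s1.append(slice(0, n - o))
            s2.append(slice(o, n))
        else:
            s1.append(slice(-o, n))
            s2.append(slice(0, n + o))
    return tuple(s1), tuple(s2)


# ---------------------------------------------------------------------------
# first order


def first_order_features(d: DiscretizedVolume, raw: VolumeWithMask) -> dict[str, float]:
    """14 first-order statistics of the in-mask intensity distribution.

    All are computed from the raw intensities except entropy (base-2, over
    the discretized level histogram) and uniformity (sum of squared level
    probabilities).  For a constant region the conventions are variance 0,
    skewness 0, kurtosis 0, entropy 0 and uniformity 1.
    """
    mask = d.mask
    if not mask.any():
        raise ValueError("empty mask")
    x = raw.intensities[mask].astype(float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    centered = x - mean
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4 - 3.0)  # Fisher excess
    else:
        skew = 0.0
        kurt = 0.0
    counts = np.bincount(d.levels[mask], minlength=d.n_levels + 1)[1:]
    p = counts[counts > 0] / n
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {
        "fo_mean": mean,
        "fo_median": float(q50),
        "fo_min": float(x.min()),
        "fo_max": float(x.max()),
        "fo_range": float(x.max() - x.min()),
        "fo_variance": var,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": float(np.sum(x**2)),
        "fo_entropy": float(-np.sum(p * np.log2(p))),
        "fo_rms": float(np.sqrt(np.mean(x**2))),
        "fo_mad": float(np.mean(np.abs(centered))),
        "fo_uniformity": float(np.sum(p**2)),
        "fo_iqr": float(q75 - q25),
    }


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    d: DiscretizedVolume, distance: int = 1, offsets: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix over the 13 3D directions.

    Only voxel pairs that are both inside the mask contribute.  Counts from
    all directions are pooled into one matrix, symmetrized, and normalized
    to sum 1.  ``offsets`` restricts accumulation to a subset of directions.
    """
    lev = d.levels
    G = d.n_levels
    counts = np.zeros(G * G, dtype=np.int64)
    if offsets is None:
        offsets = OFFSETS_13
    for off in np.asarray(offsets) * distance:
        s1, s2 = _offset_slices(off, lev.shape)
        a = lev[s1].ravel()
        b = lev[s2].ravel()
        valid = (a > 0) & (b > 0)
        if valid.any():
            counts += np.bincount(
                (a[valid] - 1) * G + (b[valid] - 1), minlength=G * G
            )
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "degenerate ROI: no pair of in-mask voxels is adjacent in any "
            "of the 13 directions"
        )
    P = counts.reshape(G, G).astype(float)
    P = P + P.T
    return P / P.sum()


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """13 Haralick-style features of a normalized symmetric GLCM."""
    P = np.asarray(P, dtype=float)
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    G = P.shape[0]
    i = np.arange(1, G + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))
    nz = P > 0
    entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
    if sigma2 > EPS:
        correlation = float(np.sum(P * (I - mu) * (J - mu)) / sigma2)
    else:
        correlation = 1.0  # single-level ROI: perfectly correlated by convention
    # diagonal-sum and diagonal-difference marginals
    p_sum = np.bincount((I + J).ravel(), weights=P.ravel())[2:]
    p_diff = np.bincount(np.abs(I - J).ravel(), weights=P.ravel())
    k_sum = np.arange(2, 2 * G + 1)
    nzs = p_sum > 0
    nzd = p_diff > 0
    return {
        "glcm_contrast": float(np.sum(P * (I - J) ** 2)),
        "glcm_dissimilarity": float(np.sum(P * np.abs(I - J))),
        "glcm_homogeneity": float(np.sum(P / (1.0 + (I - J) ** 2))),
        "glcm_energy": float(np.sum(P**2)),
        "glcm_entropy": entropy,
        "glcm_correlation": correlation,
        "glcm_cluster_shade": float(np.sum(P * (I + J - 2 * mu) ** 3)),
        "glcm_cluster_prominence": float(np.sum(P * (I + J - 2 * mu) ** 4)),
        "glcm_max_probability": float(P.max()),
        "glcm_sum_average": float(np.sum(k_sum * p_sum)),
        "glcm_sum_entropy": float(-np.sum(p_sum[nzs] * np.log2(p_sum[nzs]))),
        "glcm_difference_entropy": float(-np.sum(p_diff[nzd] * np.log2(p_diff[nzd]))),
        "glcm_idn": float(np.sum(P / (1.0 + np.abs(I - J) / G))),
    }


# ---------------------------------------------------------------------------
# GLRLM


def _runs_for_direction(coords: np.ndarray, lv: np.ndarray, off: np.ndarray):
    """Maximal in-mask runs of equal level along one direction.

    Voxels on the same lattice line through direction ``off`` share the
    cross product ``p x off``; sorting by (line, position) exposes runs as
    maximal stretches of consecutive positions with equal level.
    Returns (run levels, run lengths).
    """
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    dx, dy, dz = (int(o) for o in off)
    t = x * dx + y * dy + z * dz
    c0 = y * dz - z * dy
    c1 = z * dx - x * dz
    c2 = x * dy - y * dx
    # single-integer sort key: (line id, position along line)
    B = int(coords.max()) + 2 if coords.size else 2
    lid = ((c0 + 2 * B) * (4 * B) + (c1 + 2 * B)) * (4 * B) + (c2 + 2 * B)
    key = lid * (2 * B * 3 + 1) + (t - t.min())
    order = np.argsort(key, kind="stable")
    lid = lid[order]
    t = t[order]
    lv = lv[order]
    step = dx * dx + dy * dy + dz * dz
    cont = (lid[1:] == lid[:-1]) & (t[1:] - t[:-1] == step) & (lv[1:] == lv[:-1])
    starts = np.flatnonzero(np.concatenate(([True], ~cont)))
    lengths = np.diff(np.append(starts, lv.size))
    return lv[starts], lengths


def glrlm_matrix(d: DiscretizedVolume, off: np.ndarray) -> np.ndarray:
    """Run-length count matrix (levels x run length) for one direction."""
    coords = np.argwhere(d.levels > 0)
    lv = d.levels[d.levels > 0]
    run_lv, run_len = _runs_for_direction(coords, lv, np.asarray(off))
    G = d.n_levels
    L = int(run_len.max())
    R = np.bincount((run_lv - 1) * L + (run_len - 1), minlength=G * L)
    return R.reshape(G, L).astype(float)


def _rl_features_batch(R: np.ndarray, n_voxels: int) -> np.ndarray:
    """The 16 run-length/size-zone feature forms for a stack of matrices.

    ``R``: (n_matrices, G, L) counts.  Returns (n_matrices, 16).  All but
    the four joint low/high gray-level emphasis terms and the entropy
    depend only on the two marginals; the joint terms are bilinear forms.
    """
    D, G, L = R.shape
    i = np.arange(1.0, G + 1)
    j = np.arange(1.0, L + 1)
    Nr = R.sum(axis=(1, 2))
    ri = R.sum(axis=2)  # (D, G)
    rj = R.sum(axis=1)  # (D, L)
    wi2 = 1.0 / i**2
    wj2 = 1.0 / j**2
    mu_i = (ri @ i) / Nr
    mu_j = (rj @ j) / Nr
    p = R / Nr[:, None, None]
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    plogp = p * logp
    out = np.empty((D, 16))
    out[:, 0] = (rj @ wj2) / Nr  # SRE / SAE
    out[:, 1] = (rj @ j**2) / Nr  # LRE / LAE
    out[:, 2] = (ri**2).sum(1) / Nr  # GLN
    out[:, 3] = out[:, 2] / Nr  # GLNN
    out[:, 4] = (rj**2).sum(1) / Nr  # RLN / SZN
    out[:, 5] = out[:, 4] / Nr  # RLNN / SZNN
    out[:, 6] = Nr / n_voxels  # RP / ZP
    out[:, 7] = (ri * (i[None, :] - mu_i[:, None]) ** 2).sum(1) / Nr  # GLV
    out[:, 8] = (rj * (j[None, :] - mu_j[:, None]) ** 2).sum(1) / Nr  # RV / ZV
    out[:, 9] = -plogp.sum(axis=(1, 2))  # RE / ZE
    out[:, 10] = (ri @ wi2) / Nr  # LGLRE
    out[:, 11] = (ri @ i**2) / Nr  # HGLRE
    out[:, 12] = np.einsum("dgl,g,l->d", R, wi2, wj2) / Nr  # SRLGLE
    out[:, 13] = np.einsum("dgl,g,l->d", R, i**2, wj2) / Nr  # SRHGLE
    out[:, 14] = np.einsum("dgl,g,l->d", R, wi2, j**2) / Nr  # LRLGLE
    out[:, 15] = np.einsum("dgl,g,l->d", R, i**2, j**2) / Nr  # LRHGLE
    return out


def glrlm_features(d: DiscretizedVolume) -> dict[str, float]:
    """16 run-length features, averaged over the 13 direction matrices."""
    mask = d.mask
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.argwhere(mask)
    lv = d.levels[mask]
    n_vox = lv.size
    G = d.n_levels
    all_lv, all_len, all_dir = [], [], []
    for di, off in enumerate(OFFSETS_13):
        run_lv, run_len = _runs_for_direction(coords, lv, off)
        all_lv.append(run_lv)
        all_len.append(run_len)
        all_dir.append(np.full(run_lv.size, di))
    run_lv = np.concatenate(all_lv)
    run_len = np.concatenate(all_len)
    run_dir = np.concatenate(all_dir)
    L = int(run_len.max())
    flat = (run_dir * G + (run_lv - 1)) * L + (run_len - 1)
    R = np.bincount(flat, minlength=13 * G * L).reshape(13, G, L).astype(float)
    acc = _rl_features_batch(R, n_vox).mean(axis=0)
    return dict(zip(GLRLM_NAMES, map(float, acc)))


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_zones(d: DiscretizedVolume) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level in-mask zone.

    Zones of all gray levels are found in one pass: same-level 26-adjacent
    in-mask voxel pairs (enumerated with the 13 offset shifts) form a
    sparse graph whose connected components are the zones.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    lev = d.levels
    inmask = lev.ravel() > 0
    if not inmask.any():
        raise ValueError("empty mask")
    # compact indexing: the graph is built over mask voxels only
    m = int(inmask.sum())
    compact = np.full(lev.size, -1, dtype=np.int64)
    compact[inmask] = np.arange(m)
    compact3 = compact.reshape(lev.shape)
    rows, cols = [], []
    for off in OFFSETS_13:
        s1, s2 = _offset_slices(off, lev.shape)
        a = lev[s1].ravel()
        b = lev[s2].ravel()
        valid = (a > 0) & (a == b)
        if valid.any():
            rows.append(compact3[s1].ravel()[valid])
            cols.append(compact3[s2].ravel()[valid])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(m, m))
        _, comp = connected_components(graph, directed=False)
    else:
        comp = np.arange(m)
    lv = lev.ravel()[inmask]
    uniq, inv = np.unique(comp, return_inverse=True)
    sizes = np.bincount(inv)
    first = np.zeros(uniq.size, dtype=np.int64)
    first[inv[::-1]] = np.arange(lv.size - 1, -1, -1)
    zone_lv = lv[first]
    return list(zip(zone_lv.astype(int).tolist(), sizes.astype(int).tolist()))


def glszm_features(d: DiscretizedVolume) -> dict[str, float]:
    """16 size-zone features (Thibault), same algebraic forms as GLRLM
    with run length replaced by zone size."""
    if not d.mask.any():
        raise ValueError("empty mask")
    zones = glszm_zones(d)
    n_vox = int(d.mask.sum())
    G = d.n_levels
    L = max(s for _, s in zones)
    Z = np.zeros((1, G, L))
    for g, s in zones:
        Z[0, g - 1, s - 1] += 1
    vals = _rl_features_batch(Z, n_vox)[0]
    return dict(zip(GLSZM_NAMES, map(float, vals)))


# ---------------------------------------------------------------------------
# NGTDM

_KERNEL_26 = np.ones((3, 3, 3))
_KERNEL_26[1, 1, 1] = 0.0


def ngtdm_table(d: DiscretizedVolume):
    """Per-level (p_i, s_i, n_i) of the neighborhood gray tone difference matrix.

    ``s_i`` sums |i - mean level of the in-mask 26-neighborhood| over valid
    voxels of level i (valid: at least one in-mask neighbour); ``n_i``
    counts those voxels; ``p_i = n_i / N_valid``.
    """
    lev = d.levels
    mask = d.mask
    if not mask.any():
        raise ValueError("empty mask")
    sums = ndimage.correlate(lev.astype(float) * mask, _KERNEL_26, mode="constant")
    cnts = ndimage.correlate(mask.astype(float), _KERNEL_26, mode="constant")
    valid = mask & (cnts > 0.5)
    li = lev[valid]
    abar = sums[valid] / cnts[valid]
    G = d.n_levels
    s = np.bincount(li - 1, weights=np.abs(li - abar), minlength=G)
    n = np.bincount(li - 1, minlength=G).astype(float)
    p = n / n.sum()
    return p, s, n


def ngtdm_features(d: DiscretizedVolume) -> dict[str, float]:
    """5 Amadasun–King features with an epsilon guard on zero denominators.

    Constant-ROI conventions: s_i are all zero, so coarseness saturates at
    its documented cap 1/EPS and contrast, busyness, complexity and
    strength are 0.
    """
    p, s, n = ngtdm_table(d)
    Nv = n.sum()
    G = p.size
    i = np.arange(1, G + 1, dtype=float)
    act = p > 0
    Ngp = int(act.sum())
    ps = float(np.sum(p * s))
    coarseness = 1.0 / max(ps, EPS)
    if Ngp > 1:
        ii = i[act]
        pp = p[act]
        ss = s[act]
        dij2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            np.sum(pp[:, None] * pp[None, :] * dij2) / (Ngp * (Ngp - 1)) * s.sum() / Nv
        )
        ipd = np.abs(ii[:, None] * pp[:, None] - ii[None, :] * pp[None, :])
        denom = float(ipd.sum())
        busyness = ps / denom if denom > EPS else 0.0
        dij = np.abs(ii[:, None] - ii[None, :])
        complexity = float(
            np.sum(
                dij
                * (pp[:, None] * ss[:, None] + pp[None, :] * ss[None, :])
                / (pp[:, None] + pp[None, :])
            )
            / Nv
        )
        strength = float(
            np.sum((pp[:, None] + pp[None, :]) * dij2) / max(s.sum(), EPS)
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# ---------------------------------------------------------------------------
# assembly


def texture_features(v: VolumeWithMask, n_levels: int = 32) -> dict[str, float]:
    """All 64 texture features of one masked volume.

    The volume is tight-cropped to the mask bounding box (exact for every
    family: matrices only see in-mask voxels and their 1-neighborhood),
    discretized at ``n_levels``, and passed through the five families.
    """
    v = crop_to_mask(v, margin=1)
    d = discretize(v, n_levels)
    out = {}
    out.update(first_order_features(d, v))
    out.update(glcm_features(glcm_matrix(d)))
    out.update(glrlm_features(d))
    out.update(glszm_features(d))
    out.update(ngtdm_features(d))
    return out


def extract_rfg(
    v: VolumeWithMask,
    n_levels: int = 32,
    wavelet_mode: str = "symmetric",
    _bank=None,
) -> pd.Series:
    """The 833-feature radiomic feature group for one ROI on one phase.

    Order: tumor volume, 64 original-image features, then 64 features per
    wavelet-filtered image (12 images, family-major, ratio ascending).
    Wavelet images share the input's ROI and are re-discretized
    independently.  ``_bank`` lets callers reuse a precomputed filter bank
    when extracting several ROIs from the same phase volume.
    """
    if not v.mask.any():
        raise ValueError("cannot extract an RFG from an empty ROI")
    feats: dict[str, float] = {"volume_mm3": v.mask_volume_mm3()}
    for name, val in texture_features(v, n_levels).items():
        feats[f"orig_{name}"] = val
    bank = _bank if _bank is not None else filter_bank(v, mode=wavelet_mode)
    for spec, fv in bank:
        fv = fv.with_mask(v.mask)
        for name, val in texture_features(fv, n_levels).items():
            feats[f"wav_{spec.label}_{name}"] = val
    s = pd.Series(feats)
    assert len(s) == 833
    return s
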