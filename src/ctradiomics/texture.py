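"""Gray-level texture matrices and their scalar features.

All four matrix families operate on a :class:`~ctradiomics.volume.DiscretizedROI`
whose ``levels`` array is 0 outside the mask and ``1..Ng`` inside.  Offsets are
expressed in voxel units; spatial anisotropy of the grid is deliberately not
compensated here (spacing enters only through shape features).

Conventions
-----------
* GLCM and GLRLM use the 13 unique 3D directions at Chebyshev distance 1,
  pooled into a single matrix before features are computed.
* The GLCM is symmetrized (each ordered voxel pair contributes twice) and
  normalized to probabilities.
* Run percentage (RP) is normalized per direction, ``Nr / (Nd * Nv)``, so that
  it stays in (0, 1] for any pooled direction set; zone percentage is
  ``Nz / Nv``.
* Entropies default to log base 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glzlm_matrix",
    "glzlm_features",
    "ngldm_features",
]

#: The 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
)

_LOG = {2: np.log2, 10: np.log10, "e": np.log}


def _log(base):
    try:
        return _LOG[base]
    except KeyError:
        raise ValueError(f"log base must be one of 2, 10, 'e'; got {base!r}")


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Return (levels at p, levels at p+offset) for all in-bounds voxel pairs."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, levels.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a = levels[tuple(sl_a)].ravel()
    b = levels[tuple(sl_b)].ravel()
    keep = (a > 0) & (b > 0)
    return a[keep], b[keep]


def glcm_matrix(
    roi: DiscretizedROI,
    distance: int = 1,
    directions=DIRECTIONS_13,
) -> np.ndarray:
    """Symmetrized, direction-pooled co-occurrence probability matrix.

    Returns an ``(Ng, Ng)`` array summing to 1; all-zero if no voxel pair
    exists at any offset.
    """
    if not directions:
        raise ValueError("directions must be nonempty")
    ng = roi.n_levels
    counts = np.zeros((ng, ng), dtype=float)
    for d in directions:
        off = tuple(int(distance) * c for c in d)
        a, b = _shifted_pairs(roi.levels, off)
        if a.size:
            np.add.at(counts, (a - 1, b - 1), 1.0)
    counts = counts + counts.T  # symmetrize: each unordered pair counted both ways
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features(
    roi: DiscretizedROI,
    distance: int = 1,
    directions=DIRECTIONS_13,
    log_base=2,
) -> dict:
    """Six co-occurrence features: homogeneity, energy, contrast, correlation,
    entropy, dissimilarity.

    ``correlation`` is NaN (flagged undefined) when the marginal variance is
    zero; all features are NaN with the ``empty`` flag when no voxel pair
    exists at the requested offsets.
    """
    p = glcm_matrix(roi, distance, directions)
    out: dict = {"flags": {}}
    if p.sum() == 0:
        out["flags"]["empty"] = True
        for k in ("homogeneity", "energy", "contrast", "correlation", "entropy", "dissimilarity"):
            out[k] = np.nan
        return out
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    out["homogeneity"] = float((p / (1.0 + diff)).sum())
    out["energy"] = float((p * p).sum())
    out["contrast"] = float((diff**2 * p).sum())
    out["dissimilarity"] = float((diff * p).sum())
    nz = p[p > 0]
    out["entropy"] = float(-(nz * _log(log_base)(nz)).sum())
    px = p.sum(axis=1)  # symmetric: both marginals identical
    mu = float((i * px).sum())
    var = float((((i - mu) ** 2) * px).sum())
    if var <= 0:
        out["correlation"] = np.nan
        out["flags"]["correlation_undefined"] = True
    else:
        out["correlation"] = float((((ii - mu) * (jj - mu)) * p).sum() / var)
    return out


def _runs_for_direction(levels: np.ndarray, offset: tuple[int, int, int]):
    """Gray level and length of every maximal run along ``offset``.

    A run starts at a voxel whose predecessor along the offset is outside the
    grid, outside the mask, or of a different level; it extends while the
    successor matches.  Vectorized over runs (loop bounded by the longest run).
    """
    inmask = levels > 0
    shape = levels.shape
    # predecessor lookup: start voxels have no matching predecessor
    prev_same = np.zeros(shape, dtype=bool)
    a, b = [], []
    for d, n in zip(offset, shape):
        if d >= 0:
            a.append(slice(d, n))
            b.append(slice(0, n - d))
        else:
            a.append(slice(0, n + d))
            b.append(slice(-d, n))
    core = levels[tuple(a)]
    pred = levels[tuple(b)]
    prev_same[tuple(a)] = (core == pred) & (core > 0)
    starts = np.argwhere(inmask & ~prev_same)
    if starts.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    gray = levels[tuple(starts.T)]
    lengths = np.ones(len(starts), dtype=np.int64)
    off = np.asarray(offset)
    pos = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt = pos[active] + off
        ok = np.all((nxt >= 0) & (nxt < np.asarray(shape)), axis=1)
        idx = active[ok]
        nxt = nxt[ok]
        same = levels[tuple(nxt.T)] == gray[idx]
        idx = idx[same]
        if idx.size == 0:
            break
        pos[idx] += off
        lengths[idx] += 1
        active = idx
    return gray, lengths


def glrlm_matrix(roi: DiscretizedROI, directions=DIRECTIONS_13) -> np.ndarray:
    """Run-length count matrix ``(Ng, Lmax)`` summed over directions."""
    ng = roi.n_levels
    all_gray, all_len = [], []
    for d in directions:
        g, ln = _runs_for_direction(roi.levels, d)
        all_gray.append(g)
        all_len.append(ln)
    gray = np.concatenate(all_gray)
    length = np.concatenate(all_len)
    lmax = int(length.max()) if length.size else 1
    mat = np.zeros((ng, lmax), dtype=float)
    np.add.at(mat, (gray - 1, length - 1), 1.0)
    return mat


def _run_family_features(mat: np.ndarray, n_voxels: int, n_dirs: int, prefix: str) -> dict:
    """Galloway-family statistics shared by GLRLM (runs) and GLZLM (zones).

    ``prefix`` selects the output naming; the percentage feature is
    normalized by ``n_dirs * n_voxels``.
    """
    ng, lmax = mat.shape
    n_total = mat.sum()
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, lmax + 1, dtype=float)[None, :]
    s = {
        "short": float((mat / l**2).sum() / n_total),
        "long": float((mat * l**2).sum() / n_total),
        "low": float((mat / i**2).sum() / n_total),
        "high": float((mat * i**2).sum() / n_total),
        "short_low": float((mat / (i**2 * l**2)).sum() / n_total),
        "short_high": float((mat * i**2 / l**2).sum() / n_total),
        "long_low": float((mat * l**2 / i**2).sum() / n_total),
        "long_high": float((mat * i**2 * l**2).sum() / n_total),
        "glnu": float((mat.sum(axis=1) ** 2).sum() / n_total),
        "lnu": float((mat.sum(axis=0) ** 2).sum() / n_total),
        "pct": float(n_total / (n_dirs * n_voxels)),
    }
    if prefix == "run":
        keys = ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLNU_r", "RLNU", "RP")
    else:
        keys = ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLNU_z", "ZLNU", "ZP")
    order = ("short", "long", "low", "high", "short_low", "short_high", "long_low", "long_high", "glnu", "lnu", "pct")
    return {k: s[o] for k, o in zip(keys, order)}


def glrlm_features(roi: DiscretizedROI, directions=DIRECTIONS_13) -> dict:
    """Eleven run-length features (SRE ... RP) from the pooled matrix."""
    mat = glrlm_matrix(roi, directions)
    return _run_family_features(mat, roi.n_voxels, len(directions), "run")


def glzlm_matrix(roi: DiscretizedROI, connectivity: int = 26) -> np.ndarray:
    """Zone-size count matrix ``(Ng, Smax)``.

    Zones are connected components of equal gray level at 6- or
    26-connectivity.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    ng = roi.n_levels
    levels = roi.levels
    sizes_by_gray: list[tuple[int, int]] = []
    for g in np.unique(levels[levels > 0]):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n:
            counts = np.bincount(lab.ravel())[1:]
            sizes_by_gray.extend((int(g), int(c)) for c in counts)
    smax = max(c for _, c in sizes_by_gray)
    mat = np.zeros((ng, smax), dtype=float)
    for g, c in sizes_by_gray:
        mat[g - 1, c - 1] += 1.0
    return mat


def glzlm_features(roi: DiscretizedROI, connectivity: int = 26) -> dict:
    """Eleven zone-size features (SZE ... ZP)."""
    mat = glzlm_matrix(roi, connectivity)
    return _run_family_features(mat, roi.n_voxels, 1, "zone")


def ngldm_features(roi: DiscretizedROI, epsilon: float = 1e-6) -> dict:
    """Amadasun–King neighborhood gray-level difference features.

    For each in-mask voxel with at least one in-mask 26-neighbor, the absolute
    deviation of its level from the mean level of those neighbors is
    accumulated per gray level (``s_i``).  Coarseness saturates at ``1/epsilon``
    when every deviation is zero (single occupied level), flagged; contrast is
    0 by convention in that case.
    """
    levels = roi.levels
    inmask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(levels.astype(float) * inmask, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(inmask.astype(float), kernel, mode="constant", cval=0.0)
    valid = inmask & (nbr_cnt > 0)
    out: dict = {"flags": {}}
    if not valid.any():
        out["flags"]["empty"] = True
        out["coarseness"] = np.nan
        out["contrast"] = np.nan
        return out
    abar = nbr_sum[valid] / nbr_cnt[valid]
    lv = levels[valid]
    dev = np.abs(lv - abar)
    ng = roi.n_levels
    s = np.zeros(ng)
    np.add.at(s, lv - 1, dev)
    n = int(valid.sum())
    n_i = np.bincount(lv - 1, minlength=ng).astype(float)
    p = n_i / n
    occupied = np.flatnonzero(n_i)
    ngp = occupied.size
    out["coarseness"] = float(1.0 / (epsilon + (p * s).sum()))
    if ngp <= 1:
        out["contrast"] = 0.0
        out["flags"]["saturated"] = True
        return out
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pij = p[:, None] * p[None, :]
    out["contrast"] = float(((pij * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))) * (s.sum() / n))
    if (p * s).sum() == 0:
        out["flags"]["saturated"] = True
    return out
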