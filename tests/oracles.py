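"""Independent brute-force references for the texture feature families.

Everything here is written as plain nested loops over voxels, pairs, lattice
lines or flood-fill queues — deliberately naive and structurally unlike the
vectorized implementations under test, so that agreement is evidence of
correctness rather than shared code.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque

import numpy as np


def _in_bounds(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def oracle_glcm(levels: np.ndarray, ng: int, directions, distance: int = 1, log_base: float = 2.0):
    """Pair-enumeration GLCM features (symmetrized, direction-pooled)."""
    shape = levels.shape
    counts = defaultdict(float)
    offsets = []
    for d in directions:
        off = tuple(distance * c for c in d)
        offsets.append(off)
        offsets.append(tuple(-c for c in off))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for off in offsets:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _in_bounds(q, shape) and levels[q] > 0:
                        counts[(a, levels[q])] += 1.0
    total = sum(counts.values())
    out = {}
    if total == 0:
        return None
    p = {k: v / total for k, v in counts.items()}
    out["homogeneity"] = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    out["energy"] = sum(v * v for v in p.values())
    out["contrast"] = sum((i - j) ** 2 * v for (i, j), v in p.items())
    out["dissimilarity"] = sum(abs(i - j) * v for (i, j), v in p.items())
    out["entropy"] = -sum(v * math.log(v, log_base) for v in p.values() if v > 0)
    px = defaultdict(float)
    for (i, j), v in p.items():
        px[i] += v
    mu = sum(i * v for i, v in px.items())
    var = sum((i - mu) ** 2 * v for i, v in px.items())
    if var <= 0:
        out["correlation"] = float("nan")
    else:
        out["correlation"] = sum((i - mu) * (j - mu) * v for (i, j), v in p.items()) / var
    return out


def _run_zone_formulas(mat: dict, n_total: float, n_voxels: int, n_dirs: int, prefix: str):
    """Shared Galloway formulas from a {(gray, length): count} dict."""
    def sm(f):
        return sum(f(i, l) * c for (i, l), c in mat.items()) / n_total

    glnu = defaultdict(float)
    lnu = defaultdict(float)
    for (i, l), c in mat.items():
        glnu[i] += c
        lnu[l] += c
    base = {
        "short": sm(lambda i, l: 1.0 / l**2),
        "long": sm(lambda i, l: float(l**2)),
        "low": sm(lambda i, l: 1.0 / i**2),
        "high": sm(lambda i, l: float(i**2)),
        "short_low": sm(lambda i, l: 1.0 / (i**2 * l**2)),
        "short_high": sm(lambda i, l: i**2 / l**2),
        "long_low": sm(lambda i, l: l**2 / i**2),
        "long_high": sm(lambda i, l: float(i**2 * l**2)),
        "glnu": sum(v**2 for v in glnu.values()) / n_total,
        "lnu": sum(v**2 for v in lnu.values()) / n_total,
        "pct": n_total / (n_dirs * n_voxels),
    }
    if prefix == "run":
        keys = ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLNU_r", "RLNU", "RP")
    else:
        keys = ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLNU_z", "ZLNU", "ZP")
    order = ("short", "long", "low", "high", "short_low", "short_high", "long_low", "long_high", "glnu", "lnu", "pct")
    return {k: base[o] for k, o in zip(keys, order)}


def oracle_glrlm(levels: np.ndarray, directions):
    """Line-walking run enumeration: every lattice line per direction is
    traversed start to end, splitting runs at mask gaps and level changes."""
    shape = levels.shape
    mat = defaultdict(float)
    for d in directions:
        # line starts: voxels whose predecessor along d is outside the grid
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _in_bounds(prev, shape):
                        continue
                    # walk the whole line
                    p = (x, y, z)
                    cur_level, cur_len = 0, 0
                    while _in_bounds(p, shape):
                        lv = levels[p]
                        if lv == cur_level and lv > 0:
                            cur_len += 1
                        else:
                            if cur_level > 0:
                                mat[(cur_level, cur_len)] += 1
                            cur_level, cur_len = lv, (1 if lv > 0 else 0)
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    if cur_level > 0:
                        mat[(cur_level, cur_len)] += 1
    n_voxels = int((levels > 0).sum())
    n_total = sum(mat.values())
    return _run_zone_formulas(mat, n_total, n_voxels, len(directions), "run")


def oracle_glzlm(levels: np.ndarray, connectivity: int = 26):
    """Flood-fill zone enumeration."""
    shape = levels.shape
    if connectivity == 26:
        nbrs = [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros(shape, dtype=bool)
    mat = defaultdict(float)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = levels[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    p = queue.popleft()
                    size += 1
                    for d in nbrs:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _in_bounds(q, shape) and not seen[q] and levels[q] == g:
                            seen[q] = True
                            queue.append(q)
                mat[(int(g), size)] += 1
    n_voxels = int((levels > 0).sum())
    n_total = sum(mat.values())
    return _run_zone_formulas(mat, n_total, n_voxels, 1, "zone")


def oracle_ngldm(levels: np.ndarray, ng: int, epsilon: float = 1e-6):
    """Per-voxel neighborhood-averaging reference (Amadasun-King)."""
    shape = levels.shape
    s = defaultdict(float)
    n_i = defaultdict(int)
    n = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lv = levels[x, y, z]
                if lv == 0:
                    continue
                nb = []
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        for c in (-1, 0, 1):
                            if (a, b, c) == (0, 0, 0):
                                continue
                            q = (x + a, y + b, z + c)
                            if _in_bounds(q, shape) and levels[q] > 0:
                                nb.append(levels[q])
                if not nb:
                    continue
                n += 1
                n_i[int(lv)] += 1
                s[int(lv)] += abs(lv - sum(nb) / len(nb))
    if n == 0:
        return None
    p = {i: n_i[i] / n for i in n_i}
    coarse = 1.0 / (epsilon + sum(p[i] * s[i] for i in p))
    occ = sorted(p)
    if len(occ) <= 1:
        return {"coarseness": coarse, "contrast": 0.0}
    num = sum(p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ)
    contrast = (num / (len(occ) * (len(occ) - 1))) * (sum(s.values()) / n)
    return {"coarseness": coarse, "contrast": contrast}


def oracle_histogram(x: np.ndarray, n_bins: int, log_base: float = 2.0):
    """Moment-formula and hand-binned histogram reference."""
    x = [float(v) for v in x]
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    out = {}
    if m2 == 0:
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
        out["entropy_H"] = 0.0
        out["energy_H"] = 1.0
        return out
    out["skewness"] = m3 / m2**1.5
    out["kurtosis"] = m4 / m2**2
    lo, hi = min(x), max(x)
    counts = [0] * n_bins
    for v in x:
        b = int((v - lo) / (hi - lo) * n_bins)
        counts[min(b, n_bins - 1)] += 1
    p = [c / n for c in counts]
    out["entropy_H"] = -sum(q * math.log(q, log_base) for q in p if q > 0)
    out["energy_H"] = sum(q * q for q in p)
    return out


def oracle_auc(scores, labels):
    """Exhaustive positive-negative pair enumeration with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    tot = 0.0
    for a in pos:
        for b in neg:
            tot += 1.0 if a > b else (0.5 if a == b else 0.0)
    return tot / (len(pos) * len(neg))
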