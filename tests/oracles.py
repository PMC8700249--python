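"""Independent brute-force oracles for the texture engines.

Everything here is written as literal per-voxel / per-matrix-cell Python
loops, deliberately sharing no code path with the package implementation:
co-occurrence by scanning every voxel against every direction, runs by
walking whole grid lines, zones by breadth-first flood fill, and the index
formulas transcribed term by term.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if (d[2], d[1], d[0]) > (0, 0, 0)]


def _in(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def oracle_glcm(levels, mask, directions=HALF_13):
    shape = levels.shape
    per_dir = []
    for d in directions:
        counts = defaultdict(float)
        for v in np.argwhere(mask):
            w = tuple(v + d)
            v = tuple(v)
            if _in(shape, w) and mask[w]:
                counts[(levels[v], levels[w])] += 1
                counts[(levels[w], levels[v])] += 1
        if not counts:
            continue
        total = sum(counts.values())
        p = {k: c / total for k, c in counts.items()}
        mu_i = sum(i * pij for (i, _), pij in p.items())
        mu_j = sum(j * pij for (_, j), pij in p.items())
        var_i = sum((i - mu_i) ** 2 * pij for (i, _), pij in p.items())
        var_j = sum((j - mu_j) ** 2 * pij for (_, j), pij in p.items())
        if var_i > 0 and var_j > 0:
            corr = sum(
                (i - mu_i) * (j - mu_j) * pij for (i, j), pij in p.items()
            ) / math.sqrt(var_i * var_j)
        else:
            corr = 1.0
        ent10 = -sum(pij * math.log10(pij) for pij in p.values() if pij > 0)
        per_dir.append(
            {
                "GLCM_Homogeneity": sum(pij / (1 + abs(i - j)) for (i, j), pij in p.items()),
                "GLCM_Energy": sum(pij**2 for pij in p.values()),
                "GLCM_Contrast": sum((i - j) ** 2 * pij for (i, j), pij in p.items()),
                "GLCM_Correlation": corr,
                "GLCM_Entropy_log10": ent10,
                "GLCM_Entropy_log2": ent10 / math.log10(2),
                "GLCM_Dissimilarity": sum(abs(i - j) * pij for (i, j), pij in p.items()),
            }
        )
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


def oracle_ngldm(levels, mask):
    shape = levels.shape
    entries = []  # (level, neighbourhood average)
    for v in map(tuple, np.argwhere(mask)):
        nb = [
            levels[tuple(np.add(v, d))]
            for d in ALL_26
            if _in(shape, np.add(v, d)) and mask[tuple(np.add(v, d))]
        ]
        if nb:
            entries.append((int(levels[v]), sum(nb) / len(nb)))
    n = len(entries)
    s = defaultdict(float)
    cnt = defaultdict(int)
    for g, avg in entries:
        s[g] += abs(g - avg)
        cnt[g] += 1
    p = {g: c / n for g, c in cnt.items()}
    ps = sum(p[g] * s[g] for g in p)
    coarseness = min(1.0 / ps, 1e6) if ps > 0 else 1e6
    ng = len(p)
    if ng > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in p for j in p)
            / (ng * (ng - 1))
            * (sum(s.values()) / n)
        )
        denom = sum(abs(i * p[i] - j * p[j]) for i in p for j in p)
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


def _grid_lines(shape, d):
    """All maximal grid lines along direction d, as voxel sequences."""
    starts = []
    for v in np.ndindex(shape):
        prev = tuple(np.subtract(v, d))
        if not _in(shape, prev):
            starts.append(v)
    for s in starts:
        line = []
        v = s
        while _in(shape, v):
            line.append(v)
            v = tuple(np.add(v, d))
        yield line


def _runs_on_line(line, levels, mask):
    """Maximal equal-level in-mask runs on one grid line."""
    runs = []
    current = None  # (level, length)
    for v in line:
        if not mask[v]:
            if current:
                runs.append(current)
            current = None
        elif current and levels[v] == current[0]:
            current = (current[0], current[1] + 1)
        else:
            if current:
                runs.append(current)
            current = (int(levels[v]), 1)
    if current:
        runs.append(current)
    return runs


def _matrix_indices(cells, prefix, size_key):
    """Literal Galloway/Thibault index formulas on {(level, size): count}."""
    nr = sum(cells.values())
    out = {}
    out[f"{prefix}_S{size_key}E"] = sum(c / (s * s) for (_, s), c in cells.items()) / nr
    out[f"{prefix}_L{size_key}E"] = sum(c * s * s for (_, s), c in cells.items()) / nr
    out[f"{prefix}_LG{size_key}E" if prefix == "GLZLM" else f"{prefix}_LGRE"] = (
        sum(c / (g * g) for (g, _), c in cells.items()) / nr
    )
    out[f"{prefix}_HG{size_key}E" if prefix == "GLZLM" else f"{prefix}_HGRE"] = (
        sum(c * g * g for (g, _), c in cells.items()) / nr
    )
    out[f"{prefix}_S{size_key}LGE"] = (
        sum(c / (g * g * s * s) for (g, s), c in cells.items()) / nr
    )
    out[f"{prefix}_S{size_key}HGE"] = (
        sum(c * g * g / (s * s) for (g, s), c in cells.items()) / nr
    )
    out[f"{prefix}_L{size_key}LGE"] = (
        sum(c * s * s / (g * g) for (g, s), c in cells.items()) / nr
    )
    out[f"{prefix}_L{size_key}HGE"] = (
        sum(c * g * g * s * s for (g, s), c in cells.items()) / nr
    )
    by_g = defaultdict(float)
    by_s = defaultdict(float)
    for (g, s), c in cells.items():
        by_g[g] += c
        by_s[s] += c
    out[f"{prefix}_GLNU"] = sum(v * v for v in by_g.values()) / nr
    out[f"{prefix}_{'ZLNU' if prefix == 'GLZLM' else 'RLNU'}"] = (
        sum(v * v for v in by_s.values()) / nr
    )
    return out


def oracle_glrlm(levels, mask, directions=HALF_13):
    per_dir = []
    for d in directions:
        cells = defaultdict(int)
        for line in _grid_lines(levels.shape, d):
            for g, length in _runs_on_line(line, levels, mask):
                cells[(g, length)] += 1
        idx = _matrix_indices(cells, "GLRLM", "R")
        per_dir.append(idx)
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


def oracle_glzlm(levels, mask):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    cells = defaultdict(int)
    n_zones = 0
    for v in map(tuple, np.argwhere(mask)):
        if seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in ALL_26:
                w = tuple(np.add(u, d))
                if _in(shape, w) and mask[w] and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        cells[(int(g), size)] += 1
        n_zones += 1
    out = _matrix_indices(cells, "GLZLM", "Z")
    out["GLZLM_ZP"] = n_zones / int(mask.sum())
    return out


def random_region(rng, max_side=6, max_levels=8):
    """A random blob-ish mask and level grid, guaranteed to have a pair."""
    while True:
        shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
        mask = rng.random(shape) < 0.7
        if mask.sum() < 2:
            continue
        levels = np.zeros(shape, dtype=np.int64)
        levels[mask] = rng.integers(1, max_levels + 1, int(mask.sum()))
        # need at least one neighbouring in-mask pair for the GLCM
        ok = False
        for v in map(tuple, np.argwhere(mask)):
            for d in ALL_26:
                w = tuple(np.add(v, d))
                if _in(shape, w) and mask[w]:
                    ok = True
                    break
            if ok:
                break
        if ok:
            return levels, mask
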