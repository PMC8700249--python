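"""Grey-level texture matrices and their indices.

All four families operate on an integer grey-level grid (levels 1..n inside
the region, 0 outside) plus a boolean mask of the same shape:

* GLCM — symmetric co-occurrence of level pairs at Chebyshev distance 1,
  one matrix per direction, indices averaged over the 13 unique 3-D
  directions (directions without a single in-mask pair are skipped);
* NGLDM — per-level accumulated absolute difference between a voxel and the
  mean level of its in-mask 26-neighbourhood (coarseness / contrast /
  busyness in the Amadasun–King formulation);
* GLRLM — maximal collinear runs of equal level, per direction, indices
  averaged over the 13 directions;
* GLZLM — 26-connected zones of equal level, one matrix per region.

Degenerate-value conventions (fixed so no feature is ever missing):
a zero-variance direction contributes Correlation = 1; a constant region has
NGLDM Contrast = Busyness = 0 and Coarseness capped at 1e6 (the literal
formula diverges); see each function's docstring.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_features",
    "ngldm_features",
    "glrlm_features",
    "glzlm_features",
]

# the 13 unique direction offsets (dx, dy, dz): one of each +/- pair,
# canonicalized so that (dz, dy, dx) is lexicographically positive
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_COARSENESS_CAP = 1e6


class DegenerateRegionError(ValueError):
    """The region cannot support the requested texture matrix."""


def _crop(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Crop both grids to the mask bounding box with a 1-voxel zero pad."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    lev = np.pad(levels[sl], 1)
    msk = np.pad(mask[sl], 1)
    return lev, msk


def _shifted(arr: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """``out[v] = arr[v + d]`` with zero fill (arrays are pre-padded)."""
    return np.roll(arr, shift=(-d[0], -d[1], -d[2]), axis=(0, 1, 2))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log10(p)).sum())


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    """Direction-averaged grey-level co-occurrence indices.

    For each direction the matrix counts ordered in-mask voxel pairs at unit
    offset in both orientations (symmetric). Indices: homogeneity
    sum p/(1+|i-j|), energy sum p^2, contrast sum (i-j)^2 p, correlation
    sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j), entropies (log10 and log2)
    and dissimilarity sum |i-j| p. Directions without a single in-mask pair
    are skipped from the average.
    """
    lev, msk = _crop(levels, mask)
    per_dir: list[dict[str, float]] = []
    for d in directions:
        lev_b = _shifted(lev, d)
        valid = msk & _shifted(msk, d)
        if not valid.any():
            continue
        a = lev[valid]
        b = lev_b[valid]
        nmax = int(max(a.max(), b.max()))
        m = np.zeros((nmax + 1, nmax + 1), dtype=np.float64)
        np.add.at(m, (a, b), 1.0)
        m = m + m.T  # symmetric: each pair counted in both orientations
        p = m / m.sum()
        i = np.arange(nmax + 1, dtype=np.float64)[:, None]
        j = np.arange(nmax + 1, dtype=np.float64)[None, :]
        pi = p.sum(axis=1)
        mu_i = float((np.arange(nmax + 1) * pi).sum())
        var_i = float(((np.arange(nmax + 1) - mu_i) ** 2 * pi).sum())
        # matrix is symmetric, so the j-marginal equals the i-marginal
        if var_i > 0:
            corr = float((((i - mu_i) * (j - mu_i) * p).sum()) / var_i)
        else:
            corr = 1.0
        ent10 = _entropy(p.ravel())
        per_dir.append(
            {
                "GLCM_Homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
                "GLCM_Energy": float((p**2).sum()),
                "GLCM_Contrast": float(((i - j) ** 2 * p).sum()),
                "GLCM_Correlation": corr,
                "GLCM_Entropy_log10": ent10,
                "GLCM_Entropy_log2": ent10 / np.log10(2.0),
                "GLCM_Dissimilarity": float((np.abs(i - j) * p).sum()),
            }
        )
    if not per_dir:
        raise DegenerateRegionError("region has no neighbouring voxel pair in any direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def ngldm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Amadasun–King coarseness, contrast and busyness.

    For every in-mask voxel with at least one in-mask 26-neighbour, the
    neighbourhood average ``A_k`` is the mean level over the available
    in-mask neighbours. With ``p_g`` the level probabilities over those N
    voxels and ``s_g = sum_{k: level=g} |g - A_k|``:

    * coarseness = 1 / sum_g p_g s_g          (capped at 1e6)
    * contrast   = [sum_{g,h} p_g p_h (g-h)^2 / (Ng (Ng-1))] * [sum_g s_g / N]
    * busyness   = sum_g p_g s_g / sum_{g,h: p>0} |g p_g - h p_h|   (0 if the
      denominator vanishes, e.g. constant regions)
    """
    lev, msk = _crop(levels, mask)
    nbr_sum = np.zeros(lev.shape, dtype=np.float64)
    nbr_cnt = np.zeros(lev.shape, dtype=np.float64)
    for d in DIRECTIONS_13:
        for sign in (1, -1):
            dd = (sign * d[0], sign * d[1], sign * d[2])
            nbr_sum += _shifted(lev.astype(np.float64) * msk, dd)
            nbr_cnt += _shifted(msk.astype(np.float64), dd)
    use = msk & (nbr_cnt > 0)
    g = lev[use].astype(np.float64)
    avg = nbr_sum[use] / nbr_cnt[use]
    n = g.size
    gmax = int(g.max())
    s = np.zeros(gmax + 1)
    cnt = np.zeros(gmax + 1)
    np.add.at(s, g.astype(int), np.abs(g - avg))
    np.add.at(cnt, g.astype(int), 1.0)
    p = cnt / n
    present = p > 0
    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, _COARSENESS_CAP) if ps > 0 else _COARSENESS_CAP
    ng = int(present.sum())
    if ng > 1:
        gi = np.arange(gmax + 1, dtype=np.float64)
        pij = p[:, None] * p[None, :] * (gi[:, None] - gi[None, :]) ** 2
        contrast = float(pij.sum() / (ng * (ng - 1)) * (s.sum() / n))
        gp = gi[present] * p[present]
        denom = float(np.abs(gp[:, None] - gp[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


def _runs_along(lev: np.ndarray, msk: np.ndarray, d: tuple[int, int, int]) -> dict[tuple[int, int], int]:
    """Counts of maximal equal-level in-mask runs along direction ``d``."""
    prev_msk = _shifted(msk, (-d[0], -d[1], -d[2]))
    prev_lev = _shifted(lev, (-d[0], -d[1], -d[2]))
    starts = msk & (~prev_msk | (prev_lev != lev))
    counts: dict[tuple[int, int], int] = {}
    shape = lev.shape
    for x, y, z in np.argwhere(starts):
        g = lev[x, y, z]
        length = 1
        nx, ny, nz = x + d[0], y + d[1], z + d[2]
        while (
            0 <= nx < shape[0]
            and 0 <= ny < shape[1]
            and 0 <= nz < shape[2]
            and msk[nx, ny, nz]
            and lev[nx, ny, nz] == g
        ):
            length += 1
            nx, ny, nz = nx + d[0], ny + d[1], nz + d[2]
        key = (int(g), length)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _rlm_indices(counts: dict[tuple[int, int], int], prefix: str) -> dict[str, float]:
    items = np.array([(g, ln, c) for (g, ln), c in counts.items()], dtype=np.float64)
    g, ln, r = items[:, 0], items[:, 1], items[:, 2]
    nr = r.sum()
    p = r / nr
    by_g: dict[float, float] = {}
    by_l: dict[float, float] = {}
    for gi, li, ri in zip(g, ln, r):
        by_g[gi] = by_g.get(gi, 0.0) + ri
        by_l[li] = by_l.get(li, 0.0) + ri
    return {
        f"{prefix}_SRE": float((p / ln**2).sum()),
        f"{prefix}_LRE": float((p * ln**2).sum()),
        f"{prefix}_LGRE": float((p / g**2).sum()),
        f"{prefix}_HGRE": float((p * g**2).sum()),
        f"{prefix}_SRLGE": float((p / (g**2 * ln**2)).sum()),
        f"{prefix}_SRHGE": float((p * g**2 / ln**2).sum()),
        f"{prefix}_LRLGE": float((p * ln**2 / g**2).sum()),
        f"{prefix}_LRHGE": float((p * g**2 * ln**2).sum()),
        f"{prefix}_GLNU": float(sum(v**2 for v in by_g.values()) / nr),
        f"{prefix}_RLNU": float(sum(v**2 for v in by_l.values()) / nr),
    }


def glrlm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    """Direction-averaged run-length indices (Galloway/Chu formulation).

    Ten indices: SRE, LRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU,
    RLNU. Run percentage is not part of the panel.
    """
    lev, msk = _crop(levels, mask)
    per_dir = []
    for d in directions:
        counts = _runs_along(lev, msk, d)
        per_dir.append(_rlm_indices(counts, "GLRLM"))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def glzlm_features(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Size-zone indices on 26-connected equal-level zones (Thibault).

    Analogous to the run-length indices with zone size in place of run
    length, plus zone percentage ZP = (number of zones) / (region voxels).
    """
    lev, msk = _crop(levels, mask)
    structure = np.ones((3, 3, 3), dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    n_vox = int(msk.sum())
    for g in np.unique(lev[msk]):
        lab, n_lab = ndimage.label(msk & (lev == g), structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for size in sizes:
            key = (int(g), int(size))
            counts[key] = counts.get(key, 0) + 1
    idx = _rlm_indices(counts, "GLZLM")
    out = {
        k.replace("_SRE", "_SZE")
        .replace("_LRE", "_LZE")
        .replace("_LGRE", "_LGZE")
        .replace("_HGRE", "_HGZE")
        .replace("_SRLGE", "_SZLGE")
        .replace("_SRHGE", "_SZHGE")
        .replace("_LRLGE", "_LZLGE")
        .replace("_LRHGE", "_LZHGE")
        .replace("_RLNU", "_ZLNU"): v
        for k, v in idx.items()
    }
    n_zones = sum(counts.values())
    out["GLZLM_ZP"] = n_zones / n_vox
    return out
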