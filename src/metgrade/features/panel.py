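"""The frozen 44-feature panel.

Order is fixed (conventional, histogram, shape, GLCM, NGLDM, GLRLM, GLZLM)
so that downstream selection — which breaks ties by column order — is
reproducible. Conventional and shape features are computed on raw SUV values
and physical geometry; histogram and all texture families on the resampled
grey levels.
"""

from __future__ import annotations

import numpy as np

from ..discretization import BinningConfig, discretize
from ..volume import RegionMask, SuvVolume
from .firstorder import conventional_features, histogram_features, shape_features
from .texture import glcm_features, glrlm_features, glzlm_features, ngldm_features

__all__ = ["FEATURE_NAMES", "extract_all"]

FEATURE_NAMES: tuple[str, ...] = (
    "CONVmin",
    "CONVmean",
    "CONVmax",
    "CONV_TLG",
    "CONV_RIM",
    "HISTO_Skewness",
    "HISTO_Kurtosis",
    "HISTO_Energy",
    "HISTO_Entropy_log10",
    "SHAPE_Sphericity",
    "SHAPE_Compacity",
    "SHAPE_Volume_mL",
    "SHAPE_Volume_voxels",
    "GLCM_Homogeneity",
    "GLCM_Energy",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_Entropy_log10",
    "GLCM_Entropy_log2",
    "GLCM_Dissimilarity",
    "NGLDM_Coarseness",
    "NGLDM_Contrast",
    "NGLDM_Busyness",
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_LGRE",
    "GLRLM_HGRE",
    "GLRLM_SRLGE",
    "GLRLM_SRHGE",
    "GLRLM_LRLGE",
    "GLRLM_LRHGE",
    "GLRLM_GLNU",
    "GLRLM_RLNU",
    "GLZLM_SZE",
    "GLZLM_LZE",
    "GLZLM_LGZE",
    "GLZLM_HGZE",
    "GLZLM_SZLGE",
    "GLZLM_SZHGE",
    "GLZLM_LZLGE",
    "GLZLM_LZHGE",
    "GLZLM_GLNU",
    "GLZLM_ZLNU",
    "GLZLM_ZP",
)


def extract_all(
    vol: SuvVolume, mask: RegionMask, binning: BinningConfig = BinningConfig()
) -> dict[str, float]:
    """Compute all 44 panel features for one (volume, region) pair.

    Returns a dict whose keys equal :data:`FEATURE_NAMES` in order.
    """
    levels = discretize(vol, mask, binning)
    dense = mask.to_dense()
    in_mask_levels = levels[dense]
    out: dict[str, float] = {}
    out.update(conventional_features(vol, mask))
    out.update(histogram_features(in_mask_levels))
    out.update(shape_features(mask, vol.spacing))
    out.update(glcm_features(levels, dense))
    out.update(ngldm_features(levels, dense))
    out.update(glrlm_features(levels, dense))
    out.update(glzlm_features(levels, dense))
    ordered = {name: float(out[name]) for name in FEATURE_NAMES}
    assert len(ordered) == 44
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return ordered
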