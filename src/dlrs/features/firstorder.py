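"""First-order intensity statistics of the in-mask region.

Order statistics and moments are computed on the raw (windowed) intensities;
entropy and uniformity on the discretized gray-level histogram, so they are
the only members that change across discretization settings.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import TooFewPixelsError
from .discretize import LabelImage

FIRSTORDER_FEATURE_NAMES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    labels: LabelImage, raw: np.ndarray, pixel_area: float = 1.0
) -> dict[str, float]:
    """The 18 first-order features.

    ``raw`` holds the in-mask intensity values (same ordering as
    ``labels.in_mask_labels()``); ``pixel_area`` (mm^2) scales total energy.
    Skewness and kurtosis follow the population-moment convention
    (m3/m2^1.5 and m4/m2^2, no excess subtraction), defined as 0 for a
    constant region.
    """
    v = np.asarray(raw, dtype=np.float64).ravel()
    if v.size < 2:
        raise TooFewPixelsError(f"first-order features need >= 2 pixels, got {v.size}")
    lab = labels.in_mask_labels()
    counts = np.bincount(lab, minlength=labels.n_bins + 1)[1:]
    p = counts / counts.sum()
    p_nz = p[p > 0]

    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    m3 = float(((v - mean) ** 3).mean())
    m4 = float(((v - mean) ** 4).mean())
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    in_robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(in_robust - in_robust.mean()).mean()) if in_robust.size else 0.0

    energy = float((v**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * float(pixel_area),
        "Entropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "Minimum": float(v.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(v.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float((p_nz**2).sum()),
    }
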