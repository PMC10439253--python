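"""Assembly of the 361-feature radiomics vector and z-score standardization.

The bank is 9 shape features (computed once, in physical units) plus, for each
of the four discretization settings (8, 16, 32, 64 gray levels), 18 first-order,
24 GLCM, 16 GLRLM, 16 GLSZM and 14 GLDM features: 9 + 4 x 88 = 361. Feature
names and ordering are frozen by the versioned feature dictionary so vectors
are schema-stable across runs and checkpoints.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..exceptions import ConfigError, DataError
from ..volumes import CTVolume, ROIMask, select_largest_slice
from .discretize import DEFAULT_BIN_SETTINGS, DiscretizationSetting, discretize
from .firstorder import FIRSTORDER_FEATURE_NAMES, firstorder_features
from .shape2d import SHAPE_FEATURE_NAMES, shape2d_features
from .texture import (
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
)

logger = logging.getLogger(__name__)

FEATURE_DICT_VERSION = "1.0"

FAMILY_COUNTS = {
    "shape": 9,
    "firstorder": 72,
    "glcm": 96,
    "glrlm": 64,
    "glszm": 64,
    "gldm": 56,
}

_PER_SETTING = (
    ("firstorder", FIRSTORDER_FEATURE_NAMES),
    ("glcm", GLCM_FEATURE_NAMES),
    ("glrlm", GLRLM_FEATURE_NAMES),
    ("glszm", GLSZM_FEATURE_NAMES),
    ("gldm", GLDM_FEATURE_NAMES),
)


def feature_names(settings=DEFAULT_BIN_SETTINGS) -> list[str]:
    """Canonical ordered feature names: shape first, then per-setting families."""
    names = list(SHAPE_FEATURE_NAMES)
    for bins in settings:
        for family, feats in _PER_SETTING:
            names.extend(f"{family}_{f}_{bins}" for f in feats)
    return names


def feature_dictionary(settings=DEFAULT_BIN_SETTINGS) -> dict:
    """The versioned feature dictionary (serializable to JSON)."""
    entries = []
    for name in feature_names(settings):
        if name.startswith("shape_"):
            family, bins = "shape", None
            feat = name.split("_", 1)[1]
        else:
            family, feat, bins_s = name.split("_")
            bins = int(bins_s)
        entries.append({"name": name, "family": family, "feature": feat, "bins": bins})
    return {
        "version": FEATURE_DICT_VERSION,
        "settings": list(settings),
        "n_features": len(entries),
        "features": entries,
    }


def write_feature_dictionary(path, settings=DEFAULT_BIN_SETTINGS) -> None:
    with open(path, "w") as fh:
        json.dump(feature_dictionary(settings), fh, indent=1)


@dataclass
class RadiomicsVector:
    """Ordered, named 361-feature vector for one case."""

    values: np.ndarray
    names: list[str]
    case_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise DataError("values and names must align")
        if len(set(self.names)) != len(self.names):
            raise DataError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)


def extract_radiomics(
    vol: CTVolume,
    mask: ROIMask,
    settings=DEFAULT_BIN_SETTINGS,
    case_id: str = "",
) -> RadiomicsVector:
    """Compute the full radiomics vector on the largest-tumor axial slice.

    The volume should already be resampled and window-normalized; features are
    computed at the volume's native in-plane resolution (no 64x64 resize), so
    shape features carry physical units.
    """
    if vol.shape != mask.shape:
        raise DataError(f"case {case_id}: volume {vol.shape} != mask {mask.shape}")
    settings = tuple(int(b) for b in settings)
    k = select_largest_slice(mask)
    img2 = vol.voxels[:, :, k]
    m2 = mask.voxels[:, :, k].astype(bool)
    # crop to the mask bounding box: texture matrices only see in-mask pixels
    xs, ys = np.nonzero(m2)
    sl = (slice(xs.min(), xs.max() + 1), slice(ys.min(), ys.max() + 1))
    img2, m2 = img2[sl], m2[sl]
    dx, dy = vol.spacing[:2]

    try:
        out: dict[str, float] = dict(shape2d_features(m2, (dx, dy)))
        raw = img2[m2]
        for bins in settings:
            li = discretize(img2, m2, DiscretizationSetting(bins))
            for family, values in (
                ("firstorder", firstorder_features(li, raw, pixel_area=dx * dy)),
                ("glcm", glcm_features(li)),
                ("glrlm", glrlm_features(li)),
                ("glszm", glszm_features(li)),
                ("gldm", gldm_features(li)),
            ):
                out.update({f"{family}_{k_}_{bins}": v for k_, v in values.items()})
    except DataError as err:
        raise type(err)(f"case {case_id}: {err}") from err

    names = feature_names(settings)
    return RadiomicsVector(
        values=np.array([out[n] for n in names]), names=names, case_id=case_id
    )


@dataclass
class StandardizationStats:
    """Per-feature mean/std fitted on a training set (population denominator n)."""

    mean: np.ndarray
    std: np.ndarray
    names: list[str]
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.constant is None:
            self.constant = self.std == 0
        if np.any(self.std < 0):
            raise DataError("standard deviations must be non-negative")


def zscore_fit(vectors: list[RadiomicsVector]) -> StandardizationStats:
    """Fit per-feature mean and std (denominator n) on training vectors."""
    if len(vectors) < 2:
        raise DataError(f"z-score fit needs >= 2 training vectors, got {len(vectors)}")
    names = vectors[0].names
    if any(v.names != names for v in vectors[1:]):
        raise DataError("feature name schemas differ across training vectors")
    X = np.stack([v.values for v in vectors])
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # ddof=0
    n_const = int((std == 0).sum())
    if n_const:
        logger.warning("%d features are constant on the training set; mapped to 0", n_const)
    return StandardizationStats(mean=mean, std=std, names=list(names))


def zscore_apply(vector: RadiomicsVector, stats: StandardizationStats) -> RadiomicsVector:
    """Standardize one vector; zero-variance features map to exactly 0."""
    if vector.names != stats.names:
        raise DataError("feature schema does not match standardization stats")
    safe = np.where(stats.constant, 1.0, stats.std)
    z = (vector.values - stats.mean) / safe
    z[stats.constant] = 0.0
    return RadiomicsVector(values=z, names=vector.names, case_id=vector.case_id)
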