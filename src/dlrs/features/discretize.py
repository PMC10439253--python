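"""Gray-level discretization: the substrate for all texture matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import ConfigError, TooFewPixelsError

DEFAULT_BIN_SETTINGS: tuple[int, ...] = (8, 16, 32, 64)


@dataclass(frozen=True)
class DiscretizationSetting:
    """Number of equal-width gray levels used to quantize in-mask intensities."""

    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigError(f"n_bins must be >= 2, got {self.n_bins}")


@dataclass
class LabelImage:
    """Discretized 2D image: integer labels 1..n_bins inside the mask, 0 outside."""

    labels: np.ndarray
    mask: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.labels.shape != self.mask.shape:
            raise ConfigError("labels and mask shapes differ")
        inside = self.labels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ConfigError("in-mask labels must lie in 1..n_bins")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def in_mask_labels(self) -> np.ndarray:
        return self.labels[self.mask]


def discretize(
    slice2d: np.ndarray, mask: np.ndarray, setting: DiscretizationSetting
) -> LabelImage:
    """Equal-width binning of in-mask intensities into ``n_bins`` levels.

    Bin edges span the in-mask min..max; a constant region maps entirely to
    label 1. Requires at least 2 in-mask pixels.
    """
    img = np.asarray(slice2d, dtype=np.float64)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ConfigError("slice and mask shapes differ")
    vals = img[m]
    if vals.size < 2:
        raise TooFewPixelsError(f"need >= 2 in-mask pixels, got {vals.size}")
    lo, hi = float(vals.min()), float(vals.max())
    labels = np.zeros(img.shape, dtype=np.int64)
    if hi == lo:
        labels[m] = 1
    else:
        scaled = (img[m] - lo) / (hi - lo) * setting.n_bins
        labels[m] = np.clip(np.floor(scaled).astype(np.int64) + 1, 1, setting.n_bins)
    return LabelImage(labels=labels, mask=m, n_bins=setting.n_bins)
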