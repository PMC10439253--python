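"""Volumetric CT handling: reading, resampling, HU windowing, model-input construction.

Conventions: voxel arrays are indexed ``(x, y, z)`` with axial slices along the
third axis; ``spacing`` is ``(dx, dy, dz)`` in millimetres; all coordinates are
0-based voxel indices unless a physical unit is stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .exceptions import (
    ConfigError,
    DataError,
    DegenerateVolumeError,
    EmptyMaskError,
    GridMismatchError,
)

__all__ = [
    "CTVolume",
    "ROIMask",
    "WindowSpec",
    "ModelInput",
    "read_case",
    "resample_volume",
    "window_normalize",
    "select_largest_slice",
    "build_input",
]


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield-unit intensities with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in HU (or unitless in [0, 1] after window normalization).
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm; strictly positive.
    origin : tuple of float
        Physical coordinates of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise DataError("CTVolume requires a non-empty 3D voxel grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be 3 positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("CTVolume intensities must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """Binary tumor mask aligned voxel-for-voxel with a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or vox.size == 0:
            raise DataError("ROIMask requires a non-empty 3D voxel grid")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise DataError("ROIMask voxels must be binary (0/1)")
        self.voxels = vox.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def foreground_count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class WindowSpec:
    """HU window for intensity normalization; default [-150, 150] highlights soft tissue."""

    lo: float = -150.0
    hi: float = 150.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"window requires lo < hi, got ({self.lo}, {self.hi})")


@dataclass
class ModelInput:
    """Three-channel S x S network input built from one axial slice.

    Channels: (0) window-normalized full CT slice, (1) the same slice with
    background zeroed outside the tumor, (2) the binary tumor mask. Channel 1
    always equals channel 0 multiplied elementwise by channel 2.
    """

    channels: np.ndarray
    slice_index: int
    case_id: str = ""

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 3 or ch.shape[0] != 3 or ch.shape[1] != ch.shape[2]:
            raise DataError(f"channels must be (3, S, S), got {ch.shape}")
        if ch.min() < 0 or ch.max() > 1:
            raise DataError("channel values must lie in [0, 1]")
        if not np.all(np.isin(np.unique(ch[2]), (0.0, 1.0))):
            raise DataError("mask channel must be binary")
        if not np.allclose(ch[1], ch[0] * ch[2]):
            raise DataError("channel 2 must equal channel 1 * mask channel")
        self.channels = ch

    @property
    def size(self) -> int:
        return self.channels.shape[1]


def _spacing_from_affine(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_case(image_path, mask_path, spacing_tol: float = 1e-3) -> tuple[CTVolume, ROIMask]:
    """Read an aligned NIfTI image/mask pair.

    Raises :class:`GridMismatchError` if shapes or spacings differ beyond
    ``spacing_tol`` and :class:`EmptyMaskError` for an all-zero mask. No
    registration is attempted: the mask must share the image grid exactly.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    vox = np.asanyarray(img.dataobj, dtype=np.float64)
    mvox = np.asanyarray(msk.dataobj)
    if vox.shape != mvox.shape:
        raise GridMismatchError(
            f"image shape {vox.shape} != mask shape {mvox.shape} "
            f"({image_path} vs {mask_path})"
        )
    sp_i, sp_m = _spacing_from_affine(img), _spacing_from_affine(msk)
    if max(abs(a - b) for a, b in zip(sp_i, sp_m)) > spacing_tol:
        raise GridMismatchError(f"image spacing {sp_i} != mask spacing {sp_m}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    mvox = (np.asarray(mvox) > 0.5).astype(np.uint8)
    if mvox.sum() == 0:
        raise EmptyMaskError(f"mask {mask_path} has no foreground voxel")
    return (
        CTVolume(vox, sp_i, origin),
        ROIMask(mvox, sp_i, origin),
    )


def _resample_grid(vol_shape, old_spacing, new_spacing):
    new_shape = tuple(
        max(1, int(round(n * o / t)))
        for n, o, t in zip(vol_shape, old_spacing, new_spacing)
    )
    # voxel-center coordinates of the new grid expressed in old index units
    coords = np.meshgrid(
        *[np.arange(ns) * t / o for ns, t, o in zip(new_shape, new_spacing, old_spacing)],
        indexing="ij",
    )
    return new_shape, coords


def resample_volume(vol: CTVolume, target_spacing, *, is_mask: bool = False) -> CTVolume:
    """Resample to ``target_spacing`` (mm) with trilinear interpolation.

    Masks are resampled with nearest-neighbor (``is_mask=True``) so they stay
    binary. Resampling to the volume's own spacing is the identity.
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ConfigError(f"target spacing must be positive, got {target}")
    if any(n < 2 for n in vol.shape):
        raise DegenerateVolumeError(f"cannot resample volume of shape {vol.shape}")
    if np.allclose(target, vol.spacing):
        return CTVolume(vol.voxels.copy(), target, vol.origin)
    _, coords = _resample_grid(vol.shape, vol.spacing, target)
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(
        vol.voxels, np.stack([c.ravel() for c in coords]), order=order, mode="nearest"
    ).reshape(coords[0].shape)
    return CTVolume(out, target, vol.origin)


def resample_mask(mask: ROIMask, target_spacing) -> ROIMask:
    """Nearest-neighbor mask resampling onto the target grid."""
    as_vol = CTVolume(mask.voxels.astype(np.float64), mask.spacing, mask.origin)
    res = resample_volume(as_vol, target_spacing, is_mask=True)
    return ROIMask((res.voxels > 0.5).astype(np.uint8), res.spacing, res.origin)


def window_normalize(vol: CTVolume, w: WindowSpec = WindowSpec()) -> CTVolume:
    """Clip to the HU window and rescale linearly to [0, 1]."""
    out = np.clip((vol.voxels - w.lo) / (w.hi - w.lo), 0.0, 1.0)
    return CTVolume(out, vol.spacing, vol.origin)


def select_largest_slice(mask: ROIMask) -> int:
    """Index of the axial slice with the largest in-slice tumor area (mm^2).

    Ties are broken toward the lowest index.
    """
    if mask.foreground_count() == 0:
        raise EmptyMaskError("cannot select a slice from an empty mask")
    dx, dy, _ = mask.spacing
    areas = mask.voxels.sum(axis=(0, 1)).astype(np.float64) * dx * dy
    return int(np.argmax(areas))


def _square_crop_bounds(m2: np.ndarray, margin: float) -> tuple[int, int, int, int]:
    xs, ys = np.nonzero(m2)
    x0, x1 = xs.min(), xs.max() + 1
    y0, y1 = ys.min(), ys.max() + 1
    side = max(x1 - x0, y1 - y0)
    pad = int(round(margin * side))
    half = (side + 2 * pad) / 2.0
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    bx0 = int(np.floor(cx - half))
    bx1 = int(np.ceil(cx + half))
    by0 = int(np.floor(cy - half))
    by1 = int(np.ceil(cy + half))
    nx, ny = m2.shape
    return max(bx0, 0), min(bx1, nx), max(by0, 0), min(by1, ny)


def build_input(
    vol: CTVolume,
    mask: ROIMask,
    w: WindowSpec = WindowSpec(),
    size: int = 64,
    margin: float = 0.25,
    case_id: str = "",
) -> ModelInput:
    """Construct the three-channel network input from a volume/mask pair.

    Pipeline: window-normalize, pick the largest-tumor axial slice, crop the
    square mask bounding box expanded by ``margin`` (clipped at the image
    border), then resize image channels bilinearly and the mask channel with
    nearest-neighbor to ``size`` x ``size``.
    """
    if vol.shape != mask.shape:
        raise GridMismatchError(f"volume {vol.shape} and mask {mask.shape} differ")
    if size < 2:
        raise ConfigError("input size must be >= 2")
    k = select_largest_slice(mask)
    normed = window_normalize(vol, w)
    img2 = normed.voxels[:, :, k]
    m2 = mask.voxels[:, :, k]
    x0, x1, y0, y1 = _square_crop_bounds(m2, margin)
    img_crop = img2[x0:x1, y0:y1]
    m_crop = m2[x0:x1, y0:y1].astype(np.float64)
    img_rs = resize(
        img_crop, (size, size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    m_rs = resize(
        m_crop, (size, size), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    img_rs = np.clip(img_rs, 0.0, 1.0)
    m_rs = (m_rs > 0.5).astype(np.float64)
    channels = np.stack([img_rs, img_rs * m_rs, m_rs])
    return ModelInput(channels=channels, slice_index=k, case_id=case_id)
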