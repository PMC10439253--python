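"""Synthetic CT phantoms with class-dependent intratumoral texture.

Each case is a soft-tissue background volume (Gaussian noise around a mean
HU) containing one ellipsoidal tumor. The tumor's interior texture is a
Gaussian random field whose standard deviation and correlation length depend
on the binary class, and the class additionally shifts the tumor's mean HU.
The signal therefore lives in texture statistics, visible both to the
radiomics bank (e.g. GLCM contrast) and to the CNN branch, so the fusion
model's two pathways are exercised.

Defaults emulate a portal-venous abdominal scan at desk scale: 0.75 x 0.75 x
2.5 mm voxels, soft-tissue background around 40 HU, tumors of 6-14 mm radius,
and a texture contrast (sd 12 vs 35 HU, grain 3 vs 1.2 mm) strong enough for
planted-signal recovery in small cohorts. All HU values are clipped into
(-200, 300) by construction.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, InfeasibleGeometryError
from .volumes import CTVolume, ROIMask

__all__ = ["ClassEffects", "PhantomSpec", "PhantomCase", "generate_case",
           "generate_cases", "generate_cohort", "null_spec"]

HU_RANGE = (-200.0, 300.0)


@dataclass(frozen=True)
class ClassEffects:
    """How the binary TME class expresses itself inside the tumor."""

    mean_hu_shift: float = 15.0  # added to tumor mean for class 1
    texture_sd: tuple[float, float] = (12.0, 35.0)  # HU, per class
    texture_grain: tuple[float, float] = (3.0, 1.2)  # correlation length mm, per class

    def __post_init__(self) -> None:
        if min(self.texture_sd) < 0 or min(self.texture_grain) <= 0:
            raise ConfigError(f"invalid class effects {self}")


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (0.75, 0.75, 2.5)
    background_mean_hu: float = 40.0
    background_noise_sd: float = 8.0
    tumor_mean_hu: float = 70.0
    tumor_radius_mm: tuple[float, float] = (6.0, 14.0)
    axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    class_effects: ClassEffects = field(default_factory=ClassEffects)
    prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")
        if self.tumor_radius_mm[0] <= 0 or self.tumor_radius_mm[0] > self.tumor_radius_mm[1]:
            raise ConfigError(f"invalid tumor radius range {self.tumor_radius_mm}")
        lo, hi = self.axis_ratio_range
        if not 0 < lo <= hi <= 1:
            raise ConfigError(f"invalid axis ratio range {self.axis_ratio_range}")


def null_spec(seed: int = 0) -> PhantomSpec:
    """Classes indistinguishable: no mean shift, identical texture."""
    return PhantomSpec(
        class_effects=ClassEffects(mean_hu_shift=0.0, texture_sd=(20.0, 20.0),
                                   texture_grain=(2.0, 2.0)),
        seed=seed,
    )


@dataclass
class PhantomCase:
    volume: CTVolume
    mask: ROIMask
    label: int
    case_id: str
    provenance: dict


def _grf(shape, sigma_vox, sd_target: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field: smoothed white noise rescaled to a target sd."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    s = smooth.std()
    return smooth * (sd_target / s) if s > 0 else smooth


def generate_case(spec: PhantomSpec, rng: np.random.Generator,
                  case_id: str = "case") -> PhantomCase:
    """One phantom: background + ellipsoidal tumor with class-dependent texture."""
    shape = spec.volume_shape
    sp = np.asarray(spec.spacing)
    extent = (np.asarray(shape) - 1) * sp  # physical mm

    label = int(rng.random() < spec.prevalence)

    r_base = rng.uniform(*spec.tumor_radius_mm)
    ratios = rng.uniform(*spec.axis_ratio_range, size=3)
    ratios[int(rng.integers(3))] = 1.0  # longest axis keeps the drawn radius
    radii = r_base * ratios  # mm, per axis

    margin = radii + sp  # keep the tumor fully interior
    if np.any(2 * margin >= extent):
        raise InfeasibleGeometryError(
            f"tumor radius {r_base:.1f} mm cannot fit volume extent {extent}"
        )
    center = np.array([rng.uniform(m, e - m) for m, e in zip(margin, extent)])

    background = spec.background_mean_hu + _grf(shape, 0.5, spec.background_noise_sd, rng)

    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)], indexing="ij")
    dist2 = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
    mask = (dist2 <= 1.0).astype(np.uint8)

    grain_mm = spec.class_effects.texture_grain[label]
    sd = spec.class_effects.texture_sd[label]
    sigma_vox = grain_mm / sp  # anisotropic: correlation length is physical
    texture = _grf(shape, sigma_vox, sd, rng)

    tumor_mean = spec.tumor_mean_hu + spec.class_effects.mean_hu_shift * label
    vox = background.copy()
    inside = mask.astype(bool)
    vox[inside] = tumor_mean + texture[inside]
    vox = np.clip(vox, HU_RANGE[0] + 1.0, HU_RANGE[1] - 1.0)

    provenance = {
        "label": label,
        "center_mm": center.tolist(),
        "radii_mm": radii.tolist(),
        "texture_sd": sd,
        "texture_grain_mm": grain_mm,
        "tumor_mean_hu": tumor_mean,
    }
    return PhantomCase(
        volume=CTVolume(vox, tuple(sp)),
        mask=ROIMask(mask, tuple(sp)),
        label=label,
        case_id=case_id,
        provenance=provenance,
    )


def generate_cases(spec: PhantomSpec, n: int) -> list[PhantomCase]:
    """In-memory cohort; deterministic for a fixed spec (including its seed)."""
    if n < 2:
        raise ConfigError("cohort needs n >= 2")
    rng = np.random.default_rng(spec.seed)
    return [generate_case(spec, rng, case_id=f"case_{i:04d}") for i in range(n)]


def generate_cohort(spec: PhantomSpec, n: int, out_dir) -> Path:
    """Write NIfTI volumes/masks plus a manifest CSV; returns the manifest path.

    Manifest columns: case_id, image_path, mask_path, label.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = generate_cases(spec, n)
    rows = []
    for case in cases:
        affine = np.diag(list(spec.spacing) + [1.0])
        img_path = out / f"{case.case_id}_image.nii"
        msk_path = out / f"{case.case_id}_mask.nii"
        nib.save(nib.Nifti1Image(case.volume.voxels.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(case.mask.voxels.astype(np.uint8), affine), msk_path)
        rows.append((case.case_id, str(img_path), str(msk_path), case.label))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "image_path", "mask_path", "label"])
        writer.writerows(rows)
    return manifest


def manifest_digest(manifest_path) -> str:
    """SHA-256 of the manifest plus every referenced volume (for determinism checks)."""
    h = hashlib.sha256()
    manifest_path = Path(manifest_path)
    h.update(manifest_path.read_bytes())
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            for key in ("image_path", "mask_path"):
                h.update(np.asanyarray(nib.load(row[key]).dataobj).tobytes())
    return h.hexdigest()
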