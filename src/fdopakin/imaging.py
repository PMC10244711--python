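"""4D dynamic-image handling: VOI TAC extraction, SUV images, display
smoothing, and a sphere phantom generator for round-trip tests.

Images are plain voxel arrays (x, y, z, frame) with an isotropic-or-not
voxel size and a frame schedule; masks must share the grid exactly (no
resampling).  Smoothing is display-only and is never applied before TAC
extraction.  NIfTI-1 I/O goes through nibabel with the frame schedule as a
sidecar JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .tac import (
    FrameSchedule,
    SubjectMeta,
    TimeActivityCurve,
    ValidationError,
    build_schedule,
)

__all__ = [
    "DynamicImage",
    "RegionMask",
    "extract_tac",
    "mean_frame_image",
    "gaussian_smooth",
    "suv_image",
    "make_phantom",
    "save_dynamic_image",
    "load_dynamic_image",
    "save_mask",
    "load_mask",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DynamicImage:
    """4D activity array (kBq/mL), voxel size in mm, and the frame schedule."""

    voxels: np.ndarray
    voxel_size_mm: tuple
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if vox.ndim != 4:
            raise ValidationError("dynamic image must be 4-D (x, y, z, frame)")
        if vox.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"frame axis length {vox.shape[3]} != schedule frame count {self.schedule.n_frames}"
            )
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel_size_mm must be three positive values")


@dataclass(frozen=True)
class RegionMask:
    """3D boolean VOI mask on the same grid as the image it is applied to."""

    voxels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 3:
            raise ValidationError("mask must be 3-D")
        if not vox.any():
            raise ValidationError(f"mask {self.label!r} selects no voxels")


def _check_grids(image: DynamicImage, mask: RegionMask) -> None:
    if image.voxels.shape[:3] != mask.voxels.shape:
        raise ValidationError(
            f"mask grid {mask.voxels.shape} != image grid {image.voxels.shape[:3]}"
        )


def extract_tac(image: DynamicImage, mask: RegionMask) -> TimeActivityCurve:
    """Per-frame mean activity over the masked voxels."""
    _check_grids(image, mask)
    activity = image.voxels[mask.voxels].mean(axis=0)
    return TimeActivityCurve(image.schedule, activity, region_label=mask.label)


def mean_frame_image(image: DynamicImage, start_s: float, end_s: float) -> np.ndarray:
    """Duration-weighted mean over frames whose mid-time lies in [start, end]."""
    mids = image.schedule.mid_times
    sel = (mids >= start_s) & (mids <= end_s)
    if not sel.any():
        raise ValidationError(f"no frame mid-times inside [{start_s}, {end_s}] s")
    w = image.schedule.frame_durations[sel]
    return (image.voxels[..., sel] * w).sum(axis=-1) / w.sum()


def gaussian_smooth(
    volume: np.ndarray, fwhm_mm, voxel_size_mm, fwhm_is_sigma: bool = False
) -> np.ndarray:
    """Separable Gaussian filter for display; per-axis sigma (voxels) =
    fwhm / (2·sqrt(2·ln2)) / voxel_size, or fwhm taken directly as sigma
    with ``fwhm_is_sigma``."""
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValidationError("fwhm_mm must be >= 0 per axis")
    sigma_mm = fwhm if fwhm_is_sigma else fwhm * FWHM_TO_SIGMA
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_mm / vox)


def suv_image(
    image: DynamicImage, meta: SubjectMeta, start_s: float, end_s: float
) -> np.ndarray:
    """3D SUV image (g/mL): time-averaged activity / (dose / weight)."""
    return mean_frame_image(image, start_s, end_s) / (meta.injected_dose_MBq / meta.weight_kg)


def make_phantom(
    region_tacs: dict,
    geometry: dict,
    grid_shape=(40, 40, 40),
    voxel_size_mm=(0.4, 0.4, 0.4),
) -> tuple[DynamicImage, list]:
    """Voxel phantom: spheres carrying region TACs on a zero background.

    ``geometry`` maps region label -> (center_mm triple, radius_mm); every
    label must have a TAC in ``region_tacs``.  Regions may not overlap.
    Returns the dynamic image and masks that exactly match the painted
    voxels.
    """
    labels = list(geometry)
    missing = [lab for lab in labels if lab not in region_tacs]
    if missing:
        raise ValidationError(f"no TAC supplied for region(s) {missing}")
    schedules = [region_tacs[lab].schedule for lab in labels]
    if any(not schedules[0].same_grid(s) for s in schedules[1:]):
        raise ValidationError("all region TACs must share one frame schedule")
    schedule = schedules[0]
    vox = np.asarray(voxel_size_mm, dtype=float)
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * v for n, v in zip(grid_shape, vox)], indexing="ij"),
        axis=-1,
    )
    image = np.zeros((*grid_shape, schedule.n_frames))
    claimed = np.zeros(grid_shape, dtype=bool)
    masks = []
    for lab in labels:
        center, radius = geometry[lab]
        inside = np.sum((coords - np.asarray(center, dtype=float)) ** 2, axis=-1) <= radius**2
        if not inside.any():
            raise ValidationError(f"region {lab!r} contains no voxels on this grid")
        if (inside & claimed).any():
            raise ValidationError(f"region {lab!r} overlaps a previous region")
        claimed |= inside
        image[inside] = region_tacs[lab].activity
        masks.append(RegionMask(inside, label=lab))
    return DynamicImage(image, tuple(vox), schedule), masks


# --------------------------------------------------------------------------
# NIfTI I/O (schedule as sidecar JSON)


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_dynamic_image(image: DynamicImage, path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(image.voxels, _affine(image.voxel_size_mm)), str(path))
    sidecar = path.with_name(path.name.split(".")[0] + "_frames.json")
    sidecar.write_text(
        json.dumps(
            {
                "frame_starts_s": image.schedule.frame_starts.tolist(),
                "frame_durations_s": image.schedule.frame_durations.tolist(),
            },
            indent=2,
        )
    )


def load_dynamic_image(path, schedule_json=None) -> DynamicImage:
    path = Path(path)
    img = nib.load(str(path))
    if schedule_json is None:
        schedule_json = path.with_name(path.name.split(".")[0] + "_frames.json")
    meta = json.loads(Path(schedule_json).read_text())
    schedule = FrameSchedule(
        np.asarray(meta["frame_starts_s"], dtype=float),
        np.asarray(meta["frame_durations_s"], dtype=float),
    )
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicImage(np.asarray(img.dataobj, dtype=float), voxel_size, schedule)


def save_mask(mask: RegionMask, path, voxel_size_mm=(0.4, 0.4, 0.4)) -> None:
    nib.save(
        nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(voxel_size_mm)), str(path)
    )


def load_mask(path, label: str) -> RegionMask:
    img = nib.load(str(path))
    return RegionMask(np.asarray(img.dataobj) > 0, label=label)
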