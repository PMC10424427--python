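"""Image/mask preparation and tumour sub-segmentation.

Volumes are held as plain numpy arrays with physical voxel spacing in mm.
Three region-of-interest (ROI) sets are derived per lesion:

* ``whole`` — the tumour mask as drawn;
* ``whole_high_low`` — whole plus an intensity split into high- and
  low-enhancing sub-regions;
* ``whole_rim_core`` — whole plus a core (deeper than ``depth_mm`` from the
  boundary, measured in physical mm) and the remaining rim shell.

All distances and thresholds are physical (mm); voxel indices are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "RoiSet",
    "load_nifti_pair",
    "save_roi_set",
    "resample_to_spacing",
    "erode_mask_mm",
    "split_core_rim",
    "subsegment_enhancement",
    "build_roi_sets",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid (Hounsfield units) with physical spacing.

    ``values`` is indexed ``[x, y, z]``; ``spacing`` is ``(dx, dy, dz)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")


@dataclass
class BinaryMask:
    """A 3D boolean mask on the same grid as its paired :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    empty_ok: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("BinaryMask requires a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if not self.empty_ok and not self.values.any():
            raise ValueError("mask has no foreground voxels (set empty_ok to allow)")

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass
class RoiSet:
    """Named collection of sub-segmentation masks for one lesion.

    ``name`` is one of ``whole``, ``whole_high_low``, ``whole_rim_core``.
    ``flags`` records degenerate outcomes (e.g. an empty core) so downstream
    feature tables can drop the lesion from that ROI set rather than impute.
    """

    name: str
    masks: dict[str, BinaryMask]
    params: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in {"whole", "whole_high_low", "whole_rim_core"}:
            raise ValueError(f"unknown ROI set name: {self.name}")

    @property
    def region_labels(self) -> list[str]:
        return list(self.masks)


def _check_aligned(image: ImageVolume, mask: BinaryMask) -> None:
    if image.values.shape != mask.values.shape or not np.allclose(
        image.spacing, mask.spacing
    ):
        raise ValueError("image and mask are not on the same grid")


# ---------------------------------------------------------------------------
# I/O


def load_nifti_pair(image_path: str, mask_path: str) -> tuple[ImageVolume, BinaryMask]:
    """Read an image/mask pair from NIfTI; spacing comes from the header."""
    import nibabel as nib

    img = nib.load(image_path)
    msk = nib.load(mask_path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    image = ImageVolume(np.asarray(img.dataobj, dtype=float), spacing)
    mask = BinaryMask(np.asarray(msk.dataobj) > 0.5, tuple(float(z) for z in msk.header.get_zooms()[:3]), empty_ok=True)
    _check_aligned(image, mask)
    return image, mask


def save_roi_set(roi_set: RoiSet, out_dir: str) -> None:
    """Write each region as a NIfTI label map plus a JSON provenance sidecar."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    for label, mask in roi_set.masks.items():
        affine = np.diag(list(mask.spacing) + [1.0])
        nib.save(
            nib.Nifti1Image(mask.values.astype(np.uint8), affine),
            os.path.join(out_dir, f"{roi_set.name}_{label}.nii.gz"),
        )
    sidecar = {
        "roi_set": roi_set.name,
        "regions": roi_set.region_labels,
        "params": roi_set.params,
        "flags": roi_set.flags,
    }
    with open(os.path.join(out_dir, f"{roi_set.name}.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


# ---------------------------------------------------------------------------
# Grid preparation


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK uses (z, y, x) array order
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def resample_to_spacing(
    image: ImageVolume,
    mask: BinaryMask,
    target_spacing: tuple[float, float, float],
) -> tuple[ImageVolume, BinaryMask]:
    """Resample an image/mask pair onto a grid with ``target_spacing`` (mm).

    The image is interpolated linearly in 3D.  The mask indicator is also
    interpolated linearly and re-binarized at 0.5, which preserves volume
    better than nearest-neighbour resampling.
    """
    _check_aligned(image, mask)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing must be > 0")

    old_shape = np.array(image.values.shape, dtype=float)
    old_spacing = np.array(image.spacing, dtype=float)
    new_shape = np.maximum(
        1, np.round(old_shape * old_spacing / np.array(target_spacing)).astype(int)
    )

    def _resample(values: np.ndarray, interpolator) -> np.ndarray:
        src = _to_sitk(values, image.spacing, image.origin)
        res = sitk.Resample(
            src,
            size=[int(n) for n in new_shape],
            transform=sitk.Transform(),
            interpolator=interpolator,
            outputOrigin=src.GetOrigin(),
            outputSpacing=target_spacing,
            outputDirection=src.GetDirection(),
            defaultPixelValue=float(values.min()),
        )
        return sitk.GetArrayFromImage(res).transpose(2, 1, 0)

    new_img = _resample(image.values, sitk.sitkLinear)
    ind = _resample(mask.values.astype(float), sitk.sitkLinear)
    return (
        ImageVolume(new_img, target_spacing, image.origin),
        BinaryMask(ind > 0.5, target_spacing, mask.origin, empty_ok=True),
    )


# ---------------------------------------------------------------------------
# Core / rim


def boundary_distance_mm(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance (mm) from each foreground voxel to the mask boundary.

    Computed with an anisotropic distance transform so that, e.g., 10 mm spans
    ten 1 mm in-plane voxels but only two 5 mm slices.
    """
    return ndimage.distance_transform_edt(mask.values, sampling=mask.spacing)


def erode_mask_mm(mask: BinaryMask, depth_mm: float) -> BinaryMask:
    """Keep foreground voxels strictly deeper than ``depth_mm`` from the boundary."""
    if depth_mm < 0:
        raise ValueError("depth_mm must be >= 0")
    if depth_mm == 0:
        return BinaryMask(mask.values.copy(), mask.spacing, mask.origin, empty_ok=True)
    core = boundary_distance_mm(mask) > depth_mm
    return BinaryMask(core, mask.spacing, mask.origin, empty_ok=True)


def split_core_rim(
    mask: BinaryMask, depth_mm: float
) -> tuple[BinaryMask, BinaryMask]:
    """Partition a mask into core (> ``depth_mm`` from boundary) and rim."""
    core = erode_mask_mm(mask, depth_mm)
    rim = BinaryMask(
        mask.values & ~core.values, mask.spacing, mask.origin, empty_ok=True
    )
    if core.is_empty:
        warnings.warn(
            f"core empty after {depth_mm} mm erosion: lesion too small for the "
            "core/rim ROI set",
            stacklevel=2,
        )
    return core, rim


# ---------------------------------------------------------------------------
# High / low enhancement


def subsegment_enhancement(
    image: ImageVolume,
    mask: BinaryMask,
    smoothing_sigma_mm: float = 2.0,
    min_component_cm3: float = 0.5,
    method: str = "otsu",
    degenerate_range_hu: float = 1.0,
) -> tuple[BinaryMask, BinaryMask]:
    """Split a tumour into high- and low-enhancing sub-regions.

    The intensity image is smoothed with a Gaussian of ``smoothing_sigma_mm``
    physical width, thresholded into two classes within the mask (Otsu or a
    2-component 1D k-means, ``method``), and connected components smaller than
    ``min_component_cm3`` are reassigned to the other class.  Near-constant
    tumours (intensity range below ``degenerate_range_hu``) degenerate to
    ``high = whole, low = empty``.

    Returns ``(high, low)`` with ``high ∪ low = mask`` and mean HU(high) ≥
    mean HU(low).
    """
    _check_aligned(image, mask)
    if mask.is_empty:
        raise ValueError("mask is empty")

    # normalized convolution: smooth inside the mask only, so background
    # intensities never bleed across the tumour boundary
    sigma_vox = [smoothing_sigma_mm / s for s in image.spacing]
    num = ndimage.gaussian_filter(np.where(mask.values, image.values, 0.0), sigma=sigma_vox)
    den = ndimage.gaussian_filter(mask.values.astype(float), sigma=sigma_vox)
    smoothed = np.where(mask.values, num / np.where(den > 0, den, 1.0), 0.0)
    vals = smoothed[mask.values]

    def _degenerate() -> tuple[BinaryMask, BinaryMask]:
        high = BinaryMask(mask.values.copy(), mask.spacing, mask.origin)
        low = BinaryMask(
            np.zeros_like(mask.values), mask.spacing, mask.origin, empty_ok=True
        )
        return high, low

    if np.ptp(vals) < degenerate_range_hu:
        return _degenerate()

    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(vals)
    elif method == "kmeans":
        from scipy.cluster.vq import kmeans2

        centers, assign = kmeans2(vals.astype(float), 2, minit="++", seed=0)
        thr = float(centers.mean())
    else:
        raise ValueError(f"unknown sub-segmentation method: {method}")

    high = mask.values & (smoothed > thr)
    low = mask.values & ~high

    # reassign small connected components (physical volume threshold)
    voxel_cm3 = float(np.prod(image.spacing)) / 1000.0
    min_vox = int(np.ceil(min_component_cm3 / voxel_cm3))
    for region, other in ((high, low), (low, high)):
        lab, n = ndimage.label(region)
        for i in range(1, n + 1):
            comp = lab == i
            if comp.sum() < min_vox:
                region &= ~comp
                other |= comp

    if not low.any() or not high.any():
        return _degenerate()
    if image.values[high].mean() < image.values[low].mean():
        high, low = low, high
    return (
        BinaryMask(high, mask.spacing, mask.origin, empty_ok=True),
        BinaryMask(low, mask.spacing, mask.origin, empty_ok=True),
    )


# ---------------------------------------------------------------------------


def build_roi_sets(
    image: ImageVolume,
    mask: BinaryMask,
    erode_depth_mm: float = 10.0,
    enhancement_params: dict | None = None,
) -> list[RoiSet]:
    """Build the three ROI sets evaluated per lesion.

    Returns ``[whole, whole_high_low, whole_rim_core]`` containing 1, 3 and 3
    regions respectively; degenerate sub-regions are flagged on the RoiSet.
    """
    _check_aligned(image, mask)
    whole = BinaryMask(mask.values.copy(), mask.spacing, mask.origin)

    sets = [RoiSet("whole", {"whole": whole})]

    high, low = subsegment_enhancement(image, mask, **(enhancement_params or {}))
    hl_flags = ["low_empty"] if low.is_empty else []
    sets.append(
        RoiSet(
            "whole_high_low",
            {"whole": whole, "high": high, "low": low},
            params=dict(enhancement_params or {}),
            flags=hl_flags,
        )
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        core, rim = split_core_rim(mask, erode_depth_mm)
    rc_flags = ["core_empty"] if core.is_empty else []
    sets.append(
        RoiSet(
            "whole_rim_core",
            {"whole": whole, "core": core, "rim": rim},
            params={"erode_depth_mm": erode_depth_mm},
            flags=rc_flags,
        )
    )
    return sets
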