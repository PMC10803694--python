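"""Volume preprocessing: isotropic resampling, lung segmentation, dilation.

Front end of the analysis: volumes are resampled to isotropic spacing
(linear interpolation for images, nearest neighbor for masks), the lungs are
segmented by Otsu thresholding plus interior connected components, and the
mask is dilated by a Euclidean ball to include the peri-lung region used as
the registration ROI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grid import BinaryMask, Geometry, ImageVolume

__all__ = ["resample_isotropic", "segment_lungs", "dilate_mask", "lung_volume"]


def resample_isotropic(
    image: ImageVolume, target_spacing_mm: float
) -> ImageVolume:
    """Resample to isotropic spacing, preserving physical extent.

    Output shape per axis is ``ceil(extent / target_spacing)`` (documented
    rounding rule).  Already-isotropic inputs at the target spacing are
    returned as a copy with identical grid and values.  Images use linear
    interpolation, masks nearest-neighbor.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if min(image.shape) < 2:
        raise ValueError("cannot resample a degenerate (single-slice) volume")
    spacing = np.asarray(image.spacing, dtype=float)
    if np.allclose(spacing, target_spacing_mm):
        return image.copy()

    extent = np.asarray(image.shape) * spacing
    new_shape = tuple(int(np.ceil(e / target_spacing_mm)) for e in extent)
    new_geom = Geometry(new_shape, (target_spacing_mm,) * 3, image.origin)

    # sample new voxel centers in the old index space
    axes = [
        (target_spacing_mm * np.arange(n)) / spacing[a]
        for a, n in enumerate(new_shape)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    is_mask = isinstance(image, BinaryMask)
    data = ndimage.map_coordinates(
        np.asarray(image.data, dtype=float),
        coords,
        order=0 if is_mask else 1,
        mode="nearest",
    )
    if is_mask:
        return BinaryMask((data > 0.5).astype(np.uint8), new_geom)
    return ImageVolume(data, new_geom)


def segment_lungs(image: ImageVolume, max_components: int = 2) -> BinaryMask:
    """Threshold-based lung segmentation for bimodal lung/body volumes.

    Otsu's threshold separates dark voxels (air + lung parenchyma) from the
    bright body; components connected to the volume border (outside air) are
    discarded, holes are filled, and the largest interior components (up to
    ``max_components``; the two lungs may form one component when they
    touch) are kept.
    """
    data = np.asarray(image.data, dtype=float)
    if np.ptp(data) < 1e-9:
        raise ValueError("cannot segment a constant image (no bimodality)")
    thr = threshold_otsu(data)
    low = data < thr

    # remove border-connected background
    labels, n = ndimage.label(low)
    if n < 1:
        raise ValueError("no low-intensity components found below Otsu threshold")
    border_labels = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=ax)
            border_labels.update(np.unique(face[face > 0]).tolist())
    interior = np.isin(labels, list(border_labels), invert=True) & low
    labels, n = ndimage.label(interior)
    if n < 1:
        raise ValueError("no interior lung component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:max_components] + 1
    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)
    return BinaryMask(mask.astype(np.uint8), image.geometry)


def dilate_mask(mask: BinaryMask, radius_voxels: int) -> BinaryMask:
    """Euclidean-ball dilation by ``radius_voxels``; radius 0 is identity.

    Implemented with the exact Euclidean distance transform of the mask
    complement (equivalent to dilation by a ball structuring element, but
    O(n) in the voxel count).
    """
    if radius_voxels < 0 or int(radius_voxels) != radius_voxels:
        raise ValueError("dilation radius must be a nonnegative integer")
    if radius_voxels == 0:
        return mask.copy()
    inside = mask.astype_bool()
    dist = ndimage.distance_transform_edt(~inside)
    out = dist <= radius_voxels
    return BinaryMask(out.astype(np.uint8), mask.geometry)


def lung_volume(mask: BinaryMask) -> float:
    """Mask volume in ml (voxel count x voxel volume)."""
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * mask.geometry.voxel_volume_mm3 / 1000.0
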