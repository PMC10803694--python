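"""Deformable and affine registration of respiratory phase pairs.

Conventions
-----------
The dense displacement field lives on the *fixed* (expiration) grid and
points toward *moving* (inspiration) space: for a fixed-grid point ``x`` the
corresponding moving-space point is ``x + u(x)`` (pull-back warping).  The
Jacobian analysis downstream is defined with respect to this convention, so
``det(I + grad u) > 1`` means local expansion from expiration to
inspiration.

Backends
--------
``builtin``
    Multi-resolution diffeomorphic demons (SimpleITK), deterministic given
    inputs and configuration.  Images are cropped to the ROI bounding box
    before registration; the recovered field is zeroed outside the ROI.
``external``
    Adapter contract: any callable ``f(fixed, moving, roi) -> (n,n,n,3)``
    array of mm displacements on the fixed grid.
``oracle``
    Pass-through of a supplied ground-truth field, unchanged — used to test
    downstream stages exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .grid import BinaryMask, Geometry, ImageVolume
from .qc import LandmarkSet

__all__ = [
    "DisplacementField",
    "AffineTransform",
    "RegistrationResult",
    "RegistrationConfig",
    "register_elastic",
    "register_affine",
    "transform_points",
    "warp_image",
]


@dataclass
class DisplacementField:
    """Dense (nx, ny, nz, 3) world-mm displacement on the fixed grid."""

    vectors: np.ndarray
    geometry: Geometry
    roi: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != tuple(self.geometry.shape) + (3,):
            raise ValueError(
                f"field shape {self.vectors.shape} != grid {self.geometry.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")
        if self.roi is not None and tuple(self.roi.shape) != tuple(self.geometry.shape):
            raise ValueError("ROI geometry does not match the field")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass(frozen=True)
class AffineTransform:
    """World-mm affine ``x -> matrix @ x + translation``."""

    matrix: tuple  # 3x3, row-major nested tuples
    translation: tuple

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(m)) <= 1e-8:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", tuple(map(tuple, m)))
        object.__setattr__(
            self, "translation", tuple(np.asarray(self.translation, dtype=float))
        )

    @property
    def linear(self) -> np.ndarray:
        return np.asarray(self.matrix)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts @ self.linear.T + np.asarray(self.translation)

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(tuple(map(tuple, inv)),
                               tuple(-inv @ np.asarray(self.translation)))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(tuple(map(tuple, np.eye(3))), (0.0, 0.0, 0.0))

    def to_matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class RegistrationConfig:
    """Builtin-backend settings (all deterministic)."""

    iterations: tuple[int, ...] = (150, 100, 60)  # per level, coarse -> fine
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas_mm: tuple[float, ...] = (4.0, 2.0, 0.0)  # image pyramid
    field_sigma_mm: float = 1.5  # total-field Gaussian regularization
    update_sigma_mm: float = 0.0  # update-field smoothing (0 = off)
    roi_margin_voxels: int = 4
    intensity_difference_threshold: float = 0.001


@dataclass
class RegistrationResult:
    displacement: DisplacementField
    backend: str
    converged: bool = True
    final_metric: float = float("nan")
    iterations_per_level: tuple = ()
    metric_per_level: tuple = ()


# ---------------------------------------------------------------------------
# SimpleITK interop (array axis 0/1/2 = world x/y/z; sitk stores z-fastest)
# ---------------------------------------------------------------------------

def _to_sitk(volume: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.asarray(volume.data, dtype=np.float64).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(float(s) for s in volume.geometry.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.geometry.origin))
    return img


def _field_from_sitk(img: sitk.Image, geometry: Geometry) -> np.ndarray:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3) with components (x, y, z)
    return np.ascontiguousarray(arr.transpose(2, 1, 0, 3))


def _smooth(img: sitk.Image, sigma_mm: float) -> sitk.Image:
    if sigma_mm <= 0:
        return img
    return sitk.SmoothingRecursiveGaussian(img, sigma_mm)


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    return sitk.Shrink(img, [int(factor)] * 3)


def _roi_bbox(roi: BinaryMask, margin: int) -> tuple[slice, slice, slice]:
    idx = np.argwhere(roi.astype_bool())
    if len(idx) == 0:
        raise ValueError("registration ROI is empty")
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, roi.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _crop(volume: ImageVolume, box) -> ImageVolume:
    data = volume.data[box]
    origin = volume.geometry.index_to_world([box[0].start, box[1].start, box[2].start])
    geom = Geometry(tuple(data.shape), volume.geometry.spacing, tuple(origin))
    return ImageVolume(np.asarray(data, dtype=float), geom)


def _builtin_demons(
    fixed: ImageVolume, moving: ImageVolume, roi: BinaryMask,
    config: RegistrationConfig,
) -> RegistrationResult:
    box = _roi_bbox(roi, config.roi_margin_voxels)
    f_img = _to_sitk(_crop(fixed, box))
    m_img = _to_sitk(_crop(moving, box))

    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(config.field_sigma_mm)
    if config.update_sigma_mm > 0:
        demons.SetSmoothUpdateField(True)
        demons.SetUpdateFieldStandardDeviations(config.update_sigma_mm)
    demons.SetIntensityDifferenceThreshold(config.intensity_difference_threshold)

    disp = None
    metrics, iters, improved = [], [], []
    trace: list[float] = []
    demons.AddCommand(sitk.sitkIterationEvent,
                      lambda: trace.append(float(demons.GetMetric())))
    levels = list(zip(config.shrink_factors, config.smoothing_sigmas_mm,
                      config.iterations))
    for shrink_factor, sigma_mm, n_iter in levels:
        f_lvl = _shrink(_smooth(f_img, sigma_mm), shrink_factor)
        m_lvl = _shrink(_smooth(m_img, sigma_mm), shrink_factor)
        if disp is None:
            disp = sitk.Image(f_lvl.GetSize(), sitk.sitkVectorFloat64, 3)
            disp.CopyInformation(f_lvl)
        else:
            disp = sitk.Resample(disp, f_lvl, sitk.Transform(),
                                 sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64)
        demons.SetNumberOfIterations(int(n_iter))
        trace.clear()
        disp = demons.Execute(f_lvl, m_lvl, disp)
        metrics.append(float(demons.GetMetric()))
        iters.append(int(demons.GetElapsedIterations()))
        # metric is resolution-specific: judge improvement within the level
        improved.append(len(trace) < 2 or trace[-1] <= trace[0])

    # resample the final field onto the full cropped-resolution grid
    disp = sitk.Resample(disp, f_img, sitk.Transform(),
                         sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64)
    crop_geom = Geometry(
        tuple(np.asarray(fixed.data[box].shape)), fixed.geometry.spacing,
        tuple(fixed.geometry.index_to_world([box[0].start, box[1].start, box[2].start])),
    )
    sub_field = _field_from_sitk(disp, crop_geom)

    vectors = np.zeros(tuple(fixed.geometry.shape) + (3,))
    vectors[box] = sub_field
    vectors[~roi.astype_bool()] = 0.0

    # non-convergence: similarity failed to improve over the finest level
    converged = improved[-1] if improved else True
    field_out = DisplacementField(vectors, fixed.geometry, roi=roi)
    return RegistrationResult(
        displacement=field_out, backend="builtin", converged=bool(converged),
        final_metric=metrics[-1], iterations_per_level=tuple(iters),
        metric_per_level=tuple(metrics),
    )


def register_elastic(
    fixed: ImageVolume,
    moving: ImageVolume,
    roi: BinaryMask,
    config: RegistrationConfig | None = None,
    backend: str = "builtin",
    oracle_field: DisplacementField | None = None,
    external_fn=None,
) -> RegistrationResult:
    """Recover the inspiration->expiration correspondence field on the ROI.

    See the module docstring for the field convention and backends.
    Non-convergence of the builtin backend is flagged in the result, never
    silently accepted.
    """
    if tuple(fixed.spacing) != tuple(moving.spacing):
        raise ValueError("fixed and moving volumes must share voxel spacing")
    if roi is not None and tuple(roi.shape) != tuple(fixed.shape):
        raise ValueError("ROI must live on the fixed grid")

    if backend == "oracle":
        if oracle_field is None:
            raise ValueError("oracle backend requires oracle_field")
        return RegistrationResult(displacement=oracle_field, backend="oracle",
                                  converged=True, final_metric=0.0)
    if backend == "external":
        if external_fn is None:
            raise ValueError("external backend requires external_fn")
        vectors = np.asarray(external_fn(fixed, moving, roi), dtype=float)
        fld = DisplacementField(vectors, fixed.geometry, roi=roi)
        return RegistrationResult(displacement=fld, backend="external")
    if backend == "builtin":
        if roi is None or roi.voxel_count == 0:
            raise ValueError("builtin backend requires a nonempty ROI")
        return _builtin_demons(fixed, moving, roi, config or RegistrationConfig())
    raise ValueError(f"unknown registration backend {backend!r}")


def write_field(path, field: DisplacementField) -> None:
    """Persist a displacement field as a 4D (x,y,z,3) NIfTI in mm."""
    import nibabel as nib

    aff = np.eye(4)
    aff[:3, :3] = np.diag(field.geometry.spacing)
    aff[:3, 3] = field.geometry.origin
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float32), aff)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_field(path, roi: BinaryMask | None = None) -> DisplacementField:
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    geom = Geometry(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing=tuple(float(s) for s in np.diag(aff[:3, :3])),
        origin=tuple(float(v) for v in aff[:3, 3]),
    )
    return DisplacementField(np.asanyarray(img.dataobj).astype(float), geom, roi=roi)


def _mask_moments(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(mask.astype_bool()).astype(float)
    if len(idx) == 0:
        raise ValueError("cannot register an empty mask")
    pts = mask.geometry.index_to_world(idx)
    centroid = pts.mean(axis=0)
    sigma = pts.std(axis=0)
    return centroid, sigma


def register_affine(fixed: BinaryMask, moving: BinaryMask) -> AffineTransform:
    """Mask-driven affine mapping fixed-space points to moving-space points.

    Deterministic moment matching: centroids align the translation and the
    per-axis second central moments set an axis-aligned scaling.  For the
    ellipsoidal lung masks this analysis uses, moment matching is optimal up
    to voxelization.  Accepts masks (the mask-overlap registration the
    common-space step needs); pass ``segment_lungs(image)`` output when
    starting from images.
    """
    c_f, s_f = _mask_moments(fixed)
    c_m, s_m = _mask_moments(moving)
    if np.any(s_f <= 0) or np.any(s_m <= 0):
        raise ValueError("degenerate mask: zero spatial variance on an axis")
    scale = s_m / s_f
    matrix = np.diag(scale)
    translation = c_m - scale * c_f
    return AffineTransform(tuple(map(tuple, matrix)), tuple(translation))


def _interp_field(displacement: DisplacementField, points_mm: np.ndarray) -> np.ndarray:
    idx = displacement.geometry.world_to_index(points_mm)
    out = np.empty_like(np.atleast_2d(points_mm), dtype=float)
    coords = [idx[..., 0], idx[..., 1], idx[..., 2]]
    for c in range(3):
        out[..., c] = map_coordinates(
            displacement.vectors[..., c], coords, order=1, mode="nearest"
        )
    return out


def transform_points(points: LandmarkSet, displacement: DisplacementField) -> LandmarkSet:
    """Map landmarks through the field: p -> p + u(p) (trilinear u).

    Points outside the fixed-grid extent are rejected with a diagnostic.
    """
    inside = displacement.geometry.contains_world(points.points)
    if not np.all(inside):
        bad = np.where(~inside)[0].tolist()
        raise ValueError(f"landmarks outside the fixed grid extent: rows {bad}")
    u = _interp_field(displacement, points.points)
    return points.with_points(points.points + u, phase="registered")


def warp_image(
    moving: ImageVolume,
    displacement: DisplacementField,
    background: float = 0.0,
    is_mask: bool | None = None,
) -> ImageVolume:
    """Pull-back resample: output(x) = moving(x + u(x)) on the fixed grid.

    Linear interpolation; masks are anti-aliased (Gaussian, 0.8 voxel),
    interpolated as floats and re-thresholded at 0.5 — subvoxel boundary
    transport instead of nearest-neighbor jagging.  Out-of-extent voxels
    take the ``background`` value.
    """
    geom = displacement.geometry
    xs, ys, zs = geom.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1) + displacement.vectors
    idx = moving.geometry.world_to_index(pts)
    if is_mask is None:
        is_mask = isinstance(moving, BinaryMask)
    source = np.asarray(moving.data, dtype=float)
    if is_mask:
        from scipy.ndimage import gaussian_filter

        source = gaussian_filter(source, 0.8)
    data = map_coordinates(
        source,
        [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=1, mode="constant", cval=0.0 if is_mask else background,
    )
    if is_mask:
        return BinaryMask((data > 0.5).astype(np.uint8), geom)
    return ImageVolume(data, geom)
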