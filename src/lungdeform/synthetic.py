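"""Synthetic breathing-lung cohort with closed-form ground-truth deformation.

The generator produces paired expiration/inspiration phantoms related by a
smooth, invertible, analytically known map, so every downstream stage
(registration, Jacobian analysis, QC, statistics) can be validated against
exact ground truth.

Deformation model
-----------------
The expiration-to-inspiration map is ``T(x) = x + u(x)`` with

    u(x) = (A - I)(x - c)  -  amplitude * S(r) * m(x) * (x - c)

where ``A = diag(affine_scale)`` is a global breathing expansion, ``c`` the
thorax center, ``r`` the normalized elliptical radius w.r.t. ``lung_radii``,
``S`` a C^1 smoothstep ramp that switches the radial contraction on outside
``inner_radius``, and ``m(x) = 1 - (1 - beta) * basal(z) * H(r)`` an
attenuation factor active on the peripheral shell (``H`` ramps up around
``shell_fraction``) and strongest in the inferior (basal) half.

``beta = 1`` leaves the full peripheral deformation in place (healthy
pattern); ``beta -> 0`` stiffens the peripheral/basal lung, emulating the
restricted regional deformation of fibrotic lungs.  The displacement is
continuously differentiable everywhere and, for amplitudes up to ~0.3 with
the default radii, the induced map is invertible (checked by evaluating the
Jacobian determinant on the grid).

The displacement lives on the expiration (fixed) grid and points toward
inspiration space — the same pull-back convention the registration stage
uses — so registration accuracy can be scored directly against it.  The
inspiration image is synthesized by resampling the expiration image through
the numerically inverted map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .grid import BinaryMask, Geometry, ImageVolume
from .qc import LandmarkSet
from .stats import compute_cpi

__all__ = [
    "DeformationModel",
    "SyntheticSubject",
    "make_phantom",
    "true_displacement",
    "true_jacobian",
    "make_cohort",
    "place_landmarks",
    "model_for_severity",
    "CLINICAL_DIRECTIONS",
]

# Phantom anatomy, expressed as fractions of the deformation ellipsoid
# radii so that resized models stay self-similar.
_LUNG_OFFSET_FRAC = 0.52  # lateral offset of each lung center (of R_x)
_LUNG_SEMI_FRAC = (0.36, 0.70, 0.78)  # lung ellipsoid semi-axes (of R)
_BODY_SEMI_FRAC = (1.24, 1.24, 1.09)  # body ellipsoid semi-axes (of R)

_LUNG_INTENSITY = 60.0
_BODY_INTENSITY = 300.0
_EDGE_FRAC = 0.04  # soft tissue-boundary width, fraction of normalized radius


def _smoothstep(t: np.ndarray) -> np.ndarray:
    # quintic smoothstep: C^2 at the clamp knots, so finite-difference
    # stencils converge cleanly on the induced displacement
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


@dataclass(frozen=True)
class DeformationModel:
    """Parametric ground-truth breathing deformation (see module docstring).

    Parameters
    ----------
    affine_scale : per-axis global expansion factors (dimensionless).
    center : thorax center in world mm.
    lung_radii : semi-axes (mm) of the thoracic ellipsoid in which the
        normalized radius ``r`` is measured.
    amplitude : peak radial contraction fraction in [0, 1); values <= 0.3
        keep the map invertible with the default radii.
    peripheral_attenuation : beta in [0, 1] multiplying the deformation in
        the peripheral/basal shell (1 = healthy, 0 = fully stiffened).
    shell_fraction : normalized radius beyond which the attenuation applies.
    """

    affine_scale: tuple[float, float, float] = (1.17, 1.17, 1.22)
    center: tuple[float, float, float] = (64.0, 64.0, 64.0)
    lung_radii: tuple[float, float, float] = (42.0, 34.0, 46.0)
    amplitude: float = 0.15
    peripheral_attenuation: float = 1.0
    shell_fraction: float = 0.7
    seed: int = 0
    inner_radius: float = 0.55  # radius below which no radial contraction acts
    shell_width: float = 0.08  # half-width of the attenuation ramp
    basal_floor: float = 0.35  # attenuation fraction retained superiorly

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError("amplitude must be in [0, 1)")
        if not (0.0 <= self.peripheral_attenuation <= 1.0):
            raise ValueError("peripheral_attenuation must be in [0, 1]")
        if not (0.0 < self.shell_fraction < 1.0):
            raise ValueError("shell_fraction must be in (0, 1)")
        if any(r <= 0 for r in self.lung_radii):
            raise ValueError("lung_radii must be positive")


@dataclass
class SyntheticSubject:
    """One simulated participant: phantoms, masks, landmarks and record."""

    subject_id: str
    group: str  # "control" | "IPF-like"
    model: DeformationModel
    inspiration: ImageVolume | None = None
    expiration: ImageVolume | None = None
    lung_mask_insp: BinaryMask | None = None
    lung_mask_exp: BinaryMask | None = None
    landmarks_insp: LandmarkSet | None = None
    landmarks_exp: LandmarkSet | None = None
    record: dict = field(default_factory=dict)
    severity: float = 0.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    grid_spacing: float = 2.0


def _normalized_radius(model: DeformationModel, pts: np.ndarray) -> np.ndarray:
    rel = (pts - np.asarray(model.center)) / np.asarray(model.lung_radii)
    return np.sqrt(np.sum(rel * rel, axis=-1))


def true_displacement(model: DeformationModel, points_mm: np.ndarray) -> np.ndarray:
    """Closed-form displacement u(x) in mm at world points (..., 3)."""
    pts = np.asarray(points_mm, dtype=float)
    rel = pts - np.asarray(model.center)
    r = _normalized_radius(model, pts)

    ramp = _smoothstep((r - model.inner_radius) / (1.0 - model.inner_radius))
    shell = _smoothstep(
        (r - (model.shell_fraction - model.shell_width)) / (2.0 * model.shell_width)
    )
    z_rel = rel[..., 2] / (model.lung_radii[2] / 3.0)
    basal = model.basal_floor + (1.0 - model.basal_floor) * 0.5 * (1.0 - np.tanh(z_rel))
    atten = 1.0 - (1.0 - model.peripheral_attenuation) * basal * shell

    scale = np.asarray(model.affine_scale) - 1.0
    u_affine = rel * scale
    u_radial = -(model.amplitude * ramp * atten)[..., None] * rel
    return u_affine + u_radial


def _forward_map(model: DeformationModel, pts: np.ndarray) -> np.ndarray:
    return pts + true_displacement(model, pts)


def true_jacobian(model: DeformationModel, points_mm: np.ndarray,
                  step_mm: float = 1e-3) -> np.ndarray:
    """Jacobian determinant of T = id + u by central differences on u.

    Serves as the independent ground-truth oracle for the grid-based
    Jacobian computation; exact to O(step^2) on the closed-form field.
    """
    pts = np.asarray(points_mm, dtype=float)
    flat = pts.reshape(-1, 3)
    grads = np.empty((len(flat), 3, 3))
    for ax in range(3):
        h = np.zeros(3)
        h[ax] = step_mm
        du = (true_displacement(model, flat + h) - true_displacement(model, flat - h))
        grads[:, :, ax] = du / (2.0 * step_mm)
    jac = np.linalg.det(np.eye(3) + grads)
    return jac.reshape(pts.shape[:-1])


def invert_map(model: DeformationModel, points_mm: np.ndarray,
               tol_mm: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Solve T(x) = y for x by fixed-point iteration x <- y - u(x).

    Converges because u is a contraction for invertible parameter ranges.
    """
    y = np.asarray(points_mm, dtype=float)
    x = y.copy()
    for _ in range(max_iter):
        x_new = y - true_displacement(model, x)
        err = np.max(np.abs(x_new - x))
        x = x_new
        if err < tol_mm:
            break
    return x


def check_invertibility(model: DeformationModel, geometry: Geometry) -> float:
    """Minimum Jacobian determinant of T over the grid; raises if <= 0."""
    xs, ys, zs = geometry.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)
    # coarse subsample is enough: the field is smooth at the 2 mm scale
    sub = pts[::2, ::2, ::2]
    jmin = float(true_jacobian(model, sub).min())
    if jmin <= 0.0:
        raise ValueError(
            f"deformation model is not invertible on this grid "
            f"(min Jacobian {jmin:.4f} <= 0); reduce amplitude"
        )
    return jmin


def _lung_ellipsoid_q(model: DeformationModel, pts: np.ndarray) -> np.ndarray:
    """Min normalized ellipsoid norm over the two lungs (<= 1 inside)."""
    radii = np.asarray(model.lung_radii)
    semi = np.asarray(_LUNG_SEMI_FRAC) * radii
    off = _LUNG_OFFSET_FRAC * radii[0]
    c = np.asarray(model.center)
    q = None
    for sgn in (-1.0, 1.0):
        lc = c + np.array([sgn * off, 0.0, 0.0])
        rel = (pts - lc) / semi
        qi = np.sqrt(np.sum(rel * rel, axis=-1))
        q = qi if q is None else np.minimum(q, qi)
    return q


def _body_ellipsoid_q(model: DeformationModel, pts: np.ndarray) -> np.ndarray:
    semi = np.asarray(_BODY_SEMI_FRAC) * np.asarray(model.lung_radii)
    rel = (pts - np.asarray(model.center)) / semi
    return np.sqrt(np.sum(rel * rel, axis=-1))


def _sample(data: np.ndarray, geometry: Geometry, pts: np.ndarray,
            order: int = 1, cval: float = 0.0) -> np.ndarray:
    idx = geometry.world_to_index(pts)
    return map_coordinates(
        data, [idx[..., 0], idx[..., 1], idx[..., 2]],
        order=order, mode="constant", cval=cval,
    )


def make_phantom(
    model: DeformationModel,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: float | tuple[float, float, float] = 2.0,
    subject_id: str = "sub-000",
    group: str = "control",
    severity: float = 0.0,
    with_landmarks: bool = True,
) -> SyntheticSubject:
    """Build one paired inspiration/expiration phantom subject.

    The expiration image is a two-ellipsoid "lung" (low intensity, smooth
    multiplicative texture) inside a body ellipsoid; the inspiration image is
    the expiration image pulled back through the inverse of the model map, so
    the forward registration target (inspiration -> expiration volume
    correspondence on the expiration grid) has the model displacement as
    exact ground truth.  Masks come from the analytic ellipsoid equations in
    each phase.
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    geom = Geometry(tuple(grid_shape), tuple(spacing))
    check_invertibility(model, geom)

    xs, ys, zs = geom.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)

    # --- expiration image: body + lungs with band-limited texture ---
    rng = np.random.default_rng(model.seed)
    noise = gaussian_filter(rng.standard_normal(geom.shape), sigma=2.0)
    noise /= max(noise.std(), 1e-12)
    edge = _EDGE_FRAC
    w_lung = _smoothstep((1.0 - _lung_ellipsoid_q(model, pts)) / edge + 0.5)
    w_body = _smoothstep((1.0 - _body_ellipsoid_q(model, pts)) / edge + 0.5)
    tex_lung = 1.0 + 0.25 * noise
    tex_body = 1.0 + 0.10 * noise
    exp_data = (
        _BODY_INTENSITY * tex_body * w_body * (1.0 - w_lung)
        + _LUNG_INTENSITY * tex_lung * w_lung
    )
    expiration = ImageVolume(exp_data, geom)

    # --- inspiration image by pull-back through the inverse map ---
    if model.amplitude == 0.0 and np.allclose(model.affine_scale, 1.0):
        insp_data = exp_data.copy()  # identity model: exact voxel equality
        x_inv = pts
    else:
        x_inv = invert_map(model, pts.reshape(-1, 3)).reshape(pts.shape)
        insp_data = _sample(exp_data, geom, x_inv, order=1)
    inspiration = ImageVolume(insp_data, geom)

    # --- analytic masks in both phases ---
    mask_exp = BinaryMask((_lung_ellipsoid_q(model, pts) <= 1.0).astype(np.uint8), geom)
    mask_insp = BinaryMask(
        (_lung_ellipsoid_q(model, x_inv) <= 1.0).astype(np.uint8), geom
    )

    subject = SyntheticSubject(
        subject_id=subject_id,
        group=group,
        model=model,
        inspiration=inspiration,
        expiration=expiration,
        lung_mask_insp=mask_insp,
        lung_mask_exp=mask_exp,
        severity=severity,
    )
    if with_landmarks:
        lm_exp, lm_insp = place_landmarks(subject)
        subject.landmarks_exp = lm_exp
        subject.landmarks_insp = lm_insp
    return subject


def place_landmarks(subject: SyntheticSubject, level_mm: float | None = None
                    ) -> tuple[LandmarkSet, LandmarkSet]:
    """Bilateral chest-wall landmarks at one axial level, in both phases.

    Two categories are placed on the phantom body surface in expiration
    space: A at the mid-coronal plane and B on the anterior wall.  The
    inspiration-space positions follow exactly from the true displacement,
    so they are true correspondences.
    """
    model = subject.model
    geom = (subject.expiration or subject.lung_mask_exp).geometry
    c = np.asarray(model.center)
    body = np.asarray(_BODY_SEMI_FRAC) * np.asarray(model.lung_radii)
    if level_mm is None:
        level_mm = float(c[2])
    z_rel = (level_mm - c[2]) / body[2]
    if abs(z_rel) >= 0.95:
        raise ValueError(f"landmark level {level_mm} mm outside the body extent")

    pts, cats, sides = [], [], []
    # category A: mid-coronal (y = c_y); category B: anterior wall
    for cat, y_frac in (("A", 0.0), ("B", -0.55)):
        root = 1.0 - y_frac**2 - z_rel**2
        if root <= 0:
            raise ValueError(f"landmark category {cat} outside the body at this level")
        x_half = body[0] * np.sqrt(root)
        for side, sgn in (("left", -1.0), ("right", 1.0)):
            pts.append([c[0] + sgn * x_half, c[1] + y_frac * body[1], level_mm])
            cats.append(cat)
            sides.append(side)
    pts = np.asarray(pts)
    if not np.all(geom.contains_world(pts)):
        raise ValueError("landmarks fall outside the image grid")
    lm_exp = LandmarkSet(pts, cats, sides, phase="exp")
    lm_insp = lm_exp.with_points(_forward_map(model, pts), phase="insp")
    return lm_exp, lm_insp


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _logistic(s: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(s - 0.5) / 0.18))


# Clinical column generators: name -> (baseline, slope on logistic(severity),
# noise scale at noise_sd=1).  Slope sign encodes the designed direction.
_CLINICAL_SPEC = {
    "fvc_pct": (108.0, -45.0, 6.0),
    "fev1_pct": (103.0, -32.0, 6.0),
    "tlc_pct": (102.0, -45.0, 6.0),
    "dlco_pct": (104.0, -62.0, 8.0),
    "sgrq_symptoms": (5.0, 85.0, 7.0),
    "sgrq_activity": (4.0, 80.0, 7.0),
    "sgrq_impact": (2.0, 70.0, 6.0),
    "six_mwd_m": (540.0, -160.0, 25.0),
    "fibrosis_pct": (1.0, 30.0, 3.0),
    "tpv_volume_ml": (195.0, -15.0, 18.0),
    "tpv_number": (2700.0, -1100.0, 150.0),
    "tpv_tortuosity": (1.065, 0.06, 0.012),
    "pvv_volume_ml": (96.0, -4.0, 10.0),
    "pvv_number": (1320.0, -420.0, 90.0),
    "pvv_tortuosity": (1.065, 0.05, 0.012),
    "pav_volume_ml": (100.0, -11.0, 12.0),
    "pav_number": (1350.0, -560.0, 100.0),
    "pav_tortuosity": (1.06, 0.055, 0.012),
}

#: Designed monotone direction of each severity-linked clinical column
#: (+1: increases with severity, -1: decreases).
CLINICAL_DIRECTIONS = {
    name: int(np.sign(slope)) for name, (_, slope, _) in _CLINICAL_SPEC.items()
}
CLINICAL_DIRECTIONS.update(
    {"cpi": 1, "mrc": 1, "sgrq_total": 1}
)


def model_for_severity(
    severity: float,
    rng: np.random.Generator,
    base: DeformationModel | None = None,
    anatomy_jitter: float = 0.05,
) -> DeformationModel:
    """Map a severity s in [0, 1] to a subject deformation model.

    Severity stiffens the peripheral/basal shell (beta decreases) and mildly
    reduces the global breathing amplitude; anatomy (lung radii) gets a small
    per-subject jitter.
    """
    if base is None:
        base = DeformationModel()
    beta = float(np.clip(1.0 - 0.95 * severity, 0.05, 1.0))
    amplitude = base.amplitude * (1.0 - 0.25 * severity)
    radii = tuple(
        float(r * (1.0 + anatomy_jitter * rng.uniform(-1, 1)))
        for r in base.lung_radii
    )
    # restrictive physiology: global breathing expansion shrinks with severity
    scale = tuple(
        float(1.0 + (s - 1.0) * (1.0 - 0.7 * severity)
              * (1.0 + 0.02 * rng.uniform(-1, 1)))
        for s in base.affine_scale
    )
    return replace(
        base,
        affine_scale=scale,
        lung_radii=radii,
        amplitude=amplitude,
        peripheral_attenuation=beta,
        seed=int(rng.integers(2**31)),
    )


def _clinical_record(subject_id: str, group: str, severity: float,
                     noise_sd: float, rng: np.random.Generator) -> dict:
    L = float(_logistic(np.asarray(severity)))
    rec: dict = {"subject_id": subject_id, "group": group, "severity": severity}
    rec["age"] = float(np.round(rng.normal(62 if group != "control" else 58, 5)))
    rec["sex"] = "M" if rng.uniform() < 0.94 else "F"
    for name, (base, slope, sd) in _CLINICAL_SPEC.items():
        val = base + slope * L + noise_sd * sd * rng.standard_normal()
        rec[name] = float(val)
    # bounded / derived columns
    rec["fvc_pct"] = max(rec["fvc_pct"], 1.0)
    rec["fev1_pct"] = max(rec["fev1_pct"], 1.0)
    rec["dlco_pct"] = max(rec["dlco_pct"], 1.0)
    rec["fev1_fvc_pct"] = float(81.5 + noise_sd * 4.0 * rng.standard_normal())
    for k in ("sgrq_symptoms", "sgrq_activity", "sgrq_impact"):
        rec[k] = float(np.clip(rec[k], 0.0, 100.0))
    rec["sgrq_total"] = float(
        0.35 * rec["sgrq_symptoms"] + 0.35 * rec["sgrq_activity"]
        + 0.30 * rec["sgrq_impact"]
    )
    rec["fibrosis_pct"] = float(np.clip(rec["fibrosis_pct"], 0.0, 80.0))
    # dyspnea grade: 1 below L ~ 0.47, then climbing to 4-5 at high severity
    grade = np.clip((L - 0.28) / 0.68, 0.0, 1.0)
    rec["mrc"] = int(np.clip(
        1 + np.floor(3.5 * grade + 0.35 * noise_sd * rng.standard_normal()), 1, 5
    ))
    rec["cpi"] = compute_cpi(rec["fvc_pct"], rec["fev1_pct"], rec["dlco_pct"])
    return rec


def make_cohort(
    n_control: int,
    n_ipf: int,
    severity_range: tuple[float, float] = (0.35, 0.95),
    noise_sd: float = 1.0,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: float = 2.0,
    images: bool = False,
    base_model: DeformationModel | None = None,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate a synthetic cohort and its clinical table.

    Controls draw a mild severity in [0, 0.12]; IPF-like subjects draw
    severity uniformly from ``severity_range``.  Clinical columns are
    monotone logistic transforms of severity plus Gaussian noise scaled by
    ``noise_sd`` (0 = noise-free, designed monotonicities exact).  With
    ``images=False`` only models, masks-on-demand and records are built;
    phantom volumes are generated lazily via :func:`make_phantom`.

    Fully reproducible: all randomness derives from ``seed``.
    """
    if n_control < 2 or n_ipf < 2:
        raise ValueError("need at least 2 subjects per group")
    lo, hi = float(severity_range[0]), float(severity_range[1])
    if not (0.0 <= lo <= hi <= 1.0) or hi == lo == 0.0 and n_ipf:
        raise ValueError(f"invalid severity_range {severity_range}")
    if hi < lo:
        raise ValueError("empty severity_range")

    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    records = []
    idx = 0
    for group, n in (("control", n_control), ("IPF-like", n_ipf)):
        for _ in range(n):
            sid = f"sub-{idx:03d}"
            severity = (
                float(rng.uniform(0.0, 0.12)) if group == "control"
                else float(rng.uniform(lo, hi))
            )
            model = model_for_severity(severity, rng, base=base_model)
            rec = _clinical_record(sid, group, severity, noise_sd, rng)
            if images:
                subj = make_phantom(
                    model, grid_shape, spacing, subject_id=sid,
                    group=group, severity=severity,
                )
            else:
                subj = SyntheticSubject(
                    subject_id=sid, group=group, model=model, severity=severity
                )
            subj.grid_shape = tuple(grid_shape)
            subj.grid_spacing = spacing
            subj.record = rec
            subjects.append(subj)
            records.append(rec)
            idx += 1

    table = pd.DataFrame.from_records(records)
    table.attrs["generator"] = {
        "n_control": n_control,
        "n_ipf": n_ipf,
        "severity_range": (lo, hi),
        "noise_sd": noise_sd,
        "seed": seed,
        "grid_shape": tuple(grid_shape),
        "spacing": spacing,
        "clinical_spec": {k: v for k, v in _CLINICAL_SPEC.items()},
        "directions": dict(CLINICAL_DIRECTIONS),
    }
    return subjects, table


def make_masks(subject: SyntheticSubject,
               grid_shape: tuple[int, int, int] = (64, 64, 64),
               spacing: float | tuple[float, float, float] = 2.0) -> SyntheticSubject:
    """Fill in analytic lung masks and landmarks without rendering images.

    Used by the oracle-registration analysis path, where the closed-form
    field makes the textured volumes unnecessary.
    """
    if subject.lung_mask_exp is not None:
        return subject
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    geom = Geometry(tuple(grid_shape), tuple(spacing))
    model = subject.model
    xs, ys, zs = geom.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)
    subject.lung_mask_exp = BinaryMask(
        (_lung_ellipsoid_q(model, pts) <= 1.0).astype(np.uint8), geom
    )
    # the inspiration lung is T(exp lung); invert the map only where the
    # lung can possibly land (lung extent + displacement bound)
    radii = np.asarray(model.lung_radii)
    lung_lo = np.asarray(model.center) - (_LUNG_OFFSET_FRAC * radii[0]
                                          + np.asarray(_LUNG_SEMI_FRAC) * radii)
    lung_hi = np.asarray(model.center) + (_LUNG_OFFSET_FRAC * radii[0]
                                          + np.asarray(_LUNG_SEMI_FRAC) * radii)
    margin = (max(model.affine_scale) - 1.0 + model.amplitude) * radii.max() + 8.0
    near = np.all((pts >= lung_lo - margin) & (pts <= lung_hi + margin), axis=-1)
    inside = np.zeros(geom.shape, dtype=bool)
    if np.any(near):
        x_inv = invert_map(model, pts[near], tol_mm=1e-3)
        inside[near] = _lung_ellipsoid_q(model, x_inv) <= 1.0
    subject.lung_mask_insp = BinaryMask(inside.astype(np.uint8), geom)
    lm_exp, lm_insp = place_landmarks(subject)
    subject.landmarks_exp = lm_exp
    subject.landmarks_insp = lm_insp
    return subject


def true_field(model: DeformationModel, geometry: Geometry, roi=None):
    """Evaluate the closed-form displacement on a grid (oracle field)."""
    from .registration import DisplacementField

    xs, ys, zs = geometry.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)
    return DisplacementField(true_displacement(model, pts), geometry, roi=roi)


def designed_spearman(column: str, group: str = "IPF-like",
                      severity_range: tuple[float, float] = (0.35, 0.95),
                      noise_sd: float = 1.0, n_mc: int = 20000,
                      seed: int = 12345) -> float:
    """Designed Spearman correlation between severity and a clinical column.

    Estimated by Monte Carlo from the generator's own noise model at large n
    (the transform is monotone, so the noise-free value is ±1 and noise
    shrinks it toward 0).  Deterministic for fixed ``seed``.
    """
    from scipy.stats import spearmanr

    if column not in _CLINICAL_SPEC:
        raise KeyError(f"no designed transform for column {column!r}")
    rng = np.random.default_rng(seed)
    lo, hi = severity_range
    s = rng.uniform(lo, hi, size=n_mc)
    base, slope, sd = _CLINICAL_SPEC[column]
    vals = base + slope * _logistic(s) + noise_sd * sd * rng.standard_normal(n_mc)
    return float(spearmanr(s, vals).statistic)
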