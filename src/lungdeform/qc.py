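"""Registration quality control and two-phase repeatability statistics.

Registration quality is summarised by (i) the intersection-over-union (IoU)
between the registered inspiratory lung mask and the expiratory lung mask and
(ii) residual distances of two landmark categories (DA, DB) after mapping
landmarks through the recovered displacement field.  Repeatability across two
acquisitions is summarised per metric by a two-way random-effects,
absolute-agreement, single-measurement intraclass correlation coefficient —
ICC(2,1) — and Bland-Altman 95% limits of agreement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "QCReport",
    "iou",
    "landmark_distances",
    "icc",
    "classify_icc",
    "bland_altman",
    "two_phase_repeatability",
]

# Agreement scale used to classify ICC values: null (<= 0), then slight,
# fair, moderate, good, very good (> 0.80) and almost perfect (> 0.95).
_ICC_SCALE = [
    (0.95, "almost perfect"),
    (0.80, "very good"),
    (0.60, "good"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (0.0, "slight"),
]


@dataclass
class LandmarkSet:
    """Labeled world-mm landmarks for one respiratory phase.

    ``points`` is (n, 3) in world mm; ``category`` ("A"/"B") and ``side``
    ("left"/"right") label each row; ``phase`` tags the whole set
    ("insp", "exp" or "registered").
    """

    points: np.ndarray
    category: np.ndarray
    side: np.ndarray
    phase: str

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.category = np.asarray(self.category, dtype=object)
        self.side = np.asarray(self.side, dtype=object)
        if self.points.shape[1] != 3:
            raise ValueError("landmark points must be (n, 3)")
        if len(self.category) != len(self.points) or len(self.side) != len(self.points):
            raise ValueError("label arrays must match point count")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def labels(self) -> list[tuple[str, str]]:
        return [(str(c), str(s)) for c, s in zip(self.category, self.side)]

    def with_points(self, points: np.ndarray, phase: str) -> "LandmarkSet":
        return LandmarkSet(points, self.category.copy(), self.side.copy(), phase)


@dataclass
class QCReport:
    """Cohort-level registration QC and repeatability summary."""

    iou_mean: float
    da_mm: float
    db_mm: float
    clipped_jac_voxels: int = 0
    icc_by_metric: dict = field(default_factory=dict)
    bland_altman_by_metric: dict = field(default_factory=dict)
    n_subjects: int = 0
    excluded_subjects: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "iou_mean": self.iou_mean,
            "da_mm": self.da_mm,
            "db_mm": self.db_mm,
            "clipped_jac_voxels": self.clipped_jac_voxels,
            "icc_by_metric": self.icc_by_metric,
            "bland_altman_by_metric": self.bland_altman_by_metric,
            "n_subjects": self.n_subjects,
            "excluded_subjects": self.excluded_subjects,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def iou(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Intersection over union of two masks on the same grid.

    Returns NaN (reported missing) when both masks are empty.
    """
    if tuple(mask_a.shape) != tuple(mask_b.shape):
        raise ValueError("IoU requires masks on the same grid")
    a = mask_a.astype_bool()
    b = mask_b.astype_bool()
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return float("nan")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def landmark_distances(
    registered: LandmarkSet, reference: LandmarkSet
) -> tuple[float, float]:
    """Mean per-category Euclidean distances (DA, DB) in mm.

    Points are matched by (category, side) label; unmatched labels are an
    error.  Per-subject averaging is over points within each category.
    """
    ref_index = {}
    for i, lab in enumerate(reference.labels()):
        ref_index.setdefault(lab, []).append(i)
    dists: dict[str, list[float]] = {"A": [], "B": []}
    used: dict[tuple, int] = {}
    for i, lab in enumerate(registered.labels()):
        pool = ref_index.get(lab, [])
        j = used.get(lab, 0)
        if j >= len(pool):
            raise ValueError(f"unmatched landmark label {lab}")
        used[lab] = j + 1
        d = float(np.linalg.norm(registered.points[i] - reference.points[pool[j]]))
        cat = lab[0]
        if cat not in dists:
            raise ValueError(f"unknown landmark category {cat!r}")
        dists[cat].append(d)
    if not dists["A"] or not dists["B"]:
        raise ValueError("both categories A and B are required for distances")
    return float(np.mean(dists["A"])), float(np.mean(dists["B"]))


def classify_icc(value: float) -> str:
    if value <= 0:
        return "null"
    for thr, label in _ICC_SCALE:
        if value > thr:
            return label
    return "null"


def icc(table: np.ndarray, min_subjects: int = 5) -> tuple[float, str]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``table`` is (n_subjects, 2) — one column per acquisition phase.  Computed
    from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("ICC table must be (n_subjects, 2)")
    n, k = x.shape
    if n < min_subjects:
        raise ValueError(f"ICC requires at least {min_subjects} subjects, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC table contains non-finite values")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("ICC undefined: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    value = float((msr - mse) / denom)
    return value, classify_icc(value)


def bland_altman(pairs: np.ndarray) -> tuple[float, float, float]:
    """Bland-Altman agreement: (mean difference, lower LOA, upper LOA).

    Limits of agreement are mean ± 1.96 · SD of the paired differences
    (sample SD, n−1 denominator).  Identical pairs collapse to (0, 0, 0).
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs of measurements")
    diffs = x[:, 0] - x[:, 1]
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def two_phase_repeatability(subject_pairs: list[dict]) -> QCReport:
    """Assemble the cohort QC report from two repeated pipeline runs.

    ``subject_pairs`` holds one dict per subject with keys ``subject_id``,
    ``phase1`` and ``phase2``; each phase maps metric name -> value for the
    metrics ``iou``, ``da_mm``, ``db_mm``.  Subjects missing a phase (or any
    metric) are excluded with a log entry.
    """
    metrics = ("iou", "da_mm", "db_mm")
    rows = []
    excluded = []
    for rec in subject_pairs:
        p1, p2 = rec.get("phase1"), rec.get("phase2")
        if p1 is None or p2 is None or any(
            m not in p or not np.isfinite(p[m]) for p in (p1, p2) for m in metrics
        ):
            excluded.append(rec.get("subject_id", "<unknown>"))
            logger.warning("excluding subject %s: incomplete phases", excluded[-1])
            continue
        rows.append(rec)
    if not rows:
        raise ValueError("no subjects with both phases complete")

    icc_by_metric = {}
    ba_by_metric = {}
    for m in metrics:
        tab = np.array([[r["phase1"][m], r["phase2"][m]] for r in rows])
        value, label = icc(tab)
        icc_by_metric[m] = {"icc": value, "classification": label}
        md, lo, hi = bland_altman(tab)
        ba_by_metric[m] = {"mean_diff": md, "loa_low": lo, "loa_high": hi}

    clipped = int(sum(r["phase1"].get("clipped_jac_voxels", 0) for r in rows))
    return QCReport(
        iou_mean=float(np.mean([r["phase1"]["iou"] for r in rows])),
        da_mm=float(np.mean([r["phase1"]["da_mm"] for r in rows])),
        db_mm=float(np.mean([r["phase1"]["db_mm"] for r in rows])),
        clipped_jac_voxels=clipped,
        icc_by_metric=icc_by_metric,
        bland_altman_by_metric=ba_by_metric,
        n_subjects=len(rows),
        excluded_subjects=excluded,
    )
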