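"""Clinical severity statistics: CPI, group comparisons, correlations.

The composite physiologic index (CPI) summarises functional impairment in
fibrotic interstitial lung disease from three pulmonary-function values:

    CPI = 91 - 0.65 * DLco% - 0.53 * FVC% + 0.34 * FEV1%

Group comparisons use the unpaired t-test or Mann-Whitney U test for
quantitative variables (auto-selected by a Shapiro-Wilk normality screen,
with the chosen test always reported) and the chi-square test for
categorical variables.  Associations between the deformation endpoints
(Jac-mean, Dice) and clinical severity use Spearman rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "compute_cpi",
    "compare_groups",
    "spearman",
    "severity_analysis",
]

#: clinical columns correlated against the deformation endpoints, with the
#: direction expected for a cohort where deformation decreases with severity
CORRELATION_COLUMNS = {
    "fvc_pct": +1,
    "fev1_pct": +1,
    "tlc_pct": +1,
    "dlco_pct": +1,
    "six_mwd_m": +1,
    "cpi": -1,
    "sgrq_symptoms": -1,
    "sgrq_activity": -1,
    "sgrq_impact": -1,
    "sgrq_total": -1,
    "fibrosis_pct": -1,
}


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    direction: int = 0  # sign of the effect (group1 - group2, or rho)
    n: tuple = ()
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


def compute_cpi(fvc_pct, fev1_pct, dlco_pct):
    """Composite physiologic index from %-predicted FVC, FEV1 and DLco.

    Works on scalars or array-likes; missing inputs propagate to a missing
    CPI (never imputed).  Inputs are %-predicted values (>= 0).
    """
    fvc = np.asarray(fvc_pct, dtype=float)
    fev1 = np.asarray(fev1_pct, dtype=float)
    dlco = np.asarray(dlco_pct, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(fvc[np.isfinite(fvc)] < 0) or np.any(fev1[np.isfinite(fev1)] < 0) \
                or np.any(dlco[np.isfinite(dlco)] < 0):
            raise ValueError("%-predicted inputs must be nonnegative")
    cpi = 91.0 - 0.65 * dlco - 0.53 * fvc + 0.34 * fev1
    if cpi.ndim == 0:
        return float(cpi)
    return cpi


def _two_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(uniq)}")
    g1 = values[labels == uniq[0]]
    g2 = values[labels == uniq[1]]
    return g1, g2, uniq


def compare_groups(values, group_labels, kind: str = "auto") -> StatResult:
    """Two-sided two-group comparison.

    ``kind``: "t" (unpaired t-test), "mannwhitney", "chi2" (``values`` then
    holds category labels, not numbers), or "auto" — Shapiro-Wilk screen at
    alpha = 0.05 on both groups chooses t vs Mann-Whitney; the chosen test is
    always recorded in the result, never silent.
    """
    if kind == "chi2":
        tab = pd.crosstab(np.asarray(values), np.asarray(group_labels))
        chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
        return StatResult("chi-square", float(chi2), float(p),
                          n=tuple(tab.sum(axis=0)))

    g1, g2, uniq = _two_groups(values, group_labels)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    note = ""
    if kind == "auto":
        normal = all(
            len(g) >= 3 and sps.shapiro(g).pvalue > 0.05 for g in (g1, g2)
        )
        kind = "t" if normal else "mannwhitney"
        note = f"auto-selected {kind} by Shapiro-Wilk screen"
    direction = int(np.sign(np.mean(g1) - np.mean(g2)))
    if kind == "t":
        res = sps.ttest_ind(g1, g2)
        return StatResult("unpaired t-test", float(res.statistic),
                          float(res.pvalue), direction, (len(g1), len(g2)), note)
    if kind == "mannwhitney":
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided")
        return StatResult("Mann-Whitney U", float(res.statistic),
                          float(res.pvalue), direction, (len(g1), len(g2)), note)
    raise ValueError(f"unknown test kind {kind!r}")


def spearman(x, y) -> StatResult:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Requires >= 5 complete pairs; constant input yields a missing result
    with a diagnostic note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError(f"Spearman needs >= 5 paired values, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("spearman", float("nan"), float("nan"),
                          n=(len(x),), note="constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p),
                      int(np.sign(rho)), (len(x),))


def _mrc_stratum(mrc: int) -> str:
    return {1: "MRC 1", 2: "MRC 2"}.get(int(mrc), "MRC >=3")


def severity_analysis(
    cohort: pd.DataFrame,
    endpoints: tuple[str, ...] = ("jac_mean", "dice"),
    adjust: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Severity report: MRC-strata contrasts and clinical correlations.

    Returns two tidy tables:

    - ``mrc_contrasts``: per endpoint, the three pairwise comparisons of the
      dyspnea strata MRC 1 / MRC 2 / MRC >= 3 among IPF-like subjects, with
      the chosen test, statistic and (by default unadjusted) p value.
    - ``correlations``: Spearman rho of each endpoint against the clinical
      severity columns, one row per (endpoint, variable) pair.

    ``adjust="bh"`` applies a Benjamini-Hochberg correction to each table's
    p values, added as a separate flagged column (raw p is always kept).
    """
    rows_contrast = []
    ipf = cohort[cohort["group"] != "control"].copy()
    if "mrc" in ipf.columns and len(ipf):
        ipf["mrc_stratum"] = ipf["mrc"].map(_mrc_stratum)
        strata = ["MRC 1", "MRC 2", "MRC >=3"]
        for endpoint in endpoints:
            if endpoint not in ipf.columns:
                continue
            for s1, s2 in combinations(strata, 2):
                sub = ipf[ipf["mrc_stratum"].isin([s1, s2])]
                counts = sub["mrc_stratum"].value_counts()
                if len(counts) < 2 or counts.min() < 2:
                    logger.warning("skipping contrast %s vs %s: absent/small stratum", s1, s2)
                    continue
                res = compare_groups(sub[endpoint], sub["mrc_stratum"], kind="auto")
                rows_contrast.append({
                    "endpoint": endpoint, "contrast": f"{s1} vs {s2}",
                    "test": res.test, "statistic": res.statistic,
                    "p": res.p_value, "n1": res.n[0], "n2": res.n[1],
                })
    contrasts = pd.DataFrame(rows_contrast)

    rows_corr = []
    for endpoint in endpoints:
        if endpoint not in cohort.columns:
            continue
        for col, expected_sign in CORRELATION_COLUMNS.items():
            if col not in cohort.columns:
                continue
            try:
                res = spearman(cohort[endpoint], cohort[col])
            except ValueError:
                continue
            rows_corr.append({
                "endpoint": endpoint, "variable": col,
                "rho": res.statistic, "p": res.p_value, "n": res.n[0],
                "expected_sign": expected_sign,
            })
        # vessel indexes, if present (direction not part of the core pattern)
        for col in cohort.columns:
            if col.startswith(("tpv_", "pvv_", "pav_")):
                try:
                    res = spearman(cohort[endpoint], cohort[col])
                except ValueError:
                    continue
                rows_corr.append({
                    "endpoint": endpoint, "variable": col,
                    "rho": res.statistic, "p": res.p_value, "n": res.n[0],
                    "expected_sign": 0,
                })
    correlations = pd.DataFrame(rows_corr)

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        for tab in (contrasts, correlations):
            if len(tab):
                tab["p_bh"] = multipletests(tab["p"].values, method="fdr_bh")[1]
                tab["adjusted"] = "benjamini-hochberg"
    return {"mrc_contrasts": contrasts, "correlations": correlations}
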