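"""Statistical layer: regression with t-based confidence intervals,
two-sample t-tests, ROC/AUC classification and ROI noise metrics.

The regression direction follows the densitometry reporting convention:
areal BMD (g/cm^2) is regressed on volumetric BMD (mg/mL), giving a slope
in 1/cm-scaled units (an effective projected bone thickness).  ROC
analysis treats *low* BMD as the diseased class via an explicit
``positive_is_low`` orientation, so reported thresholds stay in physical
units (g/cm^2) rather than negated scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "ROCResult",
    "ROIMetrics",
    "linear_regression_ci",
    "two_sample_ttest",
    "roc_curve",
    "roi_metrics",
    "run_cohort_analysis",
]


class StatsError(ValueError):
    """Raised on degenerate statistical inputs."""


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    slope_stderr: float
    intercept_stderr: float
    ci95_slope: tuple
    ci95_intercept: tuple
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "slope_stderr": self.slope_stderr,
            "intercept_stderr": self.intercept_stderr,
            "ci95_slope": list(self.ci95_slope),
            "ci95_intercept": list(self.ci95_intercept),
            "n": self.n,
        }


def linear_regression_ci(x, y, level: float = 0.95) -> RegressionResult:
    """Ordinary least squares of y on x with t-based confidence intervals.

    The CI half-width is the two-sided inverse Student-t quantile at the
    requested level with n-2 degrees of freedom times the standard error;
    the p-value tests the null hypothesis of zero slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("regression needs n >= 3 paired values")
    if np.ptp(x) == 0:
        raise StatsError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    dof = x.size - 2
    tq = sps.t.ppf(0.5 + level / 2.0, dof)
    return RegressionResult(
        slope=res.slope,
        intercept=res.intercept,
        pearson_r=res.rvalue,
        p_value=res.pvalue,
        slope_stderr=res.stderr,
        intercept_stderr=res.intercept_stderr,
        ci95_slope=(res.slope - tq * res.stderr, res.slope + tq * res.stderr),
        ci95_intercept=(
            res.intercept - tq * res.intercept_stderr,
            res.intercept + tq * res.intercept_stderr,
        ),
        n=x.size,
    )


def two_sample_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided t-test for identical means of two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise StatsError("zero variance in both samples; t-test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    operating_point: dict
    positive_is_low: bool = True

    def as_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "tpr": self.tpr.tolist(),
            "fpr": self.fpr.tolist(),
            "auc": self.auc,
            "operating_point": self.operating_point,
            "positive_is_low": self.positive_is_low,
        }


def roc_curve(scores, labels, positive_is_low: bool = True) -> ROCResult:
    """ROC curve over a threshold sweep of the unique scores.

    With ``positive_is_low`` (the BMD convention: disease at low values), a
    sample is called positive when its score falls below the threshold.
    AUC is integrated with the trapezoidal rule; the operating point is
    the sweep point with minimum Euclidean distance to (FPR 0, TPR 1),
    ties broken toward higher TPR.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size != labels.size:
        raise StatsError("scores and labels must pair up")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise StatsError("ROC needs both classes present")

    s = scores if positive_is_low else -scores
    # predicate: positive when s < t; sweep t over unique values plus +/-inf
    uniq = np.unique(s)
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    # tpr(t) = P(s < t | pos): count via searchsorted on sorted class scores
    pos_sorted = np.sort(s[labels])
    neg_sorted = np.sort(s[~labels])
    tpr = np.searchsorted(pos_sorted, thresholds, side="left") / n_pos
    fpr = np.searchsorted(neg_sorted, thresholds, side="left") / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    dist2 = fpr**2 + (1.0 - tpr) ** 2
    best = np.lexsort((-tpr, dist2))[0]
    phys_thr = thresholds[best] if positive_is_low else -thresholds[best]
    op = {
        "threshold": float(phys_thr),
        "tpr": float(tpr[best]),
        "fpr": float(fpr[best]),
    }
    phys_thresholds = thresholds if positive_is_low else -thresholds
    return ROCResult(
        thresholds=phys_thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        operating_point=op,
        positive_is_low=positive_is_low,
    )


@dataclass
class ROIMetrics:
    roi: tuple
    mean: float
    std: float
    snr: float
    anticorrelation_r: float | None = None


def roi_metrics(map_a, roi, map_b=None, detrend: str = "none") -> ROIMetrics:
    """Mean, standard deviation, SNR and (optionally) the Pearson
    correlation with a second map inside a pixel box.

    ``roi`` is ``(row0, row1, col0, col1)`` (half-open).  With
    ``detrend='column'`` per-column means are removed before computing the
    standard deviation and correlation — appropriate for scout images of
    z-invariant objects, where all structure lives in the column
    direction; the SNR numerator stays the raw ROI mean.
    """
    r0, r1, c0, c1 = roi
    a = np.asarray(map_a, dtype=float)[r0:r1, c0:c1]
    if a.size < 16:
        raise StatsError("ROI must contain at least 16 pixels")

    def _resid(img):
        if detrend == "none":
            return img - img.mean()
        if detrend == "column":
            return img - img.mean(axis=0, keepdims=True)
        raise StatsError(f"unknown detrend mode {detrend!r}")

    ra = _resid(a)
    std = float(ra.std(ddof=1))
    if std == 0:
        raise StatsError("constant ROI; SNR undefined")
    out = ROIMetrics(roi=tuple(roi), mean=float(a.mean()), std=std, snr=float(a.mean()) / std)
    if map_b is not None:
        b = np.asarray(map_b, dtype=float)[r0:r1, c0:c1]
        rb = _resid(b)
        out.anticorrelation_r = float(np.corrcoef(ra.ravel(), rb.ravel())[0, 1])
    return out


# --------------------------------------------------------------------- #
# cohort-level analysis


@dataclass
class CohortAnalysis:
    regressions: dict
    rocs: dict
    roc_tables: dict
    skipped: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "regressions": {k: v.as_dict() for k, v in self.regressions.items()},
            "rocs": {k: v.as_dict() for k, v in self.rocs.items()},
            "skipped": self.skipped,
        }


#: analysis views: cohort-table column -> (name, ROC ground-truth threshold
#: in mg/mL).  Projected views classify osteoporotic (<80); the measured
#: scout view classifies osteopenic-plus-osteoporotic (<120), where the
#: noisy measurement still has enough statistics.
DEFAULT_VIEWS = {
    "abmd_measured_ap": {"name": "measured_AP", "truth_threshold": 120.0},
    "abmd_projected_ap": {"name": "projected_AP", "truth_threshold": 80.0},
    "abmd_projected_lateral": {"name": "projected_lateral", "truth_threshold": 80.0},
}


def run_cohort_analysis(cohort, views: dict | None = None, per_patient: bool = True):
    """Regression and ROC analysis of a cohort table.

    For each available aBMD view, regresses aBMD on trabecular vBMD and
    runs a ROC analysis of the aBMD score against the vBMD-derived class
    label at the view's threshold.  ``per_patient`` selects the per-patient
    aggregate rows (the default analysis input); otherwise per-vertebra
    rows are used.
    """
    views = views if views is not None else DEFAULT_VIEWS
    df = cohort[cohort["vertebra"] == "mean"] if per_patient else cohort[cohort["vertebra"] != "mean"]
    if "vbmd" not in df.columns:
        raise StatsError("cohort table lacks the vbmd column")
    missing = [c for c in views if c not in df.columns]

    regressions, rocs, tables, skipped = {}, {}, {}, {}
    for col, cfg in views.items():
        name = cfg["name"]
        if col in missing or df[col].isna().all():
            skipped[name] = "column missing"
            continue
        sub = df.dropna(subset=[col, "vbmd"])
        x = sub["vbmd"].to_numpy()
        y = sub[col].to_numpy()
        try:
            regressions[name] = linear_regression_ci(x, y)
        except StatsError as exc:
            skipped[name] = f"regression skipped: {exc}"
            continue
        labels = x < cfg["truth_threshold"]
        try:
            roc = roc_curve(y, labels, positive_is_low=True)
        except StatsError as exc:
            skipped[name] = f"ROC skipped: {exc}"
            continue
        rocs[name] = roc
        tables[name] = {
            "threshold": roc.thresholds.tolist(),
            "tpr": roc.tpr.tolist(),
            "fpr": roc.fpr.tolist(),
            "minimum_distance": [
                t == roc.operating_point["threshold"] for t in roc.thresholds
            ],
        }
    return CohortAnalysis(regressions=regressions, rocs=rocs, roc_tables=tables, skipped=skipped)
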