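"""Group comparisons and diagnostic evaluation of candidate biomarkers.

Implements the statistics stage of the analysis: pooled-variance t tests
and chi-square for group characteristics, Pearson correlations between the
cognitive screening score and regional mean-HbO, and the full
discrimination analysis — empirical ROC curve, trapezoid AUC (identical to
the Mann-Whitney pairwise statistic), Youden-optimal cutoff, confusion
matrix, and predictive values.

Two predictive-value conventions are supported, because published
screening tables sometimes treat the predicted-*healthy* row as the
positive test class:

``mci_positive`` (library default)
    PPV = P(MCI | predicted MCI), NPV = P(healthy | predicted healthy).
``healthy_positive``
    PPV = P(healthy | predicted healthy), NPV = P(MCI | predicted MCI);
    on any confusion matrix the two conventions simply swap (PPV, NPV).

All candidate scores here (regional mHbO and MoCA-K alike) are *lower* in
MCI, so the default ROC orientation classifies a subject as MCI iff the
score falls at or below the cutoff; cutoffs are reported as midpoints
between adjacent observed scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import validate_feature_table

SCORE_COLUMNS = ("mhbo_left", "mhbo_right", "mhbo_total", "moca_k")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: float
    p_value: float
    kind: str  # "t" or "chi2"
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be positive")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ROCCurve:
    """Ordered (threshold, sensitivity, specificity) triples plus AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str = "low_scores_positive"

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if not 0 <= self.auc <= 1:
            raise ValueError("auc outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "thresholds": [str(x) if not np.isfinite(x) else float(x)
                           for x in self.thresholds],
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "auc": self.auc,
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROCCurve":
        thr = np.array([float(x) for x in d["thresholds"]])
        return cls(
            thresholds=thr,
            sensitivity=np.asarray(d["sensitivity"], float),
            specificity=np.asarray(d["specificity"], float),
            auc=float(d["auc"]),
            orientation=d.get("orientation", "low_scores_positive"),
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts by predicted row x true column for the two groups."""

    pred_healthy_true_healthy: int
    pred_healthy_true_mci: int
    pred_mci_true_healthy: int
    pred_mci_true_mci: int

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be non-negative integers")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.pred_healthy_true_healthy,
            self.pred_healthy_true_mci,
            self.pred_mci_true_healthy,
            self.pred_mci_true_mci,
        )

    @property
    def n_healthy(self) -> int:
        return self.pred_healthy_true_healthy + self.pred_mci_true_healthy

    @property
    def n_mci(self) -> int:
        return self.pred_healthy_true_mci + self.pred_mci_true_mci


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    youden_j: float
    ppv: float
    npv: float
    cutoff: float
    convention: str = "mci_positive"

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0 <= v <= 1):
                raise ValueError(f"{name} outside [0, 1]")
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1)) > 1e-12:
            raise ValueError("youden_j must equal sensitivity + specificity - 1")


# ---------------------------------------------------------------------------
# Elementary comparisons
# ---------------------------------------------------------------------------


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> GroupComparison:
    """Pooled-variance two-sample t from summary statistics.

    df = n1 + n2 - 2, two-sided p.  The statistic is positive when group 1
    exceeds group 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    t = float(res.statistic)
    if not np.isfinite(t):
        raise FloatingPointError("infinite t: zero pooled variance with unequal means")
    return GroupComparison(
        statistic=t,
        df=n1 + n2 - 2,
        p_value=float(res.pvalue),
        kind="t",
        detail={"mean1": mean1, "sd1": sd1, "n1": n1, "mean2": mean2, "sd2": sd2, "n2": n2},
    )


def pooled_t_test_from_data(
    x1: np.ndarray, x2: np.ndarray, equal_var: bool = True
) -> GroupComparison:
    """Two-sample t from raw data (pooled variance by default, Welch optional)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    res = stats.ttest_ind(x1, x2, equal_var=equal_var)
    df = (len(x1) + len(x2) - 2) if equal_var else float(res.df)
    return GroupComparison(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        kind="t",
        detail={
            "mean1": float(x1.mean()), "sd1": float(x1.std(ddof=1)), "n1": len(x1),
            "mean2": float(x2.mean()), "sd2": float(x2.std(ddof=1)), "n2": len(x2),
            "equal_var": equal_var,
        },
    )


def chi_square_2x2(counts: np.ndarray) -> GroupComparison:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    counts = np.asarray(counts, float)
    if counts.shape != (2, 2):
        raise ValueError("counts must be 2x2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must all be positive")
    return GroupComparison(statistic=float(chi2), df=dof, p_value=float(p), kind="chi2",
                           detail={"counts": counts.astype(int).tolist()})


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


def empirical_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    orientation: str = "low_scores_positive",
) -> ROCCurve:
    """Empirical ROC with thresholds at score midpoints plus +-infinity.

    With the default orientation a subject is classified MCI (positive)
    iff score <= threshold.  The trapezoid AUC equals the Mann-Whitney
    statistic P(score_mci < score_healthy) + 0.5 P(equal).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if orientation not in ("low_scores_positive", "high_scores_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    pos = labels == "mci"
    neg = labels == "healthy"
    if not pos.any() or not neg.any():
        raise ValueError("both groups must be represented")
    if orientation == "high_scores_positive":
        # flip so that "<= threshold" classifies positive
        scores = -scores

    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("single distinct score; degenerate ROC (AUC = 0.5)")
        thresholds = np.array([-np.inf, np.inf])
        sens = np.array([0.0, 1.0])
        spec = np.array([1.0, 0.0])
        return ROCCurve(thresholds, sens, spec, auc=0.5, orientation=orientation)

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # classified positive iff score <= threshold
    pos_sorted = np.sort(scores[pos])
    neg_sorted = np.sort(scores[neg])
    tp = np.searchsorted(pos_sorted, thresholds, side="right")
    fp = np.searchsorted(neg_sorted, thresholds, side="right")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    fpr = fp / n_neg
    auc = float(np.trapezoid(sens, fpr))
    if orientation == "high_scores_positive":
        thresholds = -thresholds
    return ROCCurve(thresholds, sens, spec, auc=auc, orientation=orientation)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-count AUC oracle: P(mci < healthy) + 0.5 P(tie).

    Brute force over all positive/negative pairs; independent of the
    trapezoid path, kept for cross-checking.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    s_pos = scores[labels == "mci"]
    s_neg = scores[labels == "healthy"]
    diff = s_pos[:, None] - s_neg[None, :]
    return float(((diff < 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def youden_optimal_cutoff(
    roc: ROCCurve, convention: str = "mci_positive"
) -> DiagnosticMetrics:
    """Metrics at the cutoff maximizing J = sensitivity + specificity - 1.

    Ties in J are broken toward higher sensitivity (favoring MCI
    detection).  Predictive values are NaN here (they need counts; see
    :func:`predictive_values`).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    if np.all(j <= 0):
        warnings.warn("degenerate ROC curve: no cutoff improves on chance")
    order = np.lexsort((roc.sensitivity, j))  # last entry = max J, then max sens
    best = order[-1]
    return DiagnosticMetrics(
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        youden_j=float(j[best]),
        ppv=float("nan"),
        npv=float("nan"),
        cutoff=float(roc.thresholds[best]),
        convention=convention,
    )


def confusion_at_cutoff(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float,
    orientation: str = "low_scores_positive",
) -> ConfusionMatrix:
    """Classify MCI iff score <= cutoff (default orientation) and count."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pred_mci = scores <= cutoff if orientation == "low_scores_positive" else scores >= cutoff
    return ConfusionMatrix(
        pred_healthy_true_healthy=int((~pred_mci & (labels == "healthy")).sum()),
        pred_healthy_true_mci=int((~pred_mci & (labels == "mci")).sum()),
        pred_mci_true_healthy=int((pred_mci & (labels == "healthy")).sum()),
        pred_mci_true_mci=int((pred_mci & (labels == "mci")).sum()),
    )


def predictive_values(
    cm: ConfusionMatrix, convention: str = "mci_positive"
) -> tuple[float, float]:
    """(PPV, NPV) under the requested positive-class convention."""
    hh, hm, mh, mm = cm.as_tuple()
    pred_healthy = hh + hm
    pred_mci = mh + mm
    if pred_healthy == 0 or pred_mci == 0:
        raise ValueError("empty predicted class; predictive values undefined")
    p_healthy_row = hh / pred_healthy
    p_mci_row = mm / pred_mci
    if convention == "mci_positive":
        return p_mci_row, p_healthy_row
    if convention == "healthy_positive":
        return p_healthy_row, p_mci_row
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticReport:
    """Per-candidate discrimination results plus score correlations."""

    candidates: dict  # name -> dict of results
    correlations: dict  # mhbo column -> {"r": ..., "p": ...}
    ranking: list  # candidate names by descending Youden J
    n_healthy: int = 0
    n_mci: int = 0

    def to_dict(self) -> dict:
        out = {
            "candidates": {},
            "correlations": self.correlations,
            "ranking": self.ranking,
            "n_healthy": self.n_healthy,
            "n_mci": self.n_mci,
        }
        for name, c in self.candidates.items():
            out["candidates"][name] = {
                "group_stats": c["group_stats"],
                "t": c["t"].__dict__ | {},
                "roc": c["roc"].to_dict(),
                "metrics": c["metrics"].__dict__ | {},
                "confusion": list(c["confusion"].as_tuple()),
                "predictive": c["predictive"],
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosticReport":
        candidates = {}
        for name, c in d["candidates"].items():
            t = c["t"]
            candidates[name] = {
                "group_stats": c["group_stats"],
                "t": GroupComparison(
                    statistic=t["statistic"], df=t["df"], p_value=t["p_value"],
                    kind=t["kind"], detail=t.get("detail", {}),
                ),
                "roc": ROCCurve.from_dict(c["roc"]),
                "metrics": DiagnosticMetrics(**c["metrics"]),
                "confusion": ConfusionMatrix(*c["confusion"]),
                "predictive": c["predictive"],
            }
        return cls(
            candidates=candidates,
            correlations=d["correlations"],
            ranking=d["ranking"],
            n_healthy=d.get("n_healthy", 0),
            n_mci=d.get("n_mci", 0),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DiagnosticReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate_biomarkers(features: pd.DataFrame) -> DiagnosticReport:
    """Full diagnostic comparison of the four candidate scores.

    For each of mHbO left/right/total and MoCA-K: group t test, empirical
    ROC with AUC, Youden-optimal cutoff with sensitivity/specificity,
    confusion matrix at that cutoff, and predictive values under both
    conventions; plus Pearson correlations of MoCA-K with each regional
    mHbO.  Candidates are ranked by Youden J.
    """
    features = validate_feature_table(features)
    labels = features["group"].to_numpy()
    n_h = int((labels == "healthy").sum())
    n_m = int((labels == "mci").sum())
    if n_h == 0 or n_m == 0:
        raise ValueError("both groups must be present")

    candidates = {}
    for name in SCORE_COLUMNS:
        scores = features[name].to_numpy(float)
        healthy = scores[labels == "healthy"]
        mci = scores[labels == "mci"]
        t = pooled_t_test_from_data(healthy, mci)
        roc = empirical_roc(scores, labels, orientation="low_scores_positive")
        metrics = youden_optimal_cutoff(roc)
        cm = confusion_at_cutoff(scores, labels, metrics.cutoff)
        ppv_m, npv_m = predictive_values(cm, "mci_positive")
        ppv_h, npv_h = predictive_values(cm, "healthy_positive")
        candidates[name] = {
            "group_stats": {
                "healthy_mean": float(healthy.mean()),
                "healthy_sd": float(healthy.std(ddof=1)),
                "mci_mean": float(mci.mean()),
                "mci_sd": float(mci.std(ddof=1)),
            },
            "t": t,
            "roc": roc,
            "metrics": DiagnosticMetrics(
                sensitivity=metrics.sensitivity,
                specificity=metrics.specificity,
                youden_j=metrics.youden_j,
                ppv=ppv_m,
                npv=npv_m,
                cutoff=metrics.cutoff,
                convention="mci_positive",
            ),
            "confusion": cm,
            "predictive": {
                "mci_positive": {"ppv": ppv_m, "npv": npv_m},
                "healthy_positive": {"ppv": ppv_h, "npv": npv_h},
            },
        }

    correlations = {}
    moca = features["moca_k"].to_numpy(float)
    for name in ("mhbo_left", "mhbo_right", "mhbo_total"):
        r, p = pearson_r(moca, features[name].to_numpy(float))
        correlations[name] = {"r": r, "p": p}

    ranking = sorted(
        candidates, key=lambda n: candidates[n]["metrics"].youden_j, reverse=True
    )
    return DiagnosticReport(
        candidates=candidates,
        correlations=correlations,
        ranking=ranking,
        n_healthy=n_h,
        n_mci=n_m,
    )
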