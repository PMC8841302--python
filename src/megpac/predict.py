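"""Cohort bookkeeping, responder classification and ROC-based prediction.

Treatment response is defined on the 6-item Hamilton Depression Rating
Scale (HAM-D-6): the reduction ratio (baseline - endpoint) / baseline after
the first two weeks of treatment, with >= 50% defining a responder. Coupling
features (per-subject mean strengths of significant clusters) are related
to the reduction ratio by Pearson correlation and combined into a response
classifier by ordinary least squares on the binary label; discrimination is
summarized by the ROC curve, its area, and the Youden-optimal operating
point. The AUC reported here is in-sample (no held-out validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .stats import anova_from_summary


def reduction_ratio(baseline: float, endpoint: float) -> float:
    """(baseline - endpoint) / baseline of the HAM-D-6 score."""
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    if endpoint < 0:
        raise ValueError(f"endpoint must be non-negative, got {endpoint}")
    return (baseline - endpoint) / baseline


def classify_response(ratio: float) -> str:
    """Responder iff the reduction ratio is >= 50% (boundary inclusive)."""
    if ratio > 1:
        raise ValueError(f"reduction ratio cannot exceed 1, got {ratio}")
    return "responder" if ratio >= 0.5 else "non_responder"


@dataclass
class CohortCounts:
    """Enrollment/exclusion arithmetic for the analyzed cohort."""

    enrolled_mdd: int
    enrolled_hc: int
    excluded_ect: int = 0
    excluded_quality_mdd: int = 0
    excluded_quality_hc: int = 0
    excluded_switch: int = 0
    remaining_mdd: int = field(init=False)
    remaining_hc: int = field(init=False)
    analyzed_total: int = field(init=False)

    def __post_init__(self) -> None:
        for name in (
            "enrolled_mdd", "enrolled_hc", "excluded_ect",
            "excluded_quality_mdd", "excluded_quality_hc", "excluded_switch",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.remaining_mdd = (
            self.enrolled_mdd
            - self.excluded_ect
            - self.excluded_quality_mdd
            - self.excluded_switch
        )
        self.remaining_hc = self.enrolled_hc - self.excluded_quality_hc
        if self.remaining_mdd < 0 or self.remaining_hc < 0:
            raise ValueError("exclusions exceed enrollment")
        self.analyzed_total = self.remaining_mdd + self.remaining_hc


def exclusion_cascade(
    enrolled_mdd: int,
    enrolled_hc: int,
    excluded_ect: int = 0,
    excluded_quality_mdd: int = 0,
    excluded_quality_hc: int = 0,
    excluded_switch: int = 0,
) -> CohortCounts:
    """Apply the exclusion cascade and return the audited counts."""
    return CohortCounts(
        enrolled_mdd=enrolled_mdd,
        enrolled_hc=enrolled_hc,
        excluded_ect=excluded_ect,
        excluded_quality_mdd=excluded_quality_mdd,
        excluded_quality_hc=excluded_quality_hc,
        excluded_switch=excluded_switch,
    )


def correlate_features(
    features: np.ndarray, ratios: np.ndarray
) -> list[tuple[float, float]]:
    """Pearson r (and two-sided p via the t transform) per feature column.

    ``features`` is (patients,) or (patients x k); ``ratios`` the matching
    reduction ratios. Correlations are computed over patients only —
    healthy controls have no reduction ratio.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    if f.shape[0] == 1 and np.asarray(features).ndim == 1:
        f = f.T
    r_vec = np.asarray(ratios, dtype=float)
    if f.shape[0] != r_vec.size:
        raise ValueError("feature rows must match number of ratios")
    if f.shape[0] < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(r_vec))):
        raise ValueError("non-finite inputs")
    out = []
    for j in range(f.shape[1]):
        col = f[:, j]
        if col.std() == 0 or r_vec.std() == 0:
            raise ValueError("zero variance in a correlated variable")
        r, p = stats.pearsonr(col, r_vec)
        out.append((float(r), float(p)))
    return out


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    sensitivity: float
    specificity: float
    threshold: float
    coefficients: np.ndarray | None = None
    single_feature_aucs: tuple[float, ...] = ()


def roc_from_scores(scores: np.ndarray, labels: np.ndarray, pos_label=1) -> RocResult:
    """ROC curve, trapezoidal AUC and the Youden-J operating point."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if scores.std() == 0:
        raise ValueError("constant score cannot rank subjects")
    fpr, tpr, thr = roc_curve(y, scores, pos_label=pos_label)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    k = int(np.argmax(j))
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        sensitivity=float(tpr[k]),
        specificity=float(1 - fpr[k]),
        threshold=float(thr[k]),
    )


def combine_and_roc(
    feature1: np.ndarray,
    feature2: np.ndarray,
    labels: np.ndarray,
    pos_label: str = "non_responder",
) -> RocResult:
    """Least-squares combination of two coupling features, scored by ROC.

    The two features are regressed onto the binary label (1 for
    ``pos_label``) by ordinary least squares with an intercept; the fitted
    score is the ROC input. Non-responders are the positive class by
    default — the clinical question is flagging patients unlikely to
    respond. Single-feature AUCs are reported alongside for comparison.
    """
    f1 = np.asarray(feature1, dtype=float)
    f2 = np.asarray(feature2, dtype=float)
    y_lab = np.asarray(labels)
    y = (y_lab == pos_label).astype(float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    X = np.column_stack([np.ones_like(f1), f1, f2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    score = X @ beta
    result = roc_from_scores(score, y, pos_label=1)
    result.coefficients = beta
    singles = []
    for f in (f1, f2):
        # orient each single feature so its AUC is >= 0.5
        r = roc_from_scores(f, y, pos_label=1)
        singles.append(max(r.auc, 1 - r.auc))
    result.single_feature_aucs = tuple(singles)
    return result


def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or table.sum() == 0:
        raise ValueError("malformed count table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def demographics_table(records: pd.DataFrame | list) -> pd.DataFrame:
    """Group-comparison table of demographics and baseline clinical scores.

    Accepts a subjects DataFrame (columns: group, age, sex, education,
    hamd6_baseline, hamd17_baseline, reduction_ratio) or a list of
    SubjectRecord. Continuous variables over three groups use one-way
    ANOVA; sex uses a Pearson chi-square on the count table; patient-only
    baseline scores use a pooled two-sample t test.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([vars(r) for r in records])
    df = records
    groups = ["responder", "non_responder", "HC"]
    present = [g for g in groups if (df["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two groups")
    rows = []

    def summarize(col, grp):
        v = df.loc[df["group"] == grp, col].dropna()
        return v.mean(), v.std(ddof=1), len(v)

    for col in ("age", "education"):
        if col not in df:
            continue
        sums = [summarize(col, g) for g in present]
        _, p = anova_from_summary(*(list(z) for z in zip(*sums)))
        rows.append({"variable": col, **{g: f"{m:.2f} ± {s:.2f}" for g, (m, s, _) in zip(present, sums)}, "p": p})

    if "sex" in df:
        tab = np.array(
            [[(df["group"].eq(g) & df["sex"].eq(s)).sum() for s in ("F", "M")] for g in present]
        )
        if tab.sum() > 0 and np.all(tab.sum(axis=1) > 0):
            _, p = chi_square_counts(tab)
            rows.append({"variable": "sex (F/M)", **{g: f"{tab[i,0]}/{tab[i,1]}" for i, g in enumerate(present)}, "p": p})

    patients = [g for g in ("responder", "non_responder") if g in present]
    if len(patients) == 2:
        for col in ("hamd17_baseline", "hamd6_baseline"):
            if col not in df:
                continue
            a = df.loc[df["group"] == "responder", col].dropna()
            b = df.loc[df["group"] == "non_responder", col].dropna()
            if len(a) > 1 and len(b) > 1:
                _, p = stats.ttest_ind(a, b, equal_var=True)
                rows.append(
                    {
                        "variable": col,
                        "responder": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                        "non_responder": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                        "p": float(p),
                    }
                )
    return pd.DataFrame(rows)
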