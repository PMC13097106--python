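"""Cohort-level statistics and adverse-event classification.

Subjects are labelled adverse / nonadverse from logged intradialytic events
(including intradialytic hypotension derived from blood-pressure records).
Start-to-end delta metrics and absolute scattering parameters are compared
between groups with two-sample t-tests, and fed to a linear discriminant
classifier (shared-covariance Gaussian model with a mild ridge) evaluated
by resubstitution or leave-one-out, with ROC/AUC summaries, exhaustive
small-subset feature search, and an AUC-versus-%-completion curve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "SessionLabel",
    "GroupComparison",
    "ClassificationResult",
    "label_idh",
    "group_compare",
    "lda_fit_score",
    "roc_auc",
    "feature_subset_search",
    "auc_timecourse",
]

ADVERSE_EVENT_TYPES = (
    "vomiting",
    "cramping",
    "dizziness",
    "headache",
    "shortness_of_breath",
    "sweating",
    "stroke",
    "fluid_return",
    "IDH",
)


@dataclass
class SessionLabel:
    """Adverse-event labelling of one dialysis session."""

    subject_id: str
    events: list = field(default_factory=list)  # (time_min, type)
    hypotensive: bool = False

    def __post_init__(self) -> None:
        for _, etype in self.events:
            if etype not in ADVERSE_EVENT_TYPES:
                raise ValueError(f"unknown adverse event type {etype!r}")

    @property
    def adverse_event(self) -> bool:
        return len(self.events) > 0


def label_idh(bp_records) -> list[float]:
    """Intradialytic-hypotension times from a blood-pressure series.

    ``bp_records`` is a sequence of ``(time_min, sbp, map)`` tuples; MAP may
    be NaN. A record is flagged when systolic pressure has dropped at least
    20 mmHg, or mean arterial pressure at least 10 mmHg, below the
    pre-dialysis (first) reading.
    """
    records = [(float(t), float(s), float(m)) for t, s, m in bp_records]
    if len(records) < 2:
        raise ValueError("need at least two blood-pressure records")
    _, sbp0, map0 = records[0]
    if not np.isfinite(sbp0) and not np.isfinite(map0):
        warnings.warn("missing baseline blood pressure; no IDH labels", stacklevel=2)
        return []
    times = []
    for t, sbp, mean_ap in records[1:]:
        sbp_drop = np.isfinite(sbp) and np.isfinite(sbp0) and (sbp0 - sbp >= 20.0)
        map_drop = (
            np.isfinite(mean_ap) and np.isfinite(map0) and (map0 - mean_ap >= 10.0)
        )
        if sbp_drop or map_drop:
            times.append(t)
    return times


@dataclass
class GroupComparison:
    """Two-sample comparison of one metric between labelled groups."""

    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    n_pos: int
    n_neg: int
    t_statistic: float
    p_value: float


def group_compare(values, labels, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test (pooled by default; Welch optional).

    ``labels`` are booleans (True = adverse); missing values are dropped
    per group. Raises if either group has no valid values.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    pos = v[lab & np.isfinite(v)]
    neg = v[~lab & np.isfinite(v)]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two valid values per group")
    t, p = stats.ttest_ind(pos, neg, equal_var=equal_var)
    return GroupComparison(
        mean_pos=float(np.mean(pos)),
        mean_neg=float(np.mean(neg)),
        sd_pos=float(np.std(pos, ddof=1)),
        sd_neg=float(np.std(neg, ddof=1)),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        t_statistic=float(t),
        p_value=float(p),
    )


@dataclass
class ClassificationResult:
    """Discriminant-analysis output for one feature subset."""

    features: tuple
    scores: np.ndarray  # decision scores, higher = more adverse-like
    labels: np.ndarray
    subject_ids: list
    tp: int
    tn: int
    fp: int
    fn: int
    roc_points: np.ndarray  # columns: fpr, tpr
    auc: float
    validation_tag: str
    n_dropped_missing: int = 0

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return self.tp, self.tn, self.fp, self.fn


def _lda_train(x: np.ndarray, y: np.ndarray, ridge: float):
    """Fit the shared-covariance linear discriminant; returns (w, threshold)."""
    x0 = x[~y]
    x1 = x[y]
    mu0 = x0.mean(axis=0)
    mu1 = x1.mean(axis=0)
    n0, n1 = x0.shape[0], x1.shape[0]
    cov = ((n0 - 1) * np.cov(x0, rowvar=False, ddof=1)
           + (n1 - 1) * np.cov(x1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    cov = np.atleast_2d(cov)
    scale = np.trace(cov) / cov.shape[0]
    if scale <= 0 or not np.isfinite(scale):
        raise np.linalg.LinAlgError("degenerate covariance")
    cov_r = cov + ridge * scale * np.eye(cov.shape[0])
    w = np.linalg.solve(cov_r, mu1 - mu0)
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError("singular covariance after regularization")
    # equal-cost Gaussian decision threshold with empirical priors
    thresh = 0.5 * w @ (mu0 + mu1) - np.log(n1 / n0)
    return w, thresh


def lda_fit_score(
    features: pd.DataFrame,
    feature_subset,
    label_column: str = "adverse_event",
    validation: str = "resubstitution",
    ridge: float = 1e-8,
    standardize: bool = True,
) -> ClassificationResult:
    """Linear discriminant analysis on a feature table.

    Rows with missing values in the subset are dropped (and counted).
    ``validation`` is ``"resubstitution"`` (score the training set) or
    ``"loocv"`` (leave-one-out: each subject scored by a model trained
    without it). Scores feed the ROC; the confusion matrix uses the
    Gaussian-model threshold with empirical priors.
    """
    subset = tuple(feature_subset)
    if not subset:
        raise ValueError("feature subset must be nonempty")
    if validation not in ("resubstitution", "loocv"):
        raise ValueError("validation must be 'resubstitution' or 'loocv'")
    cols = list(subset)
    table = features[cols + [label_column]]
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    y = complete[label_column].to_numpy(dtype=bool)
    x = complete[cols].to_numpy(dtype=float)
    if (~y).sum() < 2 or y.sum() < 2:
        raise ValueError("need at least two subjects per class")
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd

    if validation == "resubstitution":
        w, thresh = _lda_train(x, y, ridge)
        scores = x @ w - thresh
    else:
        scores = np.empty(y.size)
        for i in range(y.size):
            mask = np.ones(y.size, dtype=bool)
            mask[i] = False
            if (~y[mask]).sum() < 2 or y[mask].sum() < 2:
                raise ValueError("leave-one-out leaves fewer than two per class")
            w, thresh = _lda_train(x[mask], y[mask], ridge)
            scores[i] = x[i] @ w - thresh

    pred = scores > 0
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    roc_points, auc = roc_auc(scores, y)
    return ClassificationResult(
        features=subset,
        scores=scores,
        labels=y,
        subject_ids=list(complete.index),
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        roc_points=roc_points,
        auc=auc,
        validation_tag=validation,
        n_dropped_missing=n_dropped,
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and AUC (Mann-Whitney concordance; ties count 0.5)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return np.column_stack([fpr, tpr]), auc


def feature_subset_search(
    features: pd.DataFrame,
    candidate_features=None,
    max_subset_size: int = 3,
    label_column: str = "adverse_event",
    validation: str = "resubstitution",
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Exhaustive AUC ranking of all feature subsets up to a given size.

    Ties are broken toward smaller subsets, then lexically. Subsets that
    fail to fit (for example from missingness) are skipped and logged in
    the ``error`` column.
    """
    if candidate_features is None:
        candidate_features = [c for c in features.columns if c != label_column]
    candidate_features = list(candidate_features)
    if len(candidate_features) > 15:
        raise ValueError("exhaustive search limited to 15 candidate features")
    rows = []
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(sorted(candidate_features), size):
            try:
                res = lda_fit_score(
                    features, subset, label_column=label_column,
                    validation=validation, ridge=ridge,
                )
                rows.append(
                    {"subset": subset, "size": size, "auc": res.auc,
                     "n_used": len(res.subject_ids), "error": ""}
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {"subset": subset, "size": size, "auc": np.nan,
                     "n_used": 0, "error": str(exc)}
                )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["auc", "size", "subset"], ascending=[False, True, True],
        na_position="last",
    ).reset_index(drop=True)
    return table


def auc_timecourse(
    feature_traces: dict,
    labels: pd.Series,
    feature_subset,
    validation: str = "loocv",
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Classification AUC at each percent-completion grid point.

    ``feature_traces`` maps feature name to a DataFrame (subjects x percent
    grid) of that feature's value at each completion fraction. At each grid
    point an LDA on the subset is fitted and scored; points where fewer
    than two subjects per class have complete data yield NaN.
    """
    subset = tuple(feature_subset)
    grids = {f: df.columns.to_numpy(dtype=float) for f, df in feature_traces.items()}
    grid = grids[subset[0]]
    for f in subset[1:]:
        if not np.array_equal(grids[f], grid):
            raise ValueError("feature traces must share the percent grid")
    rows = []
    for g in grid:
        tbl = pd.DataFrame(
            {f: feature_traces[f].loc[:, g] for f in subset}
        )
        tbl["adverse_event"] = labels.reindex(tbl.index)
        try:
            res = lda_fit_score(tbl, subset, validation=validation, ridge=ridge)
            rows.append({"percent": g, "auc": res.auc,
                         "n_used": len(res.subject_ids)})
        except (ValueError, np.linalg.LinAlgError):
            rows.append({"percent": g, "auc": np.nan, "n_used": 0})
    return pd.DataFrame(rows)
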