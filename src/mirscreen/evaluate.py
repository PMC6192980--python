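"""Diagnostic evaluation: ROC/AUC, fixed-threshold performance, subgroup
accuracy tables, and (age-adjusted) logistic odds ratios.

AUC uses the tie-corrected Mann-Whitney rank statistic, so it agrees
exactly with the single-marker AUC used for pivot ranking. Sensitivity,
specificity and accuracy are reported at the published decision threshold
(index >= 0 positive); a Youden-optimal threshold is available for
synthetic studies. Logistic regression is fit by IRLS (statsmodels GLM,
binomial family) and odds ratios are reported per unit diagnostic index
with Wald 95% confidence intervals, optionally adjusted for age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from .pivot_selection import rank_auc


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self):
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.tpr,
             "one_minus_specificity": self.fpr}
        )


def roc(scores, labels):
    """ROC coordinates over all distinct thresholds + rank-statistic AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = rank_auc(scores, labels)  # raises on single-class input
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


class Performance(NamedTuple):
    sensitivity: float
    specificity: float
    accuracy: float


def performance_at_zero(indices, labels):
    """Sensitivity/specificity/accuracy of the ``index >= 0`` call."""
    indices = np.asarray(indices, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos = indices >= 0
    tp = int((pos & (labels == 1)).sum())
    fn = int((~pos & (labels == 1)).sum())
    tn = int((~pos & (labels == 0)).sum())
    fp = int((pos & (labels == 0)).sum())
    return Performance(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / labels.size,
    )


def youden_threshold(scores, labels):
    """Threshold maximizing sensitivity + specificity - 1."""
    r = roc(scores, labels)
    j = r.tpr - r.fpr
    return float(r.thresholds[int(np.argmax(j))])


def subgroup_accuracy(results, meta, by, case_groups=None, groups=None):
    """Per-group call rates and mean index.

    ``results`` needs columns sample_id, index, call; ``meta`` supplies the
    grouping column ``by``. For groups in ``case_groups`` the reported
    accuracy is the positive-call rate, for the rest the negative-call rate.
    Defaults: grouping by stage treats every group as cases; grouping by
    class_label treats only ovarian_cancer (and non_epithelial) as cases.
    """
    if by not in meta.columns:
        raise KeyError(f"grouping column {by!r} absent from metadata")
    if case_groups is None:
        if by == "stage":
            case_groups = set(meta[by].unique()) - {"NA"}
        elif by == "class_label":
            case_groups = {"ovarian_cancer", "non_epithelial"}
        else:
            case_groups = set()
    merged = results.merge(meta[["sample_id", by]], on="sample_id", how="left")
    if groups is None:
        groups = [g for g in merged[by].dropna().unique()]
    rows = []
    for g in groups:
        sub = merged[merged[by] == g]
        if len(sub) == 0:
            warnings.warn(f"empty group {g!r} in subgroup table", stacklevel=2)
            rows.append({by: g, "n": 0, "accuracy": np.nan, "mean_index": np.nan})
            continue
        pos_rate = float((sub["call"] == "positive").mean())
        acc = pos_rate if g in case_groups else 1.0 - pos_rate
        rows.append(
            {by: g, "n": len(sub), "accuracy": acc,
             "mean_index": float(sub["index"].mean())}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic odds ratios (Table-3 style)
# ---------------------------------------------------------------------------

@dataclass
class ORResult:
    coef: float
    se: float

    @property
    def odds_ratio(self):
        return float(np.exp(self.coef))

    @property
    def ci(self):
        return (
            float(np.exp(self.coef - 1.96 * self.se)),
            float(np.exp(self.coef + 1.96 * self.se)),
        )


@dataclass
class LogisticFit:
    univariable: ORResult
    age_adjusted: ORResult | None = None


def _irls_logit(Xd, y):
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(maxiter=100)
        except (PerfectSeparationWarning, PerfectSeparationError) as exc:
            raise ValueError("non-finite MLE: complete separation") from exc
    if not res.converged:
        raise ValueError("logistic IRLS did not converge within 100 iterations")
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        raise ValueError("non-finite MLE (complete separation?)")
    if np.any(np.abs(params) > 50):
        raise ValueError("non-finite MLE: complete separation")
    return params, bse


def logistic_odds_ratio(index, labels, age=None):
    """Odds ratio of ovarian cancer per unit diagnostic index.

    Fits ``label ~ index`` and, when ``age`` is given, ``label ~ index +
    age`` by maximum likelihood (IRLS); reports Wald 95% CIs on the
    odds-ratio scale.
    """
    index = np.asarray(index, dtype=float)
    y = np.asarray(labels).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need >=10 samples per class for the logistic fit")
    X1 = sm.add_constant(index)
    params, bse = _irls_logit(X1, y)
    uni = ORResult(coef=float(params[1]), se=float(bse[1]))
    adj = None
    if age is not None:
        age = np.asarray(age, dtype=float)
        X2 = sm.add_constant(np.column_stack([index, age]))
        params, bse = _irls_logit(X2, y)
        adj = ORResult(coef=float(params[1]), se=float(bse[1]))
    return LogisticFit(univariable=uni, age_adjusted=adj)
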