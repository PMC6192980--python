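"""Fisher linear discriminants and the exhaustive LOOCV panel search.

A diagnostic index is a linear score ``w . x + b`` over a panel of log2
miRNA signals; ``index >= 0`` calls ovarian cancer. Weights follow Fisher's
linear discriminant, ``w = S_pooled^-1 (mu_1 - mu_0)`` with the pooled
within-class covariance, and the intercept places the decision boundary at
the class-mean midpoint, ``b = -w . (mu_0 + mu_1) / 2`` (equal priors: the
index is a screening score whose 0 threshold must not depend on cohort
prevalence).

Panel construction enumerates every subset of the pivot miRNAs up to
``max_panel`` members and scores each by leave-one-out cross-validation on
the discovery set; the winner is chosen by (higher metric, smaller panel,
higher training AUC, lexicographically smaller panel) and refit on the full
discovery set. LOOCV is exact but does not refit from scratch: class means
and scatter matrices are downdated per fold and the pooled-scatter inverse
is updated by a rank-1 Sherman-Morrison step, so each fold costs O(p^2).
A plain per-fold refit remains available (``naive=True``) and is the
fallback when the pooled scatter is not positive definite.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .pivot_selection import rank_auc

RIDGE_EPS = 1e-6


class DegenerateSeparationError(ValueError):
    pass


@dataclass
class SearchConfig:
    max_panel: int = 10
    selection_metric: str = "balanced_accuracy"  # or "accuracy"

    def __post_init__(self):
        if self.max_panel < 1:
            raise ValueError("max_panel must be >= 1")
        if self.selection_metric not in ("accuracy", "balanced_accuracy"):
            raise ValueError(f"unknown metric {self.selection_metric!r}")


@dataclass
class DiscriminantModel:
    panel: tuple
    coefficients: np.ndarray
    intercept: float
    loocv_metric: float | None = None
    train_auc: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def panel_size(self):
        return len(self.panel)

    def index(self, X):
        """Diagnostic index for samples x panel data (array or DataFrame)."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.panel)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X @ self.coefficients + self.intercept

    def predict(self, X):
        """Binary calls: index >= 0 -> cancer (1)."""
        return (self.index(X) >= 0).astype(int)

    def to_json(self, path=None):
        rec = {
            "panel": list(self.panel),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "loocv_metric": self.loocv_metric,
            "train_auc": self.train_auc,
            "metadata": self.metadata,
        }
        text = json.dumps(rec, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            rec = json.load(fh)
        return cls(
            panel=tuple(rec["panel"]),
            coefficients=np.asarray(rec["coefficients"], dtype=float),
            intercept=rec["intercept"],
            loocv_metric=rec.get("loocv_metric"),
            train_auc=rec.get("train_auc"),
            metadata=rec.get("metadata", {}),
        )


def _as_array(X, panel=None):
    if isinstance(X, pd.DataFrame):
        if panel is None:
            panel = tuple(X.columns)
        else:
            panel = tuple(panel)
        return X[list(panel)].to_numpy(dtype=float), panel
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if panel is None:
        panel = tuple(range(X.shape[1]))
    return X, tuple(panel)


def _class_stats(X, y):
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    d0, d1 = X0 - mu0, X1 - mu1
    return X0, X1, mu0, mu1, d0.T @ d0, d1.T @ d1


def fit_fisher_lda(X, y, panel=None):
    """Fit a Fisher discriminant with midpoint intercept.

    ``w = S^-1 (mu_1 - mu_0)`` with S the pooled within-class covariance
    (denominator n - 2); if S is singular a ridge ``eps * trace(S)/p`` with
    eps = 1e-6 is added with a warning. Identical class means raise
    :class:`DegenerateSeparationError`.
    """
    X, panel = _as_array(X, panel)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes coded 0/1")
    _, _, mu0, mu1, s0, s1 = _class_stats(X, y)
    dmu = mu1 - mu0
    if np.allclose(dmu, 0):
        raise DegenerateSeparationError("degenerate separation: identical class means")
    S = (s0 + s1) / max(n - 2, 1)
    try:
        c, low = sla.cho_factor(S)
        w = sla.cho_solve((c, low), dmu)
    except np.linalg.LinAlgError:
        ridge = RIDGE_EPS * np.trace(S) / p
        if ridge <= 0:
            ridge = RIDGE_EPS
        warnings.warn(
            f"singular pooled covariance; adding ridge {ridge:.3g}", stacklevel=2
        )
        w = np.linalg.solve(S + ridge * np.eye(p), dmu)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return DiscriminantModel(panel=panel, coefficients=w, intercept=b)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _loocv_predictions_naive(X, y):
    """Per-fold refit LOOCV; the reference implementation."""
    n = X.shape[0]
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yt = y[mask]
        if len(np.unique(yt)) < 2:
            warnings.warn(f"fold {i}: single-class training set", stacklevel=2)
            preds[i] = 1 - y[i]  # counted as misclassified
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_fisher_lda(X[mask], yt)
        except DegenerateSeparationError:
            warnings.warn(f"fold {i}: degenerate separation", stacklevel=2)
            preds[i] = 1 - y[i]
            continue
        preds[i] = int(model.index(X[i])[0] >= 0)
    return preds


def _loocv_predictions_fast(X, y):
    """Vectorized exact LOOCV via rank-1 scatter downdates.

    Returns None when the total pooled scatter is not positive definite or a
    downdate turns numerically singular; callers then fall back to the naive
    path.
    """
    n, p = X.shape
    n1 = int(y.sum())
    n0 = n - n1
    if min(n0, n1) < 2 or n - 3 < 1:
        return None
    _, _, mu0, mu1, s0, s1 = _class_stats(X, y)
    T = s0 + s1
    try:
        c, low = sla.cho_factor(T)
    except np.linalg.LinAlgError:
        return None
    A = sla.cho_solve((c, low), np.eye(p))
    dmu = mu1 - mu0
    mid = (mu0 + mu1) / 2.0

    nk = np.where(y == 1, n1, n0).astype(float)
    sgn = np.where(y == 1, 1.0, -1.0)
    mu_own = np.where((y == 1)[:, None], mu1[None, :], mu0[None, :])
    U = X - mu_own                                  # x_i - mu_{class(i)}
    cfac = nk / (nk - 1.0)
    inv_nm1 = 1.0 / (nk - 1.0)

    AU = U @ A
    d = 1.0 - cfac * np.einsum("ij,ij->i", U, AU)
    if np.any(d < 1e-10):
        return None
    B = dmu[None, :] - (sgn * inv_nm1)[:, None] * U          # downdated dmu
    AB = B @ A
    coef = cfac * np.einsum("ij,ij->i", U, AB) / d
    W = AB + coef[:, None] * AU                               # ~ T_i^-1 dmu_i
    Z = X - mid[None, :] + 0.5 * inv_nm1[:, None] * U         # x_i - midpoint_i
    scores = np.einsum("ij,ij->i", W, Z)
    return (scores >= 0).astype(int)


def _metric(preds, y, metric):
    if metric == "accuracy":
        return float((preds == y).mean())
    acc1 = float((preds[y == 1] == 1).mean())
    acc0 = float((preds[y == 0] == 0).mean())
    return 0.5 * (acc1 + acc0)


def loocv_metric(X, y, panel=None, cfg=None, naive=False):
    """LOOCV selection metric (accuracy or balanced accuracy) for one panel."""
    if cfg is None:
        cfg = SearchConfig()
    X, _ = _as_array(X, panel)
    y = np.asarray(y).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >=2 samples per class for LOOCV")
    preds = None if naive else _loocv_predictions_fast(X, y)
    if preds is None:
        preds = _loocv_predictions_naive(X, y)
    return _metric(preds, y, cfg.selection_metric)


# ---------------------------------------------------------------------------
# exhaustive subset search
# ---------------------------------------------------------------------------

def subset_search(X, y, pivot_ids, cfg=None, return_leaderboard=False):
    """Enumerate every 1..max_panel subset of the pivots, score by LOOCV.

    Tie-break chain: higher metric, then smaller panel, then higher training
    AUC, then lexicographically smaller (sorted) panel. The winner is refit
    on the full data; its ``loocv_metric`` and ``train_auc`` fields are
    populated.
    """
    if cfg is None:
        cfg = SearchConfig()
    pivot_ids = list(pivot_ids)
    if not pivot_ids:
        raise ValueError("empty pivot set")
    if len(pivot_ids) > 20:
        raise ValueError(
            f"{len(pivot_ids)} pivots: exhaustive enumeration capped at 20"
        )
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=pivot_ids)
    y = np.asarray(y).astype(int)
    pool = X[pivot_ids].to_numpy(dtype=float)

    best = None  # (metric, -size, train_auc, neg-lex key, panel, model)
    rows = []
    for k in range(1, min(cfg.max_panel, len(pivot_ids)) + 1):
        for comb in itertools.combinations(range(len(pivot_ids)), k):
            panel = tuple(pivot_ids[i] for i in comb)
            Xs = pool[:, comb]
            m = loocv_metric(Xs, y, cfg=cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_fisher_lda(Xs, y, panel=panel)
            train_auc = rank_auc(model.index(Xs), y)
            rows.append(
                {
                    "panel": ",".join(panel),
                    "size": k,
                    "loocv_metric": m,
                    "train_auc": train_auc,
                }
            )
            cand = (m, -k, train_auc, tuple(sorted(panel)))
            if best is None or _beats(cand, best[0]):
                model.loocv_metric = m
                model.train_auc = train_auc
                model.metadata = {
                    "selection_metric": cfg.selection_metric,
                    "n_pivots": len(pivot_ids),
                    "max_panel": cfg.max_panel,
                }
                best = (cand, model)
    leaderboard = pd.DataFrame(rows)
    if return_leaderboard:
        return best[1], leaderboard
    return best[1]


def _beats(cand, incumbent):
    # first three elements maximized; final lexicographic key minimized
    for a, b in zip(cand[:3], incumbent[:3]):
        if a != b:
            return a > b
    return cand[3] < incumbent[3]
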