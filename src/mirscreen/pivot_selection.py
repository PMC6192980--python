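"""Single-marker AUC ranking, pivot selection, and qRT-PCR validation gates.

Each candidate miRNA is scored by the area under its single-marker ROC
curve, computed as the tie-corrected Mann-Whitney rank statistic
``AUC = P(X_case > X_control) + 0.5 P(X_case = X_control)``. Markers are
ranked by the *oriented* AUC ``max(AUC, 1 - AUC)`` so that miRNAs lowered
in cancer compete on equal footing; the top markers are the "pivot" miRNAs
that seed the combinatorial discriminant search.

Two correlation gates model the qRT-PCR validation step: a dilution-series
linearity gate (Pearson r > 0.9 between input amount and measured level)
and an array-vs-PCR concordance gate. The latter compares array log2
signals with Ct values, whose scale is inverted (lower Ct = more abundant),
so concordance passes when Pearson r < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def rank_auc(values, labels):
    """Tie-corrected AUC of ``values`` for the positive class (labels == 1).

    Mann-Whitney formulation via midranks; exactly equals the all-pairs
    count (concordant + half ties) / (n1 * n0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = sps.rankdata(values)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class MarkerAUC:
    mirna_id: str
    auc: float           # raw P(case > control) + half ties
    direction: int       # +1 if higher in cancer, -1 otherwise

    @property
    def oriented_auc(self):
        return max(self.auc, 1.0 - self.auc)


def marker_auc(values, labels, mirna_id=""):
    """Single-marker AUC with orientation (direction +1 = higher in cancer)."""
    auc = rank_auc(values, labels)
    return MarkerAUC(mirna_id=mirna_id, auc=auc, direction=1 if auc >= 0.5 else -1)


def rank_candidates(matrix, labels, candidates=None):
    """:class:`MarkerAUC` for each candidate column of a log2 matrix."""
    if candidates is None:
        candidates = matrix.probe_ids
    labels = np.asarray(labels).astype(int)
    return [
        marker_auc(matrix.values[c].to_numpy(dtype=float), labels, mirna_id=c)
        for c in candidates
    ]


def select_pivots(aucs, n_pivots=10):
    """Top ``n_pivots`` marker ids by oriented AUC.

    Ties resolve to the lexicographically smaller id. If fewer markers than
    requested are available all of them are returned with a warning.
    """
    ranked = sorted(aucs, key=lambda m: (-m.oriented_auc, m.mirna_id))
    if len(ranked) < n_pivots:
        warnings.warn(
            f"only {len(ranked)} markers available for {n_pivots} pivots",
            stacklevel=2,
        )
    return [m.mirna_id for m in ranked[:n_pivots]]


@dataclass
class PCRGateResult:
    mirna_id: str
    dilution_linearity_r: float
    concordance_r: float
    passed_quant: bool
    passed_concord: bool
    reason: str = ""

    @property
    def validated(self):
        return self.passed_quant and self.passed_concord


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >=3 points for a correlation gate")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(sps.pearsonr(x, y).statistic)


def pcr_gates(dilution_series, paired_measurements, mirna_id="", r_min=0.9,
              ct_convention=True):
    """Apply both qRT-PCR reproducibility gates to one miRNA.

    Parameters
    ----------
    dilution_series
        Sequence of (input amount, measured level) pairs; the quantitative
        gate passes when Pearson r > ``r_min``.
    paired_measurements
        Sequence of (array log2 signal, PCR readout) pairs. With
        ``ct_convention=True`` the PCR readout is a Ct value and the gate
        passes when r < 0; otherwise the readout is on an abundance scale
        and the gate passes when r > 0.
    """
    reasons = []
    r_dil = _pearson(*zip(*dilution_series))
    if np.isnan(r_dil):
        passed_quant = False
        reasons.append("zero variance in dilution series")
    else:
        passed_quant = r_dil > r_min

    r_conc = _pearson(*zip(*paired_measurements))
    if np.isnan(r_conc):
        passed_concord = False
        reasons.append("zero variance in concordance pairs")
    else:
        passed_concord = (r_conc < 0) if ct_convention else (r_conc > 0)

    return PCRGateResult(
        mirna_id=mirna_id,
        dilution_linearity_r=r_dil,
        concordance_r=r_conc,
        passed_quant=passed_quant,
        passed_concord=passed_concord,
        reason="; ".join(reasons),
    )
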