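"""Probe-level signal matrices, sample metadata, and array-level quality control.

The central container is :class:`ProbeSignalMatrix`: a samples x probes table
of microarray signals together with a probe-class annotation (``target``,
``negative_control``, ``internal_control``), a scale tag (``linear`` raw
scanner signals or ``log2`` processed signals) and a boolean detection mask.
Cells that were absent in the input, or that fall below the detection call
during preprocessing, are *undetected*: they carry a sentinel value and are
flagged ``False`` in the mask, which downstream normalization respects.

Quality control follows the array vendor's exclusion rule: a sample is
discarded when the coefficient of variation of its negative-control probes
exceeds ``cv_max`` (default 0.15) or when its scanner-flagged probe count
exceeds ``flag_max`` (default 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("target", "negative_control", "internal_control")
CLASS_LABELS = (
    "ovarian_cancer",
    "non_cancer",
    "other_cancer",
    "borderline",
    "benign",
    "non_epithelial",
)
STAGES = ("I", "II", "III_IV", "NA")
LINEAR = "linear"
LOG2 = "log2"

#: sentinel assigned on the log2 scale to undetected / floored probes
FLOOR_LOG2 = 0.1

META_COLUMNS = (
    "sample_id",
    "class_label",
    "stage",
    "age",
    "institute",
    "flagged_probe_count",
    "cancer_type",
)


class ProbeSignalMatrix:
    """Samples x probes signal matrix with probe-class annotation.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with probe ids as columns. Missing
        cells are interpreted as undetected.
    probe_class
        Mapping / Series probe id -> probe class. Probes absent from the
        annotation default to ``target`` with a warning.
    scale
        ``"linear"`` for raw scanner signals, ``"log2"`` for processed ones.
    detected
        Optional boolean DataFrame of the same shape; defaults to the
        non-missing cells of ``values``.
    """

    def __init__(self, values, probe_class, scale, detected=None):
        values = pd.DataFrame(values)
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated probe ids: {dups}")
        if scale not in (LINEAR, LOG2):
            raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")

        probe_class = pd.Series(dict(probe_class), dtype=object)
        bad = sorted(set(probe_class.unique()) - set(PROBE_CLASSES))
        if bad:
            raise ValueError(f"unknown probe classes: {bad}")
        missing = [p for p in values.columns if p not in probe_class.index]
        if missing:
            warnings.warn(
                f"{len(missing)} probes without annotation default to class "
                f"'target' (first: {missing[0]})",
                stacklevel=2,
            )
            probe_class = pd.concat(
                [probe_class, pd.Series("target", index=missing, dtype=object)]
            )

        values = values.astype(float)
        if detected is None:
            detected = values.notna()
        else:
            detected = pd.DataFrame(detected).astype(bool)
            detected = detected.reindex(index=values.index, columns=values.columns)
        self.values = values
        self.detected = detected
        self.probe_class = probe_class.reindex(values.columns)
        self.scale = scale

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def probe_ids(self):
        return list(self.values.columns)

    @property
    def n_samples(self):
        return self.values.shape[0]

    @property
    def n_probes(self):
        return self.values.shape[1]

    def probes_of_class(self, probe_cls):
        """Probe ids of a given class, in column order."""
        if probe_cls not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {probe_cls!r}")
        return [p for p in self.values.columns if self.probe_class[p] == probe_cls]

    # -- subsetting ----------------------------------------------------------
    def select_samples(self, sample_ids):
        sample_ids = list(sample_ids)
        return ProbeSignalMatrix(
            self.values.loc[sample_ids],
            self.probe_class,
            self.scale,
            detected=self.detected.loc[sample_ids],
        )

    def select_probes(self, probe_ids):
        probe_ids = list(probe_ids)
        return ProbeSignalMatrix(
            self.values[probe_ids],
            self.probe_class[probe_ids],
            self.scale,
            detected=self.detected[probe_ids],
        )

    def copy(self):
        return ProbeSignalMatrix(
            self.values.copy(), self.probe_class.copy(), self.scale,
            detected=self.detected.copy(),
        )

    def require_scale(self, scale):
        if self.scale != scale:
            raise ValueError(f"operation requires {scale} scale, matrix is {self.scale}")

    def check_preprocess_ready(self):
        """Minimum control content needed by the preprocessing stage."""
        n_ic = len(self.probes_of_class("internal_control"))
        n_nc = len(self.probes_of_class("negative_control"))
        if n_ic < 3:
            raise ValueError(f"need >=3 internal-control probes, found {n_ic}")
        if n_nc < 10:
            raise ValueError(f"need >=10 negative-control probes, found {n_nc}")

    def equals(self, other):
        return (
            self.scale == other.scale
            and self.values.equals(other.values)
            and self.detected.equals(other.detected)
            and self.probe_class.equals(other.probe_class)
        )


# ---------------------------------------------------------------------------
# file I/O (plain TSV; samples in rows, one header row of probe ids)
# ---------------------------------------------------------------------------

def read_signal_matrix(path, annotation_path, scale=LINEAR):
    """Read a signal matrix TSV plus a (probe_id, class) annotation TSV."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        raise ValueError(f"duplicated probe ids in {path}: {dup_cols}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"duplicated sample ids in {path}: {dups}")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].tolist()
        raise ValueError(f"duplicated probe ids in {path}: {dups}")
    def parse_cell(cell, row, col):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        text = str(cell).strip()
        if text == "":
            return np.nan
        try:
            # python float() round-trips repr output exactly
            return float(text)
        except ValueError:
            raise ValueError(
                f"non-numeric value in row {row!r}, column {col!r}: {cell!r}"
            ) from None

    values = pd.DataFrame(
        {
            col: [parse_cell(raw.loc[row, col], row, col) for row in raw.index]
            for col in raw.columns
        },
        index=raw.index,
    )
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if not {"probe_id", "class"}.issubset(ann.columns):
        raise ValueError("annotation file needs columns probe_id, class")
    if ann["probe_id"].duplicated().any():
        raise ValueError("duplicated probe ids in annotation")
    probe_class = ann.set_index("probe_id")["class"]
    return ProbeSignalMatrix(values, probe_class, scale)


def write_signal_matrix(matrix, path, annotation_path=None):
    matrix.values.to_csv(path, sep="\t", index_label="sample_id")
    if annotation_path is not None:
        ann = pd.DataFrame(
            {"probe_id": matrix.probe_class.index, "class": matrix.probe_class.values}
        )
        ann.to_csv(annotation_path, sep="\t", index=False)


def read_sample_meta(path):
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_meta(meta)


def write_sample_meta(meta, path):
    meta.to_csv(path, sep="\t", index=False)


def validate_sample_meta(meta):
    """Check the metadata contract; returns the (possibly coerced) frame."""
    meta = meta.copy()
    missing = [c for c in META_COLUMNS if c not in meta.columns and c != "cancer_type"]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if "cancer_type" not in meta.columns:
        meta["cancer_type"] = pd.NA
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in metadata")
    bad = set(meta["class_label"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    meta["stage"] = meta["stage"].fillna("NA")
    bad = set(meta["stage"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    staged = meta["stage"] != "NA"
    if (staged & (meta["class_label"] != "ovarian_cancer")).any():
        raise ValueError("stage must be NA for non ovarian_cancer samples")
    if (meta["flagged_probe_count"] < 0).any():
        raise ValueError("flagged_probe_count must be nonnegative")
    return meta


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-sample QC table plus the retained/excluded partition."""

    table: pd.DataFrame = field(repr=False)
    cv_max: float = 0.15
    flag_max: int = 10

    @property
    def retained(self):
        return self.table.loc[self.table["passed"], "sample_id"].tolist()

    @property
    def excluded(self):
        return self.table.loc[~self.table["passed"], "sample_id"].tolist()

    def write(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def negative_control_cv(matrix):
    """Per-sample CV (sample sd / mean) of negative-control signals.

    Computed on the linear scale with the n-1 standard deviation. Samples
    whose negative-control mean is zero get CV = inf ("degenerate controls").
    """
    matrix.require_scale(LINEAR)
    neg = matrix.probes_of_class("negative_control")
    if len(neg) < 2:
        raise ValueError("need >=2 negative-control probes for QC")
    sub = matrix.values[neg]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.inf
    return cv


def qc_filter(matrix, meta, cv_max=0.15, flag_max=10):
    """Drop samples failing the negative-control CV or flagged-probe rule.

    Exclusion uses strict inequalities: CV > ``cv_max`` or flagged count
    > ``flag_max`` excludes; values exactly at the threshold pass.
    """
    meta = validate_sample_meta(meta)
    flags = meta.set_index("sample_id")["flagged_probe_count"]
    missing = [s for s in matrix.sample_ids if s not in flags.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    cv = negative_control_cv(matrix)

    rows = []
    for sid in matrix.sample_ids:
        c = cv[sid]
        f = int(flags[sid])
        if not np.isfinite(c):
            passed, reason = False, "degenerate controls"
        elif c > cv_max and f > flag_max:
            passed, reason = False, f"negative-control CV {c:.4g} > {cv_max}; flagged {f} > {flag_max}"
        elif c > cv_max:
            passed, reason = False, f"negative-control CV {c:.4g} > {cv_max}"
        elif f > flag_max:
            passed, reason = False, f"flagged probes {f} > {flag_max}"
        else:
            passed, reason = True, ""
        rows.append(
            {
                "sample_id": sid,
                "neg_control_cv": c,
                "flagged_probe_count": f,
                "passed": passed,
                "reason": reason,
            }
        )
    report = QCReport(pd.DataFrame(rows), cv_max=cv_max, flag_max=flag_max)
    return matrix.select_samples(report.retained), report
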