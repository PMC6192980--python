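"""Detection call, background subtraction and internal-control normalization.

Raw linear signals become normalized log2 signals in three steps, all driven
by per-sample negative-control statistics:

1. *Detection call*: a probe is present when its signal exceeds
   mean + 2 x sd of the negative controls, after removing the single most
   and least intense control.
2. *Background subtraction*: the mean of the negative controls (top and
   bottom 5% by intensity removed) is subtracted from detected signals,
   which are then log2-transformed. Undetected or non-positive corrected
   signals are replaced by the constant 0.1 on the log2 scale.
3. *Internal-control normalization*: each array is shifted so that the mean
   log2 signal of three pre-selected internal-control miRNAs (miR-149-3p,
   miR-2861, miR-4463) equals a preset value. The shift is multiplicative on
   the linear scale and leaves the 0.1 floor sentinel untouched, so
   "undetected" stays a fixed code across arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import FLOOR_LOG2, LINEAR, LOG2, ProbeSignalMatrix

DEFAULT_INTERNAL_CONTROLS = ("miR-149-3p", "miR-2861", "miR-4463")


@dataclass
class NormalizationConfig:
    internal_control_ids: tuple = DEFAULT_INTERNAL_CONTROLS
    #: target mean log2 signal of the internal controls after normalization
    preset_value: float = 8.0

    def __post_init__(self):
        if not np.isfinite(self.preset_value):
            raise ValueError("preset_value must be finite")
        if len(self.internal_control_ids) < 1:
            raise ValueError("need at least one internal-control id")


@dataclass
class NegControlStats:
    """Per-sample negative-control summaries used by the detection call."""

    trimmed_detection_mean: float
    trimmed_detection_sd: float
    trimmed_background_mean: float

    @property
    def detection_threshold(self):
        return self.trimmed_detection_mean + 2.0 * self.trimmed_detection_sd


def detection_threshold(neg_signals):
    """Detection cut-off: mean + 2 sd after dropping the one min and one max.

    Requires at least four control signals so that two remain after the
    trim; the sd uses the n-1 denominator.
    """
    neg = np.asarray(neg_signals, dtype=float)
    if neg.size < 4:
        raise ValueError(f"need >=4 negative-control signals, got {neg.size}")
    trimmed = np.sort(neg, kind="stable")[1:-1]
    return float(trimmed.mean() + 2.0 * trimmed.std(ddof=1))


def trimmed_background_mean(neg_signals, trim_fraction=0.05):
    """Mean negative-control signal after removing the top and bottom
    ``trim_fraction`` (per side, count = floor(fraction x n); ties resolved
    by input order via a stable sort)."""
    neg = np.asarray(neg_signals, dtype=float)
    if neg.size == 0:
        raise ValueError("no negative-control signals")
    k = math.floor(trim_fraction * neg.size)
    ordered = np.sort(neg, kind="stable")
    if k > 0:
        ordered = ordered[k : neg.size - k]
    return float(ordered.mean())


def neg_control_stats(matrix):
    """Compute :class:`NegControlStats` for every sample of a linear matrix."""
    matrix.require_scale(LINEAR)
    neg_ids = matrix.probes_of_class("negative_control")
    stats = {}
    for sid in matrix.sample_ids:
        neg = matrix.values.loc[sid, neg_ids].to_numpy(dtype=float)
        trimmed = np.sort(neg, kind="stable")[1:-1] if neg.size >= 4 else None
        if trimmed is None:
            raise ValueError(f"sample {sid!r}: need >=4 negative controls")
        stats[sid] = NegControlStats(
            trimmed_detection_mean=float(trimmed.mean()),
            trimmed_detection_sd=float(trimmed.std(ddof=1)),
            trimmed_background_mean=trimmed_background_mean(neg),
        )
    return stats


def background_correct(matrix):
    """Apply the detection call and background subtraction; return log2 matrix.

    Per sample: probes at or below the detection threshold are undetected;
    detected probes have the trimmed background mean subtracted and are
    log2-transformed. Any probe that is undetected, or whose corrected
    signal is not positive, receives the log2-scale floor value 0.1 and is
    marked undetected in the mask. Negative-control probes are dropped from
    the output.
    """
    matrix.require_scale(LINEAR)
    matrix.check_preprocess_ready()
    stats = neg_control_stats(matrix)
    keep = [
        p
        for p in matrix.probe_ids
        if matrix.probe_class[p] != "negative_control"
    ]
    vals = matrix.values[keep]
    in_detected = matrix.detected[keep].to_numpy()

    thr = np.array([stats[s].detection_threshold for s in matrix.sample_ids])
    bg = np.array([stats[s].trimmed_background_mean for s in matrix.sample_ids])

    raw = vals.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        detected = in_detected & (raw > thr[:, None])
        corrected = raw - bg[:, None]
        ok = detected & (corrected > 0)
    out = np.full(raw.shape, FLOOR_LOG2, dtype=float)
    out[ok] = np.log2(corrected[ok])
    return ProbeSignalMatrix(
        pd.DataFrame(out, index=vals.index, columns=vals.columns),
        matrix.probe_class[keep],
        LOG2,
        detected=pd.DataFrame(ok, index=vals.index, columns=vals.columns),
    )


def normalize_internal_controls(matrix, cfg=None):
    """Shift each array so its internal-control mean hits the preset value.

    The per-sample shift is ``preset_value - mean(log2 internal controls)``,
    computed over controls that were detected (not floored). Floored values
    keep the 0.1 sentinel. A sample whose internal controls are all floored
    cannot be normalized and raises an error naming it.
    """
    if cfg is None:
        cfg = NormalizationConfig()
    matrix.require_scale(LOG2)
    ic = [p for p in cfg.internal_control_ids if p in matrix.values.columns]
    if not ic:
        raise ValueError(
            f"none of the internal controls {cfg.internal_control_ids} present"
        )
    vals = matrix.values.copy()
    det = matrix.detected
    for sid in matrix.sample_ids:
        ok = [p for p in ic if det.loc[sid, p]]
        if not ok:
            raise ValueError(f"all internal controls undetected in sample {sid!r}")
        shift = cfg.preset_value - float(vals.loc[sid, ok].mean())
        row_det = det.loc[sid].to_numpy()
        row = vals.loc[sid].to_numpy(dtype=float)
        row[row_det] += shift
        vals.loc[sid] = row
    return ProbeSignalMatrix(vals, matrix.probe_class, LOG2, detected=det.copy())


def preprocess(matrix, cfg=None):
    """Full chain: background_correct then normalize_internal_controls."""
    return normalize_internal_controls(background_correct(matrix), cfg)
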