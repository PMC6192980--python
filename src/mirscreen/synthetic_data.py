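"""Synthetic serum miRNA-array cohorts with the structure the pipeline assumes.

The generator emulates a two-class (ovarian cancer vs. non-cancer) serum
microarray study: log-normal probe signals (Gaussian on the log2 scale), a
sparse set of informative miRNAs whose log2 abundance is shifted upward in
cancer with a FIGO-stage-graded effect, three stable internal-control
miRNAs, a bank of negative-control probes defining detection and
background, institute-specific array-intensity shifts (removed downstream
by internal-control normalization), occasional signal dropout below the
detection limit, and scanner-flagged probe counts.

Default parameters describe the emulated study conditions: 300 cancer and
300 non-cancer samples, 200 target miRNAs of which 10 are informative with
a 2-sigma log2 effect, stage multipliers (0.5, 0.75, 1.0) with stage
proportions (0.25, 0.10, 0.65), and non-cancer samples drawn from three
institutes in proportions (0.08, 0.57, 0.35).

All randomness flows from a single seed through named
:class:`numpy.random.SeedSequence` streams, so each sub-generator (signals,
exosome table, PCR tables) is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_io import LINEAR, ProbeSignalMatrix, validate_sample_meta
from .preprocess import DEFAULT_INTERNAL_CONTROLS

# named sub-streams of the master seed
_STREAMS = {"cohort": 0, "exosome": 1, "pcr": 2}


def _rng(seed, stream):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_cancer: int = 300
    n_noncancer: int = 300
    n_other_cancer: int = 0
    n_borderline: int = 0
    n_benign: int = 0
    n_target_mirnas: int = 200
    n_informative: int = 10
    #: log2 shift of informative miRNAs in cancer at stage III-IV
    effect_size: float = 2.0
    stage_multipliers: tuple = (0.5, 0.75, 1.0)
    stage_proportions: tuple = (0.25, 0.10, 0.65)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_negative_controls: int = 30
    neg_control_mean: float = 20.0   # linear scale
    neg_control_sd: float = 2.0
    internal_control_log2: tuple = (8.0, 7.5, 8.5)
    institute_shift: dict = field(
        default_factory=lambda: {"A": 0.0, "B": 0.3, "C": -0.3}
    )
    institute_proportions: tuple = (0.08, 0.57, 0.35)
    #: log2 effect fraction applied to the non-carcinoma tumor classes
    borderline_effect: float = 0.5
    benign_effect: float = 0.25
    other_cancer_effect: float = 0.0
    flagged_rate: float = 0.002
    dropout_rate: float = 0.005

    def __post_init__(self):
        for name in ("n_cancer", "n_noncancer", "n_other_cancer",
                     "n_borderline", "n_benign", "n_target_mirnas",
                     "n_informative", "n_negative_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_informative > self.n_target_mirnas:
            raise ValueError("n_informative exceeds n_target_mirnas")
        if list(self.stage_multipliers) != sorted(self.stage_multipliers):
            raise ValueError("stage multipliers must be nondecreasing")
        for name in ("flagged_rate", "dropout_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generating ground truth: which miRNAs carry signal, and how much."""

    informative_effects: dict          # miRNA id -> log2 shift at full stage
    stages: dict                       # sample id -> stage (cancer only)
    config: SyntheticConfig

    @property
    def informative_ids(self):
        return list(self.informative_effects)


def target_ids(cfg):
    width = len(str(cfg.n_target_mirnas))
    return [f"miR-sim-{i:0{width}d}" for i in range(1, cfg.n_target_mirnas + 1)]


def generate_cohort(cfg=None):
    """Generate (linear raw matrix, sample metadata, truth) from a config."""
    if cfg is None:
        cfg = SyntheticConfig()
    rng = _rng(cfg.seed, "cohort")

    targets = target_ids(cfg)
    informative = targets[: cfg.n_informative]
    neg_ids = [f"NC-{i:03d}" for i in range(1, cfg.n_negative_controls + 1)]
    ic_ids = list(DEFAULT_INTERNAL_CONTROLS)

    classes = (
        ["ovarian_cancer"] * cfg.n_cancer
        + ["non_cancer"] * cfg.n_noncancer
        + ["other_cancer"] * cfg.n_other_cancer
        + ["borderline"] * cfg.n_borderline
        + ["benign"] * cfg.n_benign
    )
    n = len(classes)
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    classes = np.array(classes)

    stage_names = np.array(["I", "II", "III_IV"])
    stages = np.full(n, "NA", dtype=object)
    is_cancer = classes == "ovarian_cancer"
    stages[is_cancer] = rng.choice(
        stage_names, size=int(is_cancer.sum()), p=cfg.stage_proportions
    )

    institutes = np.full(n, "A", dtype=object)
    non = classes == "non_cancer"
    institutes[non] = rng.choice(
        ["A", "B", "C"], size=int(non.sum()), p=cfg.institute_proportions
    )

    # per-sample multiplier on the informative-miRNA effect
    mult = np.zeros(n)
    smap = dict(zip(stage_names, cfg.stage_multipliers))
    mult[is_cancer] = [smap[s] for s in stages[is_cancer]]
    mult[classes == "borderline"] = cfg.borderline_effect
    mult[classes == "benign"] = cfg.benign_effect
    mult[classes == "other_cancer"] = cfg.other_cancer_effect

    inst_shift = np.array([cfg.institute_shift[i] for i in institutes])

    # target signals on the log2 scale
    log2 = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=(n, len(targets)))
    eff = np.zeros(len(targets))
    eff[: cfg.n_informative] = cfg.effect_size
    log2 += mult[:, None] * eff[None, :]
    log2 += inst_shift[:, None]

    # internal controls: stable per-probe levels + institute shift + noise
    ic = (
        np.asarray(cfg.internal_control_log2)[None, :]
        + inst_shift[:, None]
        + rng.normal(0.0, 0.1, size=(n, len(ic_ids)))
    )

    # to linear scale, with additive scanner background
    bg = np.clip(
        rng.normal(cfg.neg_control_mean, cfg.neg_control_sd,
                   size=(n, len(targets) + len(ic_ids))),
        0.0, None,
    )
    linear = np.column_stack([2.0 ** log2, 2.0 ** ic]) + bg

    # dropout: signal collapses to background level (below detection)
    drop = rng.random(size=linear.shape) < cfg.dropout_rate
    drop_bg = np.clip(
        rng.normal(cfg.neg_control_mean, cfg.neg_control_sd, size=linear.shape),
        0.0, None,
    )
    linear[drop] = drop_bg[drop]

    neg = np.clip(
        rng.normal(cfg.neg_control_mean, cfg.neg_control_sd,
                   size=(n, len(neg_ids))),
        0.0, None,
    )

    all_ids = targets + ic_ids + neg_ids
    values = pd.DataFrame(
        np.column_stack([linear, neg]), index=sample_ids, columns=all_ids
    )
    probe_class = pd.Series(
        ["target"] * len(targets)
        + ["internal_control"] * len(ic_ids)
        + ["negative_control"] * len(neg_ids),
        index=all_ids,
    )
    matrix = ProbeSignalMatrix(values, probe_class, LINEAR)

    n_probes = len(all_ids)
    flagged = rng.binomial(n_probes, cfg.flagged_rate, size=n)
    age_means = {
        "ovarian_cancer": (56.8, 11.5),
        "non_cancer": (45.5, 10.8),
        "other_cancer": (60.0, 11.0),
        "borderline": (53.0, 15.5),
        "benign": (57.2, 10.3),
        "non_epithelial": (45.0, 15.0),
    }
    ages = np.array(
        [rng.normal(*age_means[c]) for c in classes]
    ).clip(20.0, 90.0).round(1)

    meta = validate_sample_meta(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "class_label": classes,
                "stage": stages,
                "age": ages,
                "institute": institutes,
                "flagged_probe_count": flagged,
                "cancer_type": pd.NA,
            }
        )
    )
    truth = SyntheticTruth(
        informative_effects={m: cfg.effect_size for m in informative},
        stages={s: st for s, st in zip(sample_ids, stages) if st != "NA"},
        config=cfg,
    )
    return matrix, meta, truth


def generate_exosome_table(cfg, overlap_fraction=1.0, background_fraction=0.4,
                           n_cell_lines=12):
    """Cell-line exosome presence counts per target miRNA.

    ``overlap_fraction`` of the informative miRNAs and
    ``background_fraction`` of the remaining targets are marked present in
    1..``n_cell_lines`` lines; absent miRNAs get count 0.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = _rng(cfg.seed, "exosome")
    targets = target_ids(cfg)
    informative = set(targets[: cfg.n_informative])
    counts = {}
    for mid in targets:
        p = overlap_fraction if mid in informative else background_fraction
        if rng.random() < p:
            counts[mid] = int(rng.integers(1, n_cell_lines + 1))
        else:
            counts[mid] = 0
    return pd.Series(counts, name="n_lines_detected")


def generate_pcr_tables(truth, noise_sd=0.05, mirna_ids=None, n_dilutions=6,
                        n_paired=10):
    """Fabricate qRT-PCR gate inputs for the given miRNAs.

    Dilution series: measured level linear in log2 input amount with
    Gaussian noise. Concordance pairs: Ct values anti-correlated with the
    array log2 signal (Ct = 30 - log2 signal + noise). Returns
    miRNA id -> dict with ``dilution`` and ``paired`` lists of pairs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    cfg = truth.config
    rng = _rng(cfg.seed, "pcr")
    if mirna_ids is None:
        mirna_ids = truth.informative_ids
    tables = {}
    for mid in mirna_ids:
        log_input = np.arange(n_dilutions, dtype=float)
        measured = log_input + rng.normal(0.0, noise_sd, size=n_dilutions)
        dilution = list(zip(log_input, measured))
        array_log2 = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_paired)
        ct = 30.0 - array_log2 + rng.normal(0.0, noise_sd, size=n_paired)
        paired = list(zip(array_log2, ct))
        tables[mid] = {"dilution": dilution, "paired": paired}
    return tables


def config_to_dict(cfg):
    return asdict(cfg)
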