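"""End-to-end orchestration: simulate -> QC -> preprocess -> filter ->
pivots -> search -> score -> evaluate.

The discovery/validation split is stratified: ovarian-cancer samples are
split in half within each FIGO stage, non-cancer samples in half within
each institute, and every other class (other cancers, borderline, benign,
non-epithelial) is routed entirely to the validation set, mirroring the
reference workflow in which the model is built on carcinoma vs. non-cancer
only and challenged on the remaining groups.

Every artifact is written with a provenance header (package version, seed,
config hash) and no stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .array_io import (
    qc_filter,
    read_sample_meta,
    read_signal_matrix,
    write_sample_meta,
    write_signal_matrix,
)
from .candidate_filter import (
    exosome_presence_filter,
    read_exosome_table,
    serum_prevalence_filter,
    write_exosome_table,
)
from .discriminant import SearchConfig, subset_search
from .evaluate import (
    logistic_odds_ratio,
    performance_at_zero,
    roc,
    subgroup_accuracy,
)
from .pivot_selection import pcr_gates, rank_candidates, select_pivots
from .preprocess import NormalizationConfig, preprocess
from .synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    generate_exosome_table,
    generate_pcr_tables,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    # input files; when None the synthetic generator provides the cohort
    signals_path: str | None = None
    annotation_path: str | None = None
    meta_path: str | None = None
    exosome_path: str | None = None
    synthetic: SyntheticConfig | None = None
    norm: NormalizationConfig = field(default_factory=NormalizationConfig)
    cv_max: float = 0.15
    flag_max: int = 10
    min_lines: int = 1
    exosome_overlap: float = 1.0
    exosome_background: float = 0.4
    log2_threshold: float = 6.0
    min_fraction: float = 0.5
    n_pivots: int = 10
    #: append this many further AUC-ranked candidates to the search pool
    extra_candidates: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)
    apply_pcr_gates: bool = True
    pcr_noise_sd: float = 0.05
    split_fraction: float = 0.5

    def __post_init__(self):
        if self.synthetic is None and self.signals_path is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    def config_hash(self):
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        rec = asdict(self)
        rec.pop("out_dir", None)  # identical analyses hash alike
        text = json.dumps(rec, sort_keys=True, default=default)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: object
    normalized: object
    meta: pd.DataFrame
    discovery_ids: list
    validation_ids: list
    candidates: object
    pivots: list
    validated_pivots: list
    model: object
    leaderboard: pd.DataFrame
    scores: pd.DataFrame
    evaluation: dict
    truth: object = None


def split_discovery_validation(meta, fraction=0.5, seed=0):
    """Stratified discovery/validation split.

    Ovarian-cancer samples split by stage, non-cancer by institute; all
    other classes go to validation. Returns (discovery_ids, validation_ids).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(3,))
    )
    discovery, validation = [], []
    for (cls, stratum), grp in meta.groupby(
        ["class_label", meta["stage"].where(meta["class_label"] == "ovarian_cancer",
                                            meta["institute"])],
        sort=True,
    ):
        ids = sorted(grp["sample_id"])
        if cls not in ("ovarian_cancer", "non_cancer"):
            validation.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_disc = int(round(fraction * len(ids)))
        chosen = {ids[i] for i in perm[:n_disc]}
        discovery.extend(s for s in ids if s in chosen)
        validation.extend(s for s in ids if s not in chosen)
    return sorted(discovery), sorted(validation)


def _provenance(cfg):
    return {
        "package": f"mirscreen {__version__}",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }


def _write_tsv(df, path, cfg):
    with open(path, "w") as fh:
        for k, v in _provenance(cfg).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg=None):
    """Execute the full pipeline; returns a :class:`PipelineResult`.

    With ``cfg.out_dir`` set, artifacts (signals, QC report, candidate set,
    pivot report, model JSON, search leaderboard, per-sample scores and the
    evaluation summary) are written there.
    """
    if cfg is None:
        cfg = PipelineConfig()
    out = None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage: data -------------------------------------------------------
    truth = None
    if cfg.signals_path is not None:
        for name, p in (("signals", cfg.signals_path),
                        ("annotation", cfg.annotation_path),
                        ("metadata", cfg.meta_path)):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        matrix = read_signal_matrix(cfg.signals_path, cfg.annotation_path)
        meta = read_sample_meta(cfg.meta_path)
        if cfg.exosome_path is not None:
            exosome = read_exosome_table(cfg.exosome_path)
        else:
            exosome = None
    else:
        matrix, meta, truth = generate_cohort(cfg.synthetic)
        exosome = generate_exosome_table(
            cfg.synthetic,
            overlap_fraction=cfg.exosome_overlap,
            background_fraction=cfg.exosome_background,
        )
        if out is not None:
            write_signal_matrix(matrix, out / "signals.tsv", out / "annotation.tsv")
            write_sample_meta(meta, out / "metadata.tsv")
            write_exosome_table(exosome, out / "exosome_presence.tsv")

    # ---- stage: qc ---------------------------------------------------------
    matrix, qc_report = qc_filter(matrix, meta, cv_max=cfg.cv_max,
                                  flag_max=cfg.flag_max)
    meta = meta[meta["sample_id"].isin(matrix.sample_ids)].reset_index(drop=True)
    if out is not None:
        _write_tsv(qc_report.table, out / "qc_report.tsv", cfg)

    # ---- stage: preprocess -------------------------------------------------
    normalized = preprocess(matrix, cfg.norm)

    # ---- stage: split ------------------------------------------------------
    discovery_ids, validation_ids = split_discovery_validation(
        meta, fraction=cfg.split_fraction, seed=cfg.seed
    )
    meta_idx = meta.set_index("sample_id")
    disc = normalized.select_samples(discovery_ids)
    disc_labels = (meta_idx.loc[discovery_ids, "class_label"]
                   == "ovarian_cancer").to_numpy().astype(int)

    # ---- stage: candidate filter ------------------------------------------
    target_probes = normalized.probes_of_class("target")
    if exosome is not None:
        exo_pass = [p for p in exosome_presence_filter(exosome, cfg.min_lines)
                    if p in set(target_probes)]
    else:
        exo_pass = list(target_probes)
    cancer_disc = [s for s in discovery_ids
                   if meta_idx.loc[s, "class_label"] == "ovarian_cancer"]
    candidates = serum_prevalence_filter(
        normalized.select_samples(cancer_disc),
        exo_pass,
        log2_threshold=cfg.log2_threshold,
        min_fraction=cfg.min_fraction,
    )
    if out is not None:
        candidates.write(out / "candidates.tsv")

    # ---- stage: pivots -----------------------------------------------------
    aucs = rank_candidates(disc, disc_labels, candidates.ids)
    pivots = select_pivots(aucs, n_pivots=cfg.n_pivots)
    validated = list(pivots)
    gate_rows = []
    if cfg.apply_pcr_gates and truth is not None:
        tables = generate_pcr_tables(truth, noise_sd=cfg.pcr_noise_sd,
                                     mirna_ids=pivots)
        validated = []
        for mid in pivots:
            g = pcr_gates(tables[mid]["dilution"], tables[mid]["paired"],
                          mirna_id=mid)
            gate_rows.append(
                {"mirna_id": mid, "dilution_r": g.dilution_linearity_r,
                 "concordance_r": g.concordance_r, "validated": g.validated}
            )
            if g.validated:
                validated.append(mid)
        if not validated:
            raise RuntimeError("no pivot miRNA survived the qRT-PCR gates")
    if out is not None:
        auc_map = {m.mirna_id: m for m in aucs}
        piv = pd.DataFrame(
            {
                "mirna_id": pivots,
                "auc": [auc_map[p].auc for p in pivots],
                "direction": [auc_map[p].direction for p in pivots],
                "validated": [p in set(validated) for p in pivots],
            }
        )
        _write_tsv(piv, out / "pivots.tsv", cfg)
        if gate_rows:
            _write_tsv(pd.DataFrame(gate_rows), out / "pcr_gates.tsv", cfg)

    # ---- stage: search -----------------------------------------------------
    if cfg.extra_candidates > 0:
        ranked = sorted(aucs, key=lambda m: (-m.oriented_auc, m.mirna_id))
        extras = [m.mirna_id for m in ranked
                  if m.mirna_id not in set(validated)][: cfg.extra_candidates]
        validated = validated + extras
    model, leaderboard = subset_search(
        disc.values[validated], disc_labels, validated, cfg=cfg.search,
        return_leaderboard=True,
    )
    model.metadata.update(_provenance(cfg))
    if out is not None:
        model.to_json(out / "model.json")
        _write_tsv(leaderboard, out / "leaderboard.tsv", cfg)

    # ---- stage: score ------------------------------------------------------
    val = normalized.select_samples(validation_ids)
    idx = model.index(val.values)
    scores = pd.DataFrame(
        {
            "sample_id": validation_ids,
            "model": "selected_panel",
            "index": idx,
            "call": np.where(idx >= 0, "positive", "negative"),
        }
    )
    if out is not None:
        _write_tsv(scores, out / "scores.tsv", cfg)

    # ---- stage: evaluate ---------------------------------------------------
    val_meta = meta_idx.loc[validation_ids]
    core = val_meta["class_label"].isin(["ovarian_cancer", "non_cancer"])
    core_ids = val_meta.index[core]
    y = (val_meta.loc[core_ids, "class_label"] == "ovarian_cancer").to_numpy().astype(int)
    core_idx = scores.set_index("sample_id").loc[core_ids, "index"].to_numpy()
    r = roc(core_idx, y)
    perf = performance_at_zero(core_idx, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            orfit = logistic_odds_ratio(
                core_idx, y, age=val_meta.loc[core_ids, "age"].to_numpy()
            )
            or_summary = {
                "univariable_or": orfit.univariable.odds_ratio,
                "univariable_ci": orfit.univariable.ci,
                "age_adjusted_or": orfit.age_adjusted.odds_ratio,
                "age_adjusted_ci": orfit.age_adjusted.ci,
            }
        except ValueError as exc:
            or_summary = {"error": str(exc)}
    stage_table = subgroup_accuracy(scores, meta, by="stage")
    evaluation = {
        "validation_auc": r.auc,
        "validation_sensitivity": perf.sensitivity,
        "validation_specificity": perf.specificity,
        "validation_accuracy": perf.accuracy,
        "panel": list(model.panel),
        "loocv_metric": model.loocv_metric,
        "odds_ratio": or_summary,
        "stage_table": stage_table.to_dict(orient="records"),
        "n_discovery": len(discovery_ids),
        "n_validation": len(validation_ids),
        "provenance": _provenance(cfg),
    }
    if truth is not None:
        evaluation["informative_recovered"] = len(
            set(model.panel) & set(truth.informative_ids)
        )
    if out is not None:
        with open(out / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        config=cfg,
        qc_report=qc_report,
        normalized=normalized,
        meta=meta,
        discovery_ids=discovery_ids,
        validation_ids=validation_ids,
        candidates=candidates,
        pivots=pivots,
        validated_pivots=validated,
        model=model,
        leaderboard=leaderboard,
        scores=scores,
        evaluation=evaluation,
        truth=truth,
    )
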