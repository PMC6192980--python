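"""Candidate miRNA selection: exosome presence and serum prevalence filters.

Biomarker candidates must (a) be detectable in extracellular vesicles
released by ovarian cancer cell lines — consumed here as a precomputed
presence table (miRNA -> number of cell lines, out of 12, in which it was
detected) — and (b) be robustly measurable in serum: a strict majority of
the cancer-cohort samples must show a log2 signal strictly above 6
(i.e. raw signal > 2^6). Both inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .array_io import LOG2


@dataclass
class CandidateSet:
    """Ordered surviving miRNA ids with per-filter audit counts."""

    ids: list
    n_exosome_pass: int
    n_serum_excluded: int

    @property
    def n_final(self):
        return len(self.ids)

    def __post_init__(self):
        if self.n_final != self.n_exosome_pass - self.n_serum_excluded:
            raise ValueError("audit counts do not reconcile")

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(f"# n_exosome_pass={self.n_exosome_pass}\n")
            fh.write(f"# n_serum_excluded={self.n_serum_excluded}\n")
            fh.write(f"# n_final={self.n_final}\n")
            fh.write("mirna_id\n")
            for mid in self.ids:
                fh.write(f"{mid}\n")


def read_exosome_table(path):
    tab = pd.read_csv(path, sep="\t", dtype={"mirna_id": str})
    if not {"mirna_id", "n_lines_detected"}.issubset(tab.columns):
        raise ValueError("exosome table needs columns mirna_id, n_lines_detected")
    return tab.set_index("mirna_id")["n_lines_detected"].astype(int)


def write_exosome_table(table, path):
    pd.DataFrame(
        {"mirna_id": table.index, "n_lines_detected": table.values}
    ).to_csv(path, sep="\t", index=False)


def exosome_presence_filter(table, min_lines=1):
    """miRNA ids detected in at least ``min_lines`` cell lines (table order)."""
    table = pd.Series(table)
    if (table < 0).any():
        raise ValueError("negative cell-line counts")
    return [mid for mid, n in table.items() if n >= min_lines]


def serum_prevalence_filter(
    matrix, candidates, log2_threshold=6.0, min_fraction=0.5
):
    """Keep candidates whose log2 signal exceeds the threshold in a strict
    majority of the cohort samples.

    ``matrix`` must already be restricted to the intended cohort (the
    ovarian-cancer serum samples in the reference workflow) and on the log2
    scale. A candidate is kept iff
    ``fraction(samples with value > log2_threshold) > min_fraction``.
    """
    matrix.require_scale(LOG2)
    if matrix.n_samples == 0:
        raise ValueError("empty cohort for the prevalence filter")
    candidates = list(candidates)
    missing = [c for c in candidates if c not in matrix.values.columns]
    if missing:
        raise KeyError(f"candidates absent from matrix: {missing[:5]}")
    # preserve matrix probe order
    ordered = [p for p in matrix.probe_ids if p in set(candidates)]
    frac = (matrix.values[ordered] > log2_threshold).mean(axis=0)
    kept = [p for p in ordered if frac[p] > min_fraction]
    return CandidateSet(
        ids=kept,
        n_exosome_pass=len(ordered),
        n_serum_excluded=len(ordered) - len(kept),
    )
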