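"""The three fixed diagnostic indices shipped as scoring functions.

Model 1 screens ovarian cancer against non-cancer controls, model 2 against
other solid cancers plus non-cancer, and model 3 against borderline/benign
ovarian tumors plus non-cancer. Each is a frozen linear index over 9-10
normalized log2 serum miRNA signals; an index >= 0 calls ovarian cancer.

The coefficient table lives in a versioned TSV inside the package and is
checksum-verified at load time to guard against transcription errors.

Caveat: the original scale convention of these coefficients is not fully
documented; this package applies them to its own normalized log2 signals,
which reproduces the formulas exactly but not necessarily the original
cohort performance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .array_io import LOG2

INTERCEPT_TERM = "(intercept)"
MODEL_REGISTRY_SHA256 = (
    "5eb6869c5a918e316ac539f24a1fb52e4bacb448217684d4e17be62b379ca135"
)


@dataclass(frozen=True)
class PublishedModel:
    name: str
    panel: tuple
    coefficients: tuple
    intercept: float


@dataclass(frozen=True)
class DiagnosticResult:
    sample_id: str
    model: str
    index: float

    @property
    def call(self):
        return "positive" if self.index >= 0 else "negative"


def _registry_bytes():
    return (
        resources.files("mirscreen").joinpath("data/published_models.tsv").read_bytes()
    )


def load_published_models(verify=True):
    """Load the model registry; checksum-verified unless ``verify=False``."""
    raw = _registry_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != MODEL_REGISTRY_SHA256:
            raise ValueError(
                "published-model registry failed checksum verification: "
                f"{digest} != {MODEL_REGISTRY_SHA256}"
            )
    import io

    tab = pd.read_csv(io.BytesIO(raw), sep="\t")
    models = {}
    for name, grp in tab.groupby("model", sort=False):
        terms = grp[grp["term"] != INTERCEPT_TERM]
        intercept = grp.loc[grp["term"] == INTERCEPT_TERM, "value"]
        if len(intercept) != 1:
            raise ValueError(f"model {name}: expected exactly one intercept row")
        models[name] = PublishedModel(
            name=name,
            panel=tuple(terms["term"]),
            coefficients=tuple(float(v) for v in terms["value"]),
            intercept=float(intercept.iloc[0]),
        )
    return models


def get_model(name):
    models = load_published_models()
    if name not in models:
        raise KeyError(f"unknown model {name!r}; available: {sorted(models)}")
    return models[name]


def score(model, expr, sample_id=""):
    """Score one sample: ``index = sum(coef * expr[miRNA]) + intercept``.

    ``expr`` maps miRNA id -> normalized log2 signal and must contain every
    panel member.
    """
    missing = [m for m in model.panel if m not in expr]
    if missing:
        raise KeyError(f"missing panel miRNAs for {model.name}: {missing}")
    x = np.array([float(expr[m]) for m in model.panel])
    idx = float(x @ np.asarray(model.coefficients) + model.intercept)
    return DiagnosticResult(sample_id=sample_id, model=model.name, index=idx)


def score_cohort(model, matrix):
    """Score every sample of a normalized log2 matrix; order preserved."""
    matrix.require_scale(LOG2)
    missing = [m for m in model.panel if m not in matrix.values.columns]
    if missing:
        raise KeyError(f"missing panel miRNAs for {model.name}: {missing}")
    X = matrix.values[list(model.panel)].to_numpy(dtype=float)
    idx = X @ np.asarray(model.coefficients) + model.intercept
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "model": model.name,
            "index": idx,
            "call": np.where(idx >= 0, "positive", "negative"),
        }
    )
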