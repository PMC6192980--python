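import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirscreen import ProbeSignalMatrix
from mirscreen.preprocess import DEFAULT_INTERNAL_CONTROLS


def make_matrix(values, probe_class, scale="linear", sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(1, n + 1)]
    probe_ids = list(probe_class)
    return ProbeSignalMatrix(
        pd.DataFrame(values, index=sample_ids, columns=probe_ids),
        probe_class,
        scale,
    )


@pytest.fixture
def small_linear_matrix():
    """2 samples, 3 targets + 3 internal controls + 20 negative controls."""
    rng = np.random.default_rng(7)
    targets = ["miR-a", "miR-b", "miR-c"]
    ics = list(DEFAULT_INTERNAL_CONTROLS)
    negs = [f"NC-{i:02d}" for i in range(20)]
    probe_class = {t: "target" for t in targets}
    probe_class.update({c: "internal_control" for c in ics})
    probe_class.update({c: "negative_control" for c in negs})
    vals = np.column_stack(
        [
            rng.uniform(100, 1000, size=(2, len(targets) + len(ics))),
            rng.uniform(8, 12, size=(2, len(negs))),
        ]
    )
    return make_matrix(vals, probe_class)


@pytest.fixture
def meta_for(small_linear_matrix):
    def _meta(matrix, flags=0):
        n = matrix.n_samples
        return pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "class_label": ["non_cancer"] * n,
                "stage": ["NA"] * n,
                "age": [50.0] * n,
                "institute": ["A"] * n,
                "flagged_probe_count": [flags] * n,
                "cancer_type": [pd.NA] * n,
            }
        )

    return _meta
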