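import math

import numpy as np
import pytest
from hypothesis import settings

from bmdrisk import (
    CovariateStructure,
    DoseResponseDataset,
    DoseResponseRecord,
    ModelParams,
    fit_single_structure,
    garriott_like,
    predict_response,
)

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


def make_individual(rows, **kwargs):
    """rows: iterable of (level, dose, response) triples."""
    return DoseResponseDataset(
        records=[
            DoseResponseRecord("toy", lvl, dose, resp, subject_id=str(i))
            for i, (lvl, dose, resp) in enumerate(rows)
        ],
        **kwargs,
    )


def on_curve_dataset(params: ModelParams, doses, n_per_group=3, rel_jitter=0.0, seed=0):
    """Noise-free (or near) observations lying on the model curve."""
    rng = np.random.default_rng(seed)
    rows = []
    for level in params.levels:
        for dose in doses:
            m = predict_response(params, level, dose)
            for _ in range(n_per_group):
                f = math.exp(rng.normal(0, rel_jitter)) if rel_jitter else 1.0
                rows.append((level, dose, m * f))
    return make_individual(rows)


@pytest.fixture(scope="session")
def exp_params():
    return ModelParams(
        family="exponential",
        a={"m": 0.5}, b={"m": 0.3}, c=5.0, d=1.0, var={"m": 0.04},
    )


@pytest.fixture(scope="session")
def garriott_data():
    return garriott_like(seed=1)


@pytest.fixture(scope="session")
def garriott_fit(garriott_data):
    structure = CovariateStructure(frozenset({"a", "b"}))
    return structure, fit_single_structure(garriott_data, "exponential", structure)
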