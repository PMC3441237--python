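import numpy as np
import pandas as pd
import pytest

from targetindex import ClinicalTable, ExpressionMatrix


def make_matrix(values, probes=None, samples=None, cohort_id="c1", standardized=False):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        cohort_id=cohort_id,
        values=pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples),
        standardized=standardized,
    )


def make_clinical(responses, samples=None, **covariates):
    samples = samples or [f"s{j}" for j in range(len(responses))]
    df = pd.DataFrame(
        {"response": [r if r in ("pCR", "RD") else np.nan for r in responses]},
        index=pd.Index(samples, name="sample_id"),
    )
    for k, v in covariates.items():
        df[k] = v
    return ClinicalTable(df)


def random_standardized_matrix(rng, n_probes, n_samples, cohort_id="c1"):
    """Exactly z-scored rows (ddof=1), as score_index expects."""
    x = rng.normal(size=(n_probes, n_samples))
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    return make_matrix(x, cohort_id=cohort_id, standardized=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
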