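import numpy as np
import pandas as pd
import pytest

from duomics.data_model import (
    AsvAbundanceTable,
    Experiment,
    ProteinIntensityTable,
)

SUBSTRATES = ("dentine", "enamel", "titanium")


def protein_design(n_per=3, substrates=SUBSTRATES):
    return [Experiment(f"p_{s}_{i + 1}", s, None, i + 1)
            for s in substrates for i in range(n_per)]


def asv_design(timepoint="2h", n_per=3, substrates=SUBSTRATES):
    return [Experiment(f"m_{timepoint}_{s}_{i + 1}", s, timepoint, i + 1)
            for s in substrates for i in range(n_per)]


def make_protein_table(values, design=None, ids=None):
    values = np.asarray(values, dtype=float)
    if design is None:
        assert values.shape[1] % 3 == 0
        design = protein_design(values.shape[1] // 3)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"),
                        columns=[e.experiment_id for e in design])
    return ProteinIntensityTable(data, design)


def make_asv_table(values, design=None, ids=None, timepoint="2h", taxonomy=None):
    values = np.asarray(values, dtype=float)
    if design is None:
        assert values.shape[1] % 3 == 0
        design = asv_design(timepoint, values.shape[1] // 3)
    if ids is None:
        ids = [f"A{i:03d}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"),
                        columns=[e.experiment_id for e in design])
    return AsvAbundanceTable(data, design, taxonomy=taxonomy)


def random_censored_protein_table(rng, n_proteins=12, n_per=3, censor_frac=0.2,
                                  log_sd=0.4):
    """Left-censored right-skewed (lognormal) table, the structure the
    imputation stage assumes; small magnitudes keep grid oracles cheap.

    Heavy censoring (censor_frac ~0.45) with mild skew (log_sd ~0.25)
    produces fixtures where mean-median changes sign on the search
    interval, exercising the bisection path."""
    vals = 10.0 ** rng.normal(0.0, log_sd, size=(n_proteins, 3 * n_per))
    cut = np.quantile(vals, censor_frac)
    vals = np.where(vals < cut, np.nan, vals)
    # guarantee every protein keeps one value and at least one is missing
    for i in range(n_proteins):
        if np.all(np.isnan(vals[i])):
            vals[i, 0] = cut * (1 + rng.uniform(0.1, 1.0))
    if not np.any(np.isnan(vals)):
        vals[0, 0] = np.nan
    return make_protein_table(vals, design=protein_design(n_per))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
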