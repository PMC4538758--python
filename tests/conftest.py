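import numpy as np
import pandas as pd
import pytest

from sscskin.formats import ClsLabels
from sscskin.preprocess import preprocess_pipeline
from sscskin.simulate import SimulationConfig, simulate_expression, simulate_gene_sets


@pytest.fixture(scope="session")
def sim_dataset():
    """One standard simulated study, preprocessed, shared across tests."""
    cfg = SimulationConfig(seed=11)
    pm, truth = simulate_expression(cfg)
    em = preprocess_pipeline(pm, sample_meta=truth.samples)
    return cfg, pm, truth, em


@pytest.fixture(scope="session")
def baseline_labels(sim_dataset):
    """Improver/non-improver CLS for the baseline samples, from truth."""
    _, _, truth, _ = sim_dataset
    patients = list(truth.patients.index)
    labels = [0 if truth.patients.loc[p, "improver"] else 1 for p in patients]
    samples = [f"{p}_BL" for p in patients]
    return samples, ClsLabels(["improver", "nonimprover"], labels)


@pytest.fixture(scope="session")
def gene_sets(sim_dataset):
    cfg, _, truth, _ = sim_dataset
    return simulate_gene_sets(cfg, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)
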