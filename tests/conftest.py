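import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methgate.expression import ExpressionMatrix, merge_probes_to_genes, quantile_normalize
from methgate.synthetic import SimConfig, simulate_timecourse_expression

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values: np.ndarray, design: pd.DataFrame | None = None,
                level: str = "gene") -> ExpressionMatrix:
    """Wrap a bare array in an ExpressionMatrix with a minimal design."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cols = [f"s{j}" for j in range(m)]
    if design is None:
        design = pd.DataFrame(
            {
                "context": "mesoderm",
                "genotype": "WT",
                "treatment": "Dex-",
                "time_h": 0,
                "replicate": range(1, m + 1),
            },
            index=cols,
        )
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n)], columns=cols)
    return ExpressionMatrix(values=frame, design=design, level=level)


def two_group_matrix(a: np.ndarray, b: np.ndarray) -> ExpressionMatrix:
    """Gene-level matrix with two treatment groups (Dex- = a, Dex+ = b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    values = np.hstack([a, b])
    cols = [f"a{j}" for j in range(a.shape[1])] + [f"b{j}" for j in range(b.shape[1])]
    design = pd.DataFrame(
        {
            "context": "mesoderm",
            "genotype": "WT",
            "treatment": ["Dex-"] * a.shape[1] + ["Dex+"] * b.shape[1],
            "time_h": 72,
            "replicate": list(range(1, a.shape[1] + 1)) + list(range(1, b.shape[1] + 1)),
        },
        index=cols,
    )
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                         columns=cols)
    return ExpressionMatrix(values=frame, design=design, level="gene")


GROUP_A = dict(treatment="Dex-")
GROUP_B = dict(treatment="Dex+")


@pytest.fixture(scope="session")
def default_sim():
    """One default-design simulation shared across tests (seed 7)."""
    config = SimConfig(seed=7)
    matrix, probe_map, truth = simulate_timecourse_expression(config)
    return config, matrix, probe_map, truth


@pytest.fixture(scope="session")
def default_gene_matrix(default_sim):
    _, matrix, probe_map, truth = default_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gene = merge_probes_to_genes(quantile_normalize(matrix), probe_map)
    return gene, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    config = SimConfig(seed=5, noise_sd=0.0, sample_offset_sd=0.0)
    matrix, probe_map, truth = simulate_timecourse_expression(config)
    return config, matrix, probe_map, truth
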