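import numpy as np
import pandas as pd
import pytest

from metabomwas import SynthConfig, generate_cohort
from metabomwas.containers import AbundanceMatrix
from metabomwas.preprocess import log2_transform, pqn_normalize


SMALL = dict(
    n_per_group={"NHAA": 80, "HA": 60, "NHW": 60},
    n_metabolites=120,
    n_interaction_metabolites=6,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-sample, 120-metabolite cohort with site artifacts and holes."""
    cfg = SynthConfig(**SMALL, seed=42)
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Same design without missingness/outliers: complete positive matrix."""
    cfg = SynthConfig(**SMALL, missing_frac=0.0, outlier_rate=0.0, seed=43)
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_log2(clean_cohort):
    """Analysis-scale (PQN + log2) complete matrix with its metadata/truth."""
    _, matrix, metadata, annotation, truth = clean_cohort
    normalized, _ = pqn_normalize(matrix)
    return log2_transform(normalized), metadata, annotation, truth


def make_matrix(values, scale_tag="log2", prefix_s="s", prefix_m="m") -> AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix_s}{i}" for i in range(values.shape[0])],
        columns=[f"{prefix_m}{j}" for j in range(values.shape[1])],
    )
    return AbundanceMatrix(df, scale_tag=scale_tag)
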