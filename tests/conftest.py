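import numpy as np
import pandas as pd
import pytest

from oncostage.simulate import (
    SimConfig,
    generate_expression_dataset,
    generate_survival_outcomes,
)


@pytest.fixture(scope="session")
def mixed_config() -> SimConfig:
    """Moderate dataset with every planted class represented."""
    return SimConfig(
        n_per_group=30,
        n_null=120,
        n_global_de=8,
        n_stage_salient=8,
        n_monotone_up=6,
        n_monotone_down=4,
        n_prognostic=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def mixed_dataset(mixed_config):
    return generate_expression_dataset(mixed_config)


@pytest.fixture(scope="session")
def mixed_survival(mixed_config, mixed_dataset):
    expr, truth = mixed_dataset
    return generate_survival_outcomes(expr, truth, mixed_config)


@pytest.fixture(scope="session")
def limma_oracle(tmp_path_factory):
    """Frozen outputs of the Bioconductor limma voom/eBayes reference run."""
    import pathlib

    base = pathlib.Path(__file__).parent / "data"
    counts = pd.read_csv(base / "limma_oracle_counts.tsv", sep="\t", index_col=0)
    stages = pd.read_csv(base / "limma_oracle_stages.tsv", sep="\t", index_col=0)["stage"]
    expected = pd.read_csv(base / "limma_oracle_expected.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(base / "limma_oracle_meta.tsv", sep="\t").iloc[0]
    return counts, stages, expected, meta


def make_groups(n_per_group: int) -> list[str]:
    from oncostage.datatypes import GROUPS

    return [g for g in GROUPS for _ in range(n_per_group)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
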