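import numpy as np
import pandas as pd
import pytest

from generank import ExomeConfig, simulate_exome, simulate_phenotypes
from generank.datasets import build_all_datasets


@pytest.fixture(scope="session")
def exome():
    """A small mini-exome study shared across tests."""
    cfg = ExomeConfig(n_genes=60, seed=3)
    study, truth = simulate_exome(cfg)
    return cfg, study, truth


@pytest.fixture(scope="session")
def phenotypes(exome):
    cfg, study, truth = exome
    return simulate_phenotypes(study, truth, cfg, seed=11)


@pytest.fixture(scope="session")
def datasets(exome):
    _, study, _ = exome
    return build_all_datasets(study)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_study(genotypes, gene_ids, func_classes=None):
    """Construct a GenotypeStudy from a raw matrix and per-column genes."""
    from generank.types import NONSYNONYMOUS, GenotypeStudy

    genotypes = np.asarray(genotypes, dtype=np.int8)
    m = genotypes.shape[1]
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{j}" for j in range(m)],
            "gene_id": gene_ids,
            "func_class": func_classes if func_classes is not None else [NONSYNONYMOUS] * m,
            "maf": np.nan,
        }
    )
    return GenotypeStudy(genotypes=genotypes, markers=markers)
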