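import numpy as np
import pandas as pd
import pytest

from rescuescreen.differential import Contrast, test_contrast
from rescuescreen.enrichment import AnnotationCatalog
from rescuescreen.quantify import fpkm_matrix
from rescuescreen.rescue import apply_screen
from rescuescreen.simulate import SimulationConfig, simulate_dataset

#: Conditions of the standard screen simulation used throughout: a large
#: null background with a planted set of restored genes at a strong effect.
STANDARD_CONFIG = SimulationConfig(
    n_null=2000,
    n_restored=100,
    effect_log2fc=1.5,
    n_replicates=3,
    dispersion=0.05,
    seed=7,
)

#: Contrast design of the screen: pathogenic vs wild-type, then the
#: pathogenic genotype against a protective and a rescue genotype.
SCREEN_CONTRASTS = (
    Contrast("wt_vs_path", "WT", "PATHOGENIC"),
    Contrast("path_vs_prot", "PATHOGENIC", "PROTECTIVE_A"),
    Contrast("path_vs_resc", "PATHOGENIC", "RESCUE_A"),
)


@pytest.fixture(scope="session")
def standard_dataset():
    return simulate_dataset(STANDARD_CONFIG)


@pytest.fixture(scope="session")
def standard_fpkm(standard_dataset):
    return fpkm_matrix(standard_dataset.counts, standard_dataset.lengths)


@pytest.fixture(scope="session")
def standard_tables(standard_dataset, standard_fpkm):
    return {
        c.name: test_contrast(standard_fpkm, c, standard_dataset.sample_sheet)
        for c in SCREEN_CONTRASTS
    }


@pytest.fixture(scope="session")
def standard_screen(standard_tables):
    return apply_screen(standard_tables, pathogenic="wt_vs_path")


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{j}" for j in range(6)]
    return pd.DataFrame(
        rng.integers(0, 500, (5, 6)), index=pd.Index(genes, name="gene_id"), columns=samples
    )


@pytest.fixture
def toy_catalog():
    """Five hand-built terms over a 40-gene universe, two categories."""
    universe = frozenset(f"u{i}" for i in range(40))
    terms = {
        "alpha": frozenset(f"u{i}" for i in range(0, 10)),
        "beta": frozenset(f"u{i}" for i in range(5, 20)),
        "gamma": frozenset(f"u{i}" for i in range(20, 24)),
        "delta": frozenset(f"u{i}" for i in range(0, 40)),
        "epsilon": frozenset(f"u{i}" for i in range(30, 36)),
    }
    categories = {
        "alpha": "KEYWORD",
        "beta": "KEYWORD",
        "gamma": "KEYWORD",
        "delta": "DOMAIN",
        "epsilon": "DOMAIN",
    }
    return AnnotationCatalog(terms=terms, categories=categories, universe=universe)
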