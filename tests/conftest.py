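import numpy as np
import pandas as pd
import pytest

import lineagemap as lm
from lineagemap import preprocess as pp


@pytest.fixture(scope="session")
def small_config() -> lm.GeneratorConfig:
    """A fast cohort: 800 genes, 7 subsets x 60 cells, 200 tumor cells."""
    return lm.GeneratorConfig(
        n_genes=800,
        cells_per_subset=60,
        n_tumor_cells=200,
        n_bulk_samples=30,
        cnv_segments=[
            ("chr1", 0, 36, 2.0),
            ("chr5", 0, 36, 0.5),
            ("chr8", 0, 30, 3.0),
            ("chr13", 0, 30, 1.5),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_normal(small_config) -> lm.SyntheticCohort:
    return lm.make_normal_cells(small_config)


@pytest.fixture(scope="session")
def small_tumor(small_config, small_normal) -> lm.SyntheticCohort:
    return lm.make_tumor_cells(small_config, small_normal)


@pytest.fixture(scope="session")
def small_bulk(small_config, small_normal) -> lm.BulkCohort:
    return lm.make_bulk_mixtures(small_config, small_normal)


@pytest.fixture(scope="session")
def default_normal() -> lm.SyntheticCohort:
    """The generator-default normal cohort (7 subsets x 150 cells)."""
    return lm.make_normal_cells(lm.GeneratorConfig())


@pytest.fixture(scope="session")
def small_normal_expr(small_normal) -> pd.DataFrame:
    filtered, _ = pp.qc_filter_cells(small_normal.counts)
    filtered, _ = pp.qc_filter_genes(filtered)
    return pp.normalize_log(filtered)


def toy_expression(n_genes=20, n_samples=5, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.lognormal(size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
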