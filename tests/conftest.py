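import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import atlasrep as ar
from atlasrep.markers import MarkerCatalog
from atlasrep.simulate import GeneratorConfig, simulate_pair, split_config


class PairBundle:
    """Simulated atlas pair with the derived objects most tests need."""

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        self.ds_a, self.ds_b, self.truth, raw_a, raw_b = simulate_pair(cfg)
        self.cat_a = MarkerCatalog(raw_a, "atlasA")
        self.cat_b = MarkerCatalog(raw_b, "atlasB")
        self.nv_a = ar.normalize_log_cpm(self.ds_a)
        self.nv_b = ar.normalize_log_cpm(self.ds_b)
        self.hvg = ar.select_hvgs([self.nv_a, self.nv_b])
        self._match = None

    @property
    def match(self):
        if self._match is None:
            self._match = ar.match_datasets(self.nv_a, self.nv_b, self.hvg)
        return self._match


@pytest.fixture(scope="session")
def default_pair():
    """Default study conditions plus three private types per atlas."""
    return PairBundle(GeneratorConfig(n_unique_a=3, n_unique_b=3, seed=1))


@pytest.fixture(scope="session")
def split_pair():
    """Every shared type split into two siblings in atlas B."""
    return PairBundle(split_config(seed=1))


@pytest.fixture(scope="session")
def small_pair():
    """Small, fast pair for oracle-equality tests (200 cells, 300 genes)."""
    return PairBundle(
        GeneratorConfig(n_types=10, n_genes=300, cells_per_type_a=(10, 10),
                        cells_per_type_b=(10, 10), seed=2)
    )


def tiny_dataset(seed=0, n_genes=30, n_cells=24, n_clusters=4, dataset_id="tiny"):
    rng = np.random.default_rng(seed)
    counts = sp.csr_matrix(rng.poisson(3.0, (n_genes, n_cells)))
    cells = pd.DataFrame(
        {"cluster": [f"k{i % n_clusters}" for i in range(n_cells)]},
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
    )
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    return ar.ExpressionDataset(dataset_id, counts, genes, cells)


@pytest.fixture()
def tiny_ds():
    return tiny_dataset()
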