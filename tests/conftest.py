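import numpy as np
import pandas as pd
import pytest

from gctme import sc_preprocess, synthetic


@pytest.fixture(scope="session")
def planted_sc():
    """Small single-cell dataset with strong planted markers (fold 8)."""
    cfg = synthetic.SimScConfig(
        n_genes=1200, n_markers_per_type=50, marker_fold=8.0, seed=11
    )
    adata, markers = synthetic.simulate_sc_dataset(cfg)
    return adata, markers, cfg


@pytest.fixture(scope="session")
def small_qc_config():
    """QC thresholds scaled to the synthetic gene count."""
    return sc_preprocess.QcConfig(
        min_genes_per_cell=50,
        min_gene_cell_fraction=0.02,
        min_cells_per_type=20,
        min_stages_per_type=2,
    )


@pytest.fixture(scope="session")
def population_tpm(planted_sc, small_qc_config):
    """TPM pseudobulk by (cell type, subject) from the planted dataset."""
    adata, _, _ = planted_sc
    filtered = sc_preprocess.qc_filter(adata, small_qc_config)
    pb = sc_preprocess.pseudobulk_summarize(filtered)
    return sc_preprocess.tpm_normalize(pb)


@pytest.fixture(scope="session")
def random_signature():
    """A 300-gene x 5-population synthetic signature with distinct profiles."""
    rng = np.random.default_rng(42)
    vals = rng.lognormal(mean=2.0, sigma=1.0, size=(300, 5))
    return pd.DataFrame(
        vals,
        index=[f"g{i:04d}" for i in range(300)],
        columns=["EMEC", "Stromal", "Endothelial", "Goblet", "PC"],
    )
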