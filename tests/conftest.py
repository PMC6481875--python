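import numpy as np
import pandas as pd
import pytest

from coexpair.core import ExpressionMatrix, PairedStudy, align_paired_study
from coexpair.simulate import SimulationConfig, generate_paired_study


def make_matrix(tissue, values, units=None, genes=None, scale="fpkm"):
    values = np.asarray(values, dtype=float)
    n_genes, n_units = values.shape
    units = units or [f"P{i+1}" for i in range(n_units)]
    genes = genes or [f"{tissue}_g{i}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=units)
    return ExpressionMatrix(tissue, df, scale=scale)


@pytest.fixture
def tiny_study():
    """5-unit, 2-tissue study with random positive expression."""
    rng = np.random.default_rng(123)
    a = make_matrix("EET", rng.lognormal(1.0, 1.0, size=(12, 5)))
    b = make_matrix("CAR", rng.lognormal(1.0, 1.0, size=(15, 5)))
    return align_paired_study([a, b])


@pytest.fixture
def planted_study():
    """Small planted-module study on the log2 scale (exact correlations)."""
    cfg = SimulationConfig(
        n_units=5,
        tissues=("EET", "CAR"),
        n_modules=3,
        genes_per_module_per_tissue=4,
        loading_range=(0.8, 1.0),
        negative_fraction=1 / 3,
        noise_sd=0.0,
        n_null_genes_per_tissue=20,
        subthreshold_fraction=0.0,
        log2_scale=True,
        seed=11,
    )
    study, truth = generate_paired_study(cfg)
    return cfg, study, truth
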