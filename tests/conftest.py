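import numpy as np
import pandas as pd
import pytest

from proteodx.matrix_io import ExpressionMatrix
from proteodx.synthetic_cohort import SimConfig, simulate_cohort


def make_matrix(values, genes=None, samples=None, layer="protein", scale="log2", mask=None):
    """Build an ExpressionMatrix from a plain array; NaNs become missing."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=genes, columns=samples)
    if mask is None:
        mdf = vdf.isna()
    else:
        mdf = pd.DataFrame(np.asarray(mask, dtype=bool), index=genes, columns=samples)
    return ExpressionMatrix(vdf, mdf, layer=layer, scale=scale)


@pytest.fixture
def small_config():
    return SimConfig(
        n_patients=20,
        n_controls=4,
        n_genes_protein=200,
        n_genes_targeted=80,
        n_markers_b=5,
        n_markers_t=5,
        censor_midpoint=16.0,
        seed=11,
    )


@pytest.fixture
def small_cohort(small_config):
    return simulate_cohort(small_config, [])


def no_censor_config(**kw):
    """Config with censoring effectively off (midpoint far below all abundances)."""
    defaults = dict(
        n_patients=20,
        n_controls=4,
        n_genes_protein=150,
        n_genes_targeted=60,
        censor_midpoint=-100.0,
        censor_slope=10.0,
        seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)
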