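import numpy as np
import pandas as pd
import pytest

from netmark.containers import CASE, CONTROL, ExpressionMatrix, PhenotypeLabels
from netmark.synthetic import SyntheticParams, generate_dataset


def make_em(values, gene_ids=None, sample_ids=None, scale="log2") -> ExpressionMatrix:
    """Small expression matrix from a nested list / array."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        scale=scale,
    )


def make_labels(n_case: int, n_control: int, case_prefix="s", offset=0) -> PhenotypeLabels:
    """Labels where the first n_case samples are cases."""
    groups = {}
    for i in range(n_case):
        groups[f"{case_prefix}{offset + i}"] = CASE
    for i in range(n_control):
        groups[f"{case_prefix}{offset + n_case + i}"] = CONTROL
    return PhenotypeLabels(groups)


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at the default conditions (seed 7)."""
    return generate_dataset(SyntheticParams(), seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """A light synthetic study for fast pipeline-level tests."""
    params = SyntheticParams(
        n_genes=300, n_per_group=6, n_de=40, effect_size=3.0, n_edges=60, planted_hub_degree=4,
        frac_coexpressed=0.2, n_sets=20, set_size=10, de_overlap=8,
    )
    return generate_dataset(params, seed=11)
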