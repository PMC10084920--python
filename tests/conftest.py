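import numpy as np
import pandas as pd
import pytest

from luas.synthetic import CohortConfig, ExpressionMatrix, gen_expression_cohort


@pytest.fixture(scope="session")
def default_cohort() -> ExpressionMatrix:
    return gen_expression_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort() -> ExpressionMatrix:
    cfg = CohortConfig(
        n_samples=30,
        n_genes_per_role={
            "adeno_marker": 3,
            "squam_marker": 3,
            "immune": 2,
            "dnb": 3,
            "background": 5,
        },
        noise_sd=0.0,
        dnb_burst_sd=0.0,
        dnb_burst_corr=0.0,
        seed=0,
    )
    return gen_expression_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_markers_cohort() -> ExpressionMatrix:
    """Zero noise, no immune bump: marker rank order is purely lineage-driven."""
    cfg = CohortConfig(
        n_samples=30,
        n_genes_per_role={
            "adeno_marker": 3,
            "squam_marker": 3,
            "immune": 0,
            "dnb": 3,
            "background": 5,
        },
        noise_sd=0.0,
        dnb_burst_sd=0.0,
        dnb_burst_corr=0.0,
        seed=0,
    )
    return gen_expression_cohort(cfg)


def toy_matrix(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    """Wrap a raw array into an ExpressionMatrix for small hand-built cases."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        gene_roles=pd.Series("unknown", index=pd.Index(genes), name="role"),
        sample_meta=pd.DataFrame(
            {"latent_coordinate": np.nan, "subtype": "unknown"}, index=pd.Index(samples)
        ),
    )
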