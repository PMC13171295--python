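import numpy as np
import pandas as pd
import anndata as ad
import pytest
from hypothesis import settings, HealthCheck

import txrescue as tx

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


SMALL_CFG = tx.CohortConfig(
    n_genes=400, cells_per_sample=250, n_celltypes=4,
    n_cancer_up=40, n_cancer_down=40, n_rescued_planted=12,
    n_treatment_only=15, markers_per_type=8, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across read-only tests."""
    return tx.generate_cohort(SMALL_CFG)


def make_adata(counts, genes=None, obs=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    obs = obs if obs is not None else pd.DataFrame(
        index=[f"c{i}" for i in range(counts.shape[0])])
    return ad.AnnData(X=counts.astype(np.int64), obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))
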