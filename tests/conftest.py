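import numpy as np
import pandas as pd
import pytest

from methylhub.config import SimConfig
from methylhub.matrix import PairedMatrix
from methylhub.synthetic import simulate_methylation_expression, simulate_ppi


def make_paired(values, n_pairs=None, feature_prefix="f"):
    """PairedMatrix from a 2D array; columns are pair-ordered tumor then normal."""
    values = np.asarray(values, dtype=float)
    if n_pairs is None:
        n_pairs = values.shape[1] // 2
    assert values.shape[1] == 2 * n_pairs
    pair_ids = [f"P{i}" for i in range(n_pairs)]
    samples = [f"{p}_T" for p in pair_ids] + [f"{p}_N" for p in pair_ids]
    pairing = pd.DataFrame(
        {"pair_id": pair_ids * 2, "status": ["tumor"] * n_pairs + ["normal"] * n_pairs},
        index=pd.Index(samples, name="sample"),
    )
    df = pd.DataFrame(
        values,
        index=[f"{feature_prefix}{i}" for i in range(values.shape[0])],
        columns=samples,
    )
    return PairedMatrix(df, pairing)


@pytest.fixture(scope="session")
def small_cohort():
    """High-power small synthetic cohort shared by integration-level tests."""
    cfg = SimConfig(n_genes=300, ppi_n_nodes=300, n_ei_planted=8, n_es_planted=8,
                    n_hubs_planted=2, seed=7)
    ann, beta, expr, truth = simulate_methylation_expression(cfg)
    ppi, hub_truth = simulate_ppi(cfg, truth)
    return {"config": cfg, "annotation": ann, "beta": beta, "expr": expr,
            "truth": truth, "ppi": ppi, "hub_truth": hub_truth}
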