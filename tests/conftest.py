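import numpy as np
import pandas as pd
import pytest

from clonehist import simcohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated patient reused by read-only tests."""
    cfg = simcohort.CohortConfig(
        n_patients=1, ages=(27,), wgd_time=(0.2,), n_biopsies=4,
        mutation_rate=200, subclone_mutations=40, n_clusters=2,
        n_genes=600, seed=11,
    )
    return simcohort.simulate_cohort(cfg)


def make_cluster_table(spec: dict, biopsies: list) -> pd.DataFrame:
    """Cluster table from {cluster_id: (n_subs, [ccf per biopsy])}."""
    rows = []
    for cid, (n, ccfs) in spec.items():
        rows.append([cid, n] + list(ccfs))
    return pd.DataFrame(rows, columns=["cluster", "n_subs"] + [f"ccf_{b}" for b in biopsies])


def bh_stepup_oracle(pvals: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
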