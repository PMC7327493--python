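import warnings

import numpy as np
import pandas as pd
import pytest

from crosstage import cluster, qc, synthio


@pytest.fixture(autouse=True)
def _quiet_kcnq_warning():
    # synthetic gene ids do not include Kcnq1ot1; the skip warning is expected
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Kcnq1ot1.*")
        yield


@pytest.fixture(scope="session")
def three_cluster_pair():
    """3+3 cluster stage pair with 2 shared sub-types and fold-8 markers."""
    cfg = synthio.SynthConfig(
        seed=5,
        n_genes=300,
        n_cells_per_stage=600,
        n_clusters_stage_a=3,
        n_clusters_stage_b=3,
        shared_clusters=((0, 0), (1, 1)),
    )
    mat_a, mat_b, truth = synthio.generate_stage_pair(cfg)
    return cfg, mat_a, mat_b, truth


@pytest.fixture(scope="session")
def qc_pair(three_cluster_pair):
    """The same pair after QC with a permissive total threshold."""
    _, mat_a, mat_b, _ = three_cluster_pair
    permissive = qc.QcConfig(mintotal=1.0)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Kcnq1ot1.*")
        tcm_a, _ = qc.run_qc(mat_a.counts.astype(float), permissive)
        tcm_b, _ = qc.run_qc(mat_b.counts.astype(float), permissive)
    return tcm_a, tcm_b


@pytest.fixture(scope="session")
def noise_model():
    """A mildly overdispersed mean-variance background model."""
    return cluster.BackgroundNoiseModel(
        coefficients=(0.5, 1.2, 0.02), domain=(0.1, 100.0)
    )


@pytest.fixture(scope="session")
def chain_dataset():
    """Single-stage data with a 3-cluster chain and 100 gradient genes."""
    cfg = synthio.SynthConfig(
        seed=11,
        n_genes=300,
        n_cells_per_stage=300,
        n_clusters_stage_a=3,
        trajectory_chain=(0, 1, 2),
        n_gradient_genes=100,
        n_marker_genes_per_cluster=10,
    )
    mat_a, _, truth = synthio.generate_stage_pair(cfg)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Kcnq1ot1.*")
        tcm, _ = qc.run_qc(mat_a.counts.astype(float), qc.QcConfig(mintotal=1.0))
    model = cluster.cluster_cells(tcm, k_max=5)
    return cfg, tcm, truth, model


def match_clusters(labels: pd.Series, truth_labels: pd.Series) -> dict:
    """Map fitted cluster ids to planted ids by majority vote."""
    out = {}
    for c in labels.unique():
        members = labels.index[labels == c]
        out[c] = truth_labels[members].mode().iloc[0]
    return out
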