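import numpy as np
import pandas as pd
import pytest

import swarmnet as sn
from swarmnet.ann import MLPConfig


@pytest.fixture(scope="session")
def fast_mlp():
    """Small-budget screening config for unit tests."""
    return MLPConfig(max_epochs=200, patience_epochs=50, mccv_iterations=5, seed=0)


@pytest.fixture(scope="session")
def swarm_mlp():
    """Train/validation-only config used by swarm-side unit tests."""
    return MLPConfig(
        max_epochs=500,
        patience_epochs=100,
        train_fraction=0.8,
        val_fraction=0.2,
        test_fraction=0.0,
    )


@pytest.fixture(scope="session")
def planted_small():
    """3 hidden regulators driving a 5-gene pathway among 50 genes."""
    return sn.make_pathway_scenario(
        n_transcriptome=50, n_pathway=5, n_regulators=3,
        effect_size=2.0, n_samples=200, noise_sd=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def planted_small_norm(planted_small):
    return sn.minmax_normalize(planted_small.expression)


def make_matrix(scores: np.ndarray, genes=None, accepted=None) -> sn.InteractionMatrix:
    """Hand-built InteractionMatrix for analysis-stage tests."""
    scores = np.asarray(scores, dtype=float).copy()
    n = scores.shape[0]
    np.fill_diagonal(scores, np.nan)
    if genes is None:
        genes = tuple(chr(ord("A") + i) for i in range(n))
    if accepted is None:
        accepted = np.ones(n, dtype=int)
    return sn.InteractionMatrix(
        gene_ids=tuple(genes), scores=scores,
        accepted_replicates=np.asarray(accepted, dtype=int),
    )


@pytest.fixture()
def three_gene_matrix():
    # A->B = -2, A->C = -1, everything else 0
    s = np.zeros((3, 3))
    s[0, 1] = -2.0
    s[0, 2] = -1.0
    return make_matrix(s)


@pytest.fixture()
def expr_tsv(tmp_path):
    """3-gene x 2-sample TSV fixture on disk."""
    p = tmp_path / "expr.tsv"
    pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["TP53", "MDM2", "CDK1"],
        columns=["s1", "s2"],
    ).rename_axis("gene").to_csv(p, sep="\t")
    return str(p)
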