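"""Stage 2 — swarm inference of the directed signed interaction matrix.

For every gene of the enriched set taken as output, a swarm of replicate
N-2-1 perceptrons is trained on all remaining genes as inputs.  Replicates
whose predicted-vs-observed Pearson r on the validation partition falls
below the cut-off (default 0.7) are rejected; the per-input signed scores of
the accepted replicates are averaged into one column of the interaction
matrix.  Entry (s, t) is the inferred influence of source gene s on target
gene t: positive = stimulatory, negative = inhibitory.

How a trained net's weights become a score is the one step the procedure's
description leaves open.  The default is the connection-weight product
score(i) = sum_h W_in_hidden[i, h] * W_hidden_out[h] (the classic
Olden-style signed importance); an analytic mean-gradient alternative
(mean over samples of d yhat / d x_i) is built in as a cross-check, and the
two provably agree in sign in the near-linear regime.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import derive_seeds
from .ann import MLPConfig, ParameterError, TrainedMLP, predict, train_mlp
from .preprocess import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "SwarmConfig",
    "InteractionMatrix",
    "extract_interaction_scores",
    "infer_target",
    "infer_network",
    "gradient_oracle_check",
]


def _default_swarm_mlp() -> MLPConfig:
    # swarm defaults: 100-epoch MSE window, no test partition (the swarm
    # needs only a train/validation split; MCCV scoring belongs to stage 1)
    return MLPConfig(
        patience_epochs=100,
        mse_improvement_threshold=0.01,
        max_epochs=3000,
        train_fraction=0.8,
        val_fraction=0.2,
        test_fraction=0.0,
    )


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters: 10 replicates per output, Pearson r cut-off 0.7."""

    replicates_per_output: int = 10
    pearson_r_cutoff: float = 0.7
    mlp: MLPConfig = field(default_factory=_default_swarm_mlp)
    score_method: str = "connection_weight"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_output < 1:
            raise ParameterError("replicates_per_output must be >= 1")
        if not (0.0 <= self.pearson_r_cutoff <= 1.0):
            raise ParameterError("pearson_r_cutoff must be in [0, 1]")
        if self.score_method not in ("connection_weight", "mean_gradient"):
            raise ParameterError(f"unknown score_method {self.score_method!r}")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")

    def snapshot(self) -> dict:
        d = asdict(self)
        d["mlp"]["init_weight_range"] = list(self.mlp.init_weight_range)
        return d


@dataclass
class InteractionMatrix:
    """Directed signed gene-gene scores, source row -> target column.

    The diagonal is undefined (NaN) and excluded from every computation, so
    an N-gene matrix has N(N-1) defined entries.  Targets for which no
    replicate passed the quality gate have a NaN column and
    ``accepted_replicates`` 0 — missing is recorded, never silently zero.
    """

    gene_ids: tuple[str, ...]
    scores: np.ndarray  # (N, N) float, NaN diagonal / missing
    accepted_replicates: np.ndarray  # (N,) int, per target
    config_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ParameterError("scores must be N x N")
        if self.accepted_replicates.shape != (n,):
            raise ParameterError("accepted_replicates must have one entry per target")
        if not np.isnan(np.diag(self.scores)).all():
            raise ParameterError("diagonal must be undefined (NaN)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def n_defined_entries(self) -> int:
        mask = np.isfinite(self.scores)
        np.fill_diagonal(mask, False)
        return int(mask.sum())

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.gene_ids)

    def save(self, prefix: str) -> list[str]:
        """Persist as square TSV (NA diagonal), long-form edge TSV and a JSON
        sidecar with config and acceptance counts; the two tables are
        bit-consistent."""
        square = f"{prefix}.matrix.tsv"
        df = self.to_square_frame()
        df.index.name = "source"
        df.to_csv(square, sep="\t", na_rep="NA")
        long = f"{prefix}.edges.tsv"
        rows = []
        for i, s in enumerate(self.gene_ids):
            for j, t in enumerate(self.gene_ids):
                if i == j or not np.isfinite(self.scores[i, j]):
                    continue
                rows.append((s, t, self.scores[i, j],
                             int(self.accepted_replicates[j])))
        pd.DataFrame(
            rows, columns=["source", "target", "score", "n_accepted_replicates"]
        ).to_csv(long, sep="\t", index=False)
        sidecar = f"{prefix}.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "format": "swarmnet.InteractionMatrix",
                    "version": 1,
                    "gene_ids": list(self.gene_ids),
                    "accepted_replicates": self.accepted_replicates.tolist(),
                    "config": self.config_snapshot,
                },
                fh,
                indent=1,
            )
        return [square, long, sidecar]

    @classmethod
    def load(cls, prefix: str) -> "InteractionMatrix":
        df = pd.read_csv(f"{prefix}.matrix.tsv", sep="\t", index_col=0)
        with open(f"{prefix}.json") as fh:
            side = json.load(fh)
        return cls(
            gene_ids=tuple(df.index),
            scores=df.to_numpy(dtype=float),
            accepted_replicates=np.asarray(side["accepted_replicates"], dtype=int),
            config_snapshot=side.get("config", {}),
        )


def extract_interaction_scores(
    mlp: TrainedMLP, method: str = "connection_weight", X: np.ndarray | None = None
) -> np.ndarray:
    """Signed per-input influence scores from a trained perceptron."""
    if method == "connection_weight":
        return mlp.W_in_hidden @ mlp.W_hidden_out
    elif method == "mean_gradient":
        if X is None:
            raise ParameterError("mean_gradient scoring needs data X")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != mlp.n_inputs:
            raise ParameterError("X shape inconsistent with the model")
        h = 1.0 / (1.0 + np.exp(-(X @ mlp.W_in_hidden + mlp.b_hidden)))
        o = 1.0 / (1.0 + np.exp(-(h @ mlp.W_hidden_out + mlp.b_out)))
        # d yhat / d x_i = o(1-o) * sum_h W2[h] h(1-h) W1[i,h]
        s = (o * (1.0 - o))[:, None] * mlp.W_hidden_out * h * (1.0 - h)  # (n, H)
        return (s @ mlp.W_in_hidden.T).mean(axis=0)
    raise ParameterError(f"unknown score method {method!r}")


def infer_target(
    matrix: ExpressionMatrix,
    target_gene: str,
    config: SwarmConfig,
    _replicate_archive: list | None = None,
) -> tuple[pd.Series, int]:
    """Swarm one output gene: returns (mean scores over accepted replicates
    indexed by source gene, number of accepted replicates).

    Replicate seeds are keyed on the target's symbol (not its row position).
    If no replicate reaches the Pearson r cut-off the scores are NaN.
    """
    target_gene = target_gene.upper()
    if target_gene not in matrix.data.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    if matrix.n_genes < 2:
        raise ParameterError("need at least 2 genes")
    if not matrix.normalized:
        raise ParameterError("swarm inference expects a normalized matrix")
    sources = [g for g in matrix.gene_ids if g != target_gene]
    X = matrix.data.loc[sources].to_numpy(dtype=float).T  # samples x (N-1)
    y = matrix.data.loc[target_gene].to_numpy(dtype=float)

    accepted = []
    for rep in range(config.replicates_per_output):
        split_seed, init_seed = derive_seeds(config.seed, target_gene, rep)
        mlp = train_mlp(X, y, config.mlp, split_seed, init_seed,
                        input_gene_ids=tuple(sources))
        ok = mlp.val_pearson_r >= config.pearson_r_cutoff
        if _replicate_archive is not None:
            _replicate_archive.append((target_gene, rep, mlp, ok))
        if ok:
            accepted.append(
                extract_interaction_scores(mlp, config.score_method, X=X)
            )
    if not accepted:
        return pd.Series(np.nan, index=sources), 0
    mean_scores = np.mean(np.stack(accepted, axis=0), axis=0)
    return pd.Series(mean_scores, index=sources), len(accepted)


def infer_network(
    matrix: ExpressionMatrix, genes: GeneSet, config: SwarmConfig
) -> InteractionMatrix:
    """Run the swarm with every gene of the set as output and assemble the
    N x N interaction matrix (gene-keyed seeding, so the result is invariant
    to input file row order)."""
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing[:10]}")
    from .preprocess import subset_to_genes

    sub = subset_to_genes(matrix, genes)
    order = list(sub.gene_ids)
    n = len(order)
    scores = np.full((n, n), np.nan)
    accepted = np.zeros(n, dtype=int)
    pos = {g: i for i, g in enumerate(order)}
    for j, target in enumerate(order):
        col, n_acc = infer_target(sub, target, config)
        accepted[j] = n_acc
        for src, val in col.items():
            scores[pos[src], j] = val
        log.info("swarm %s: %d/%d replicates accepted",
                 target, n_acc, config.replicates_per_output)
    return InteractionMatrix(
        gene_ids=tuple(order),
        scores=scores,
        accepted_replicates=accepted,
        config_snapshot=config.snapshot(),
    )


def gradient_oracle_check(
    mlp: TrainedMLP, X: np.ndarray, epsilon: float = 1e-4
) -> dict:
    """Compare connection-weight signs with central finite-difference
    sensitivities of the prediction averaged over the data."""
    X = np.asarray(X, dtype=float)
    cw = extract_interaction_scores(mlp, "connection_weight")
    fd = np.empty(mlp.n_inputs)
    for i in range(mlp.n_inputs):
        Xp = X.copy()
        Xm = X.copy()
        Xp[:, i] += epsilon
        Xm[:, i] -= epsilon
        fd[i] = float(np.mean((predict(mlp, Xp) - predict(mlp, Xm)) / (2 * epsilon)))
    agree = np.sign(cw) == np.sign(fd)
    return {
        "agreement_fraction": float(np.mean(agree)),
        "connection_weight": cw,
        "finite_difference": fd,
    }
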