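"""Ground-truth network and cohort expression simulation.

The real study inputs are patient transcriptome cohorts; this module stands
in for them with networks whose edges are known, so every downstream stage
can be tested for parameter recovery.  The generative model is deliberately
close to, but not identical with, the inference engine's functional form:
an acyclic signed-weight network with a sigmoid squashing link and additive
Gaussian noise.  Each regulated gene is

    x_child = sigmoid( GAIN * sum_j w_j * (x_parent_j - 0.5) ) + eps,

with exogenous (parent-free) genes drawn uniform on (0, 1) and
eps ~ N(0, noise_sd).  GAIN = 4 = 1/sigmoid'(0), so an edge of weight w
contributes slope ~ w at the operating point and moderate weights produce
recoverable monotone signed effects.  Downstream min-max normalization makes
the absolute scale irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, GeneSet

GAIN = 4.0

__all__ = [
    "SyntheticNetwork",
    "SyntheticDataset",
    "generate_network",
    "simulate_expression",
    "make_pathway_scenario",
    "make_cohort_pair",
    "edge_recovery_metrics",
]


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticNetwork:
    """A directed signed ground-truth regulatory network."""

    gene_ids: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (source, target, signed weight)
    generation_params: dict

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        for s, t, w in self.edges:
            g.add_edge(s, t, weight=w)
        return g

    def edge_dict(self) -> dict[tuple[str, str], float]:
        return {(s, t): w for s, t, w in self.edges}

    def write_tsv(self, path: str) -> None:
        pd.DataFrame(self.edges, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """Expression plus the ground truth that generated it."""

    expression: ExpressionMatrix
    network: SyntheticNetwork
    pathway_genes: GeneSet
    regulator_genes: GeneSet | None
    cohort_label: str

    def __post_init__(self) -> None:
        universe = set(self.expression.gene_ids)
        if not set(self.pathway_genes).issubset(universe):
            raise ParameterError("pathway genes must be in the expression matrix")
        if self.regulator_genes is not None:
            if not set(self.regulator_genes).issubset(universe):
                raise ParameterError("regulator genes must be in the expression matrix")
            if set(self.regulator_genes) & set(self.pathway_genes):
                raise ParameterError("pathway and regulator sets must be disjoint")


def generate_network(
    n_genes: int,
    density: float,
    weight_magnitude_range: tuple[float, float] = (0.5, 1.0),
    negative_fraction: float = 0.5,
    seed: int = 0,
    acyclic: bool = True,
    gene_prefix: str = "G",
) -> SyntheticNetwork:
    """Sample a random directed signed network.

    Edge count is round(density * n_genes * (n_genes - 1)); signs are
    negative with probability ``negative_fraction`` (real interaction
    matrices in this setting are predominantly negative).  With
    ``acyclic=True`` (default) edges are drawn forward along a random gene
    ordering, guaranteeing a DAG that :func:`simulate_expression` accepts;
    this caps the edge count at n(n-1)/2.
    """
    if n_genes < 2:
        raise ParameterError("n_genes must be >= 2")
    if not (0.0 < density <= 1.0):
        raise ParameterError("density must be in (0, 1]")
    lo, hi = weight_magnitude_range
    if not (0.0 <= lo <= hi):
        raise ParameterError("weight_magnitude_range must satisfy 0 <= lo <= hi")
    if not (0.0 <= negative_fraction <= 1.0):
        raise ParameterError("negative_fraction must be in [0, 1]")

    width = max(3, len(str(n_genes)))
    gene_ids = tuple(f"{gene_prefix}{i:0{width}d}" for i in range(1, n_genes + 1))
    n_edges = int(round(density * n_genes * (n_genes - 1)))
    rng = np.random.default_rng(seed)

    if acyclic:
        order = rng.permutation(n_genes)
        pairs = [
            (order[i], order[j])
            for i in range(n_genes)
            for j in range(i + 1, n_genes)
        ]
    else:
        pairs = [
            (i, j) for i in range(n_genes) for j in range(n_genes) if i != j
        ]
    if n_edges > len(pairs):
        raise ParameterError(
            f"density {density} needs {n_edges} edges but only {len(pairs)} "
            f"{'acyclic ' if acyclic else ''}pairs exist"
        )
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    magnitudes = rng.uniform(lo, hi, size=n_edges)
    negative = rng.random(n_edges) < negative_fraction
    edges = tuple(
        (
            gene_ids[pairs[k][0]],
            gene_ids[pairs[k][1]],
            float(-m if neg else m),
        )
        for k, m, neg in zip(chosen, magnitudes, negative)
    )
    params = {
        "n_genes": n_genes,
        "density": density,
        "weight_magnitude_range": (lo, hi),
        "negative_fraction": negative_fraction,
        "seed": seed,
        "acyclic": acyclic,
    }
    return SyntheticNetwork(gene_ids, edges, params)


def simulate_expression(
    network: SyntheticNetwork,
    n_samples: int,
    noise_sd: float,
    seed: int = 0,
    sample_prefix: str = "S",
) -> ExpressionMatrix:
    """Propagate uniform exogenous inputs through the network.

    Genes without parents are drawn uniform on (0, 1); each regulated gene is
    the sigmoid of the gain-scaled weighted sum of its centred parents plus
    Gaussian noise of scale ``noise_sd``.  Raises on cyclic input.
    """
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    g = network.to_digraph()
    if not nx.is_directed_acyclic_graph(g):
        raise ParameterError("network is cyclic; expression simulation needs a DAG")

    genes = list(network.gene_ids)
    idx = {g_: i for i, g_ in enumerate(genes)}
    rng = np.random.default_rng(seed)
    # draw all randomness up-front, indexed by gene position, so the result
    # does not depend on the traversal order
    base = rng.uniform(0.0, 1.0, size=(len(genes), n_samples))
    noise = rng.normal(0.0, 1.0, size=(len(genes), n_samples)) * noise_sd

    values = np.empty((len(genes), n_samples))
    order = nx.lexicographical_topological_sort(g, key=lambda n: idx[n])
    for gene in order:
        i = idx[gene]
        parents = list(g.predecessors(gene))
        if not parents:
            values[i] = base[i]
        else:
            z = np.zeros(n_samples)
            for p in parents:
                z += g.edges[p, gene]["weight"] * (values[idx[p]] - 0.5)
            values[i] = 1.0 / (1.0 + np.exp(-GAIN * z)) + noise[i]
    width = max(4, len(str(n_samples)))
    samples = [f"{sample_prefix}{j:0{width}d}" for j in range(1, n_samples + 1)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, normalized=False)


def make_pathway_scenario(
    n_transcriptome: int,
    n_pathway: int,
    n_regulators: int,
    effect_size: float,
    n_samples: int,
    noise_sd: float,
    seed: int = 0,
    negative_fraction: float = 0.5,
    cohort_label: str = "cohort1",
    _weight_scale: float = 1.0,
    _structure_seed: int | None = None,
) -> SyntheticDataset:
    """Planted pathway-augmentation scenario.

    ``n_regulators`` hidden genes each regulate every one of the
    ``n_pathway`` seed pathway genes with edge magnitude ``effect_size``
    (signs drawn with ``negative_fraction``); the remaining background genes
    are independent noise.  The ground-truth regulator identities are
    recorded so stepwise recovery can be scored.
    """
    if n_pathway < 1 or n_regulators < 0 or effect_size <= 0:
        raise ParameterError("need n_pathway >= 1, n_regulators >= 0, effect_size > 0")
    if n_pathway + n_regulators > n_transcriptome:
        raise ParameterError("n_pathway + n_regulators must be <= n_transcriptome")

    structure_seed = seed if _structure_seed is None else _structure_seed
    srng = np.random.default_rng(structure_seed)
    pathway = tuple(f"P{i:03d}" for i in range(1, n_pathway + 1))
    regulators = tuple(f"R{i:03d}" for i in range(1, n_regulators + 1))
    n_bg = n_transcriptome - n_pathway - n_regulators
    background = tuple(f"B{i:04d}" for i in range(1, n_bg + 1))
    gene_ids = pathway + regulators + background

    edges = []
    for r in regulators:
        for p in pathway:
            sign = -1.0 if srng.random() < negative_fraction else 1.0
            edges.append((r, p, sign * effect_size * _weight_scale))
    params = {
        "n_genes": n_transcriptome,
        "density": len(edges) / (n_transcriptome * (n_transcriptome - 1)),
        "weight_magnitude_range": (
            effect_size * _weight_scale,
            effect_size * _weight_scale,
        ),
        "negative_fraction": negative_fraction,
        "seed": seed,
        "acyclic": True,
        "scenario": "pathway",
        "structure_seed": structure_seed,
    }
    network = SyntheticNetwork(gene_ids, tuple(edges), params)
    expression = simulate_expression(network, n_samples, noise_sd, seed=seed)
    return SyntheticDataset(
        expression=expression,
        network=network,
        pathway_genes=GeneSet("pathway", pathway),
        regulator_genes=GeneSet("regulators", regulators) if regulators else None,
        cohort_label=cohort_label,
    )


def make_cohort_pair(
    base_scenario_params: dict,
    strength_multiplier_cohort2: float,
    seeds: tuple[int, int],
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two cohorts sharing network topology and edge signs.

    Cohort 2's edge weights are scaled by ``strength_multiplier_cohort2``, so
    a planted regulator is a strong driver in cohort 1 and proportionally
    weaker (or absent, multiplier 0) in cohort 2.  Expression noise is drawn
    independently per cohort from ``seeds``.
    """
    if strength_multiplier_cohort2 < 0:
        raise ParameterError("strength multiplier must be non-negative")
    s1, s2 = seeds
    c1 = make_pathway_scenario(
        **base_scenario_params, seed=s1, cohort_label="cohort1", _structure_seed=s1
    )
    c2 = make_pathway_scenario(
        **base_scenario_params,
        seed=s2,
        cohort_label="cohort2",
        _weight_scale=strength_multiplier_cohort2,
        _structure_seed=s1,  # shared topology and signs
    )
    return c1, c2


def edge_recovery_metrics(interaction_matrix, network: SyntheticNetwork) -> dict:
    """Score an inferred interaction matrix against the ground truth.

    Returns AUROC of |score| as an edge detector over all defined ordered
    pairs, plus sign accuracy among the top-K predictions (K = number of
    true edges) that are true edges.
    """
    from sklearn.metrics import roc_auc_score

    true = network.edge_dict()
    genes = list(interaction_matrix.gene_ids)
    scores = interaction_matrix.scores
    labels, mags, signs, pairs = [], [], [], []
    for i, s in enumerate(genes):
        for j, t in enumerate(genes):
            if i == j or not np.isfinite(scores[i, j]):
                continue
            pairs.append((s, t))
            labels.append(1 if (s, t) in true else 0)
            mags.append(abs(scores[i, j]))
            signs.append(np.sign(scores[i, j]))
    labels = np.asarray(labels)
    mags = np.asarray(mags)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ParameterError("ground truth has no defined positives and negatives")
    auroc = float(roc_auc_score(labels, mags))
    k = int(labels.sum())
    top = np.argsort(-mags, kind="stable")[:k]
    hit_signs = [
        signs[t] == np.sign(true[pairs[t]]) for t in top if labels[t] == 1
    ]
    sign_accuracy = float(np.mean(hit_signs)) if hit_signs else 0.0
    return {
        "auroc": auroc,
        "sign_accuracy": sign_accuracy,
        "n_true_edges": k,
        "n_defined_pairs": int(labels.size),
        "precision_at_k": float(np.mean(labels[top])) if k else 0.0,
    }
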