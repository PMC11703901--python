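"""Stage 1 — stepwise single-input screening and concordance enrichment.

Every candidate transcriptome gene is scored by how well it alone predicts a
given pathway gene under Monte Carlo cross-validation (mean held-out test
MSE of a 1-2-1 sigmoid perceptron; lower is stronger).  The whole ranking is
repeated (default ten times, with fresh MCCV partitions and weight draws),
and only candidates inside the top-``top_k`` prefix of *every* repetition —
the concordant genes — are accepted, which controls false discovery.  The
union of concordant genes over all pathway genes, minus the seed pathway
itself, is the enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import derive_seeds
from .ann import MLPConfig, ParameterError, _fit, _split, predict
from .preprocess import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "StepwiseResult",
    "EnrichedPathway",
    "rank_candidates",
    "concordant_genes",
    "enrich_pathway",
    "stepwise_forward_select",
]


@dataclass
class StepwiseResult:
    """Per-pathway-gene screening outcome across repetitions."""

    pathway_gene: str
    repetition_rankings: list[pd.DataFrame]  # columns: candidate, mean_test_mse, rank
    concordant: tuple[str, ...]
    top_k: int


@dataclass
class EnrichedPathway:
    """Seed pathway plus the concordantly top-ranked transcriptome genes."""

    seed_genes: GeneSet
    added_genes: GeneSet | None
    provenance: dict[str, set[str]]  # added gene -> pathway genes it predicted
    per_gene_results: dict[str, StepwiseResult]

    @property
    def all_genes(self) -> GeneSet:
        if self.added_genes is None:
            return self.seed_genes
        return GeneSet("enriched", self.seed_genes.genes + self.added_genes.genes)


def rank_candidates(
    matrix: ExpressionMatrix,
    target_gene: str,
    candidates: GeneSet,
    config: MLPConfig,
    repetition_seed: int = 0,
    direction: str = "candidate_as_input",
) -> pd.DataFrame:
    """One MCCV screening pass: rank all candidates for one target gene.

    Returns a DataFrame (candidate, mean_test_mse, rank) sorted ascending by
    score with lexicographic tie-breaks.  ``direction`` selects whether the
    candidate is the model input and the pathway gene the output (default)
    or the reverse.
    """
    if not matrix.normalized:
        raise ParameterError("rank_candidates expects a normalized matrix")
    target_gene = target_gene.upper()
    if target_gene not in matrix.data.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    if target_gene in candidates:
        raise ParameterError("candidates must exclude the target gene")
    if direction not in ("candidate_as_input", "candidate_as_output"):
        raise ParameterError(f"unknown direction {direction!r}")
    cand = sorted(set(candidates) & set(matrix.gene_ids))
    if not cand:
        raise ParameterError("no candidate genes present in the matrix")

    target_vals = matrix.data.loc[target_gene].to_numpy(dtype=float)
    cand_vals = matrix.data.loc[cand].to_numpy(dtype=float)
    n = target_vals.size
    if config.test_fraction <= 0:
        raise ParameterError("stepwise screening needs a positive test_fraction")

    # Each (candidate, repetition, iteration) gets its own independent MCCV
    # partition and weight draw.  Independence across candidates matters for
    # false-discovery control: with shared partitions the split noise cancels
    # between candidates, spuriously correlated candidates rank identically
    # in every repetition, and the concordance filter loses its power.
    totals = np.zeros(len(cand))
    ids = ("input",)
    for c_idx, c in enumerate(cand):
        if direction == "candidate_as_input":
            X = cand_vals[c_idx][:, None]
            y = target_vals
        else:
            X = target_vals[:, None]
            y = cand_vals[c_idx]
        for i in range(config.mccv_iterations):
            split_seed, init_seed = derive_seeds(config.seed, repetition_seed, c, i)
            split_rng = np.random.default_rng(split_seed)
            tr, va, te = _split(split_rng, n, config)
            mlp = _fit(X, y, config, tr, va, init_seed, split_rng, ids)
            pred = predict(mlp, X[te])
            totals[c_idx] += float(np.mean((pred - y[te]) ** 2))

    out = pd.DataFrame(
        {"candidate": cand, "mean_test_mse": totals / config.mccv_iterations}
    )
    out = out.sort_values(
        ["mean_test_mse", "candidate"], kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def concordant_genes(rankings: list[pd.DataFrame], top_k: int) -> tuple[str, ...]:
    """Intersection of the top-``top_k`` prefixes of all rankings.

    Order follows the first ranking.  Requires at least two rankings over an
    identical candidate universe.
    """
    if len(rankings) < 2:
        raise ParameterError("concordance needs at least 2 rankings")
    if top_k < 0:
        raise ParameterError("top_k must be >= 0")
    universes = [frozenset(r["candidate"]) for r in rankings]
    if len(set(universes)) != 1:
        raise ParameterError("rankings must share an identical candidate universe")
    if top_k == 0:
        return ()
    prefixes = [list(r["candidate"][:top_k]) for r in rankings]
    common = set(prefixes[0])
    for p in prefixes[1:]:
        common &= set(p)
    return tuple(g for g in prefixes[0] if g in common)


def enrich_pathway(
    matrix: ExpressionMatrix,
    pathway: GeneSet,
    config: MLPConfig,
    top_k: int = 10,
    n_repetitions: int = 10,
    direction: str = "candidate_as_input",
) -> EnrichedPathway:
    """Screen every pathway gene against all non-pathway genes and keep the
    concordant candidates.

    For each pathway gene the full candidate ranking is recomputed
    ``n_repetitions`` times with repetition-indexed seeds; a candidate is
    added only if it sits in the top-``top_k`` of every repetition.
    Provenance records which pathway gene(s) each added gene predicted.
    """
    present = [g for g in pathway if g in matrix.data.index]
    if not present:
        raise ParameterError("no pathway gene is present in the matrix")
    skipped = [g for g in pathway if g not in matrix.data.index]
    if skipped:
        log.warning("pathway genes absent from matrix, skipped: %s", skipped[:10])
    candidates = GeneSet(
        "candidates", tuple(g for g in matrix.gene_ids if g not in set(pathway))
    )
    provenance: dict[str, set[str]] = {}
    results: dict[str, StepwiseResult] = {}
    for target in present:
        rankings = []
        for rep in range(n_repetitions):
            (rep_seed,) = derive_seeds(config.seed, target, rep, n=1)
            rankings.append(
                rank_candidates(
                    matrix, target, candidates, config,
                    repetition_seed=rep_seed, direction=direction,
                )
            )
        if n_repetitions >= 2:
            conc = concordant_genes(rankings, top_k)
        else:
            conc = tuple(rankings[0]["candidate"][:top_k])
        results[target] = StepwiseResult(target, rankings, conc, top_k)
        for gene in conc:
            provenance.setdefault(gene, set()).add(target)
        log.info("stepwise %s: %d concordant of %d candidates",
                 target, len(conc), len(candidates))
    added = tuple(sorted(provenance))
    return EnrichedPathway(
        seed_genes=GeneSet(pathway.name, tuple(present)),
        added_genes=GeneSet("added", added) if added else None,
        provenance=provenance,
        per_gene_results=results,
    )


def stepwise_forward_select(
    matrix: ExpressionMatrix,
    target_gene: str,
    candidates: GeneSet,
    config: MLPConfig,
    max_terms: int = 5,
    min_improvement: float = 1e-4,
) -> pd.DataFrame:
    """Classic iterative stepwise loop (off the default path).

    Greedily grows the input set: at each round the candidate whose addition
    gives the lowest MCCV test MSE joins the model, until ``max_terms`` or
    until the best addition improves the score by less than
    ``min_improvement``.
    """
    from .ann import mccv_mse

    target_gene = target_gene.upper()
    if target_gene not in matrix.data.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    y = matrix.data.loc[target_gene].to_numpy(dtype=float)
    remaining = sorted(set(candidates) & set(matrix.gene_ids) - {target_gene})
    selected: list[str] = []
    rows = []
    best_score = np.inf
    while remaining and len(selected) < max_terms:
        scores = []
        for c in remaining:
            X = matrix.data.loc[selected + [c]].to_numpy(dtype=float).T
            scores.append(mccv_mse(X, y, config))
        k = int(np.lexsort((remaining, scores))[0])
        if best_score - scores[k] < min_improvement:
            break
        selected.append(remaining[k])
        best_score = scores[k]
        rows.append({"step": len(selected), "added": remaining[k],
                     "mean_test_mse": scores[k]})
        remaining.pop(k)
    return pd.DataFrame(rows, columns=["step", "added", "mean_test_mse"])
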