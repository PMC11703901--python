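"""Stage 3 — edge-list construction, sorting, filtering and export.

The interaction matrix is flattened to a long-form edge list carrying two
orderings: signed (largest to smallest raw score, showing the balance of
stimulatory vs inhibitory interactions) and absolute (interaction strength).
Top-K selection, per-gene neighbourhood filtering and Cytoscape-consumable
exports (SIF, GraphML, TSV) operate on that list.  All rank tie-breaks are
lexicographic by (source, target) for reproducibility.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "to_edge_list",
    "top_k_edges",
    "filter_by_gene",
    "count_possible_interactions",
    "summarize_distribution",
    "export_network",
    "load_edge_list",
]

_COLUMNS = ["source", "target", "score", "abs_score", "rank_signed", "rank_abs"]


def to_edge_list(matrix) -> pd.DataFrame:
    """Flatten an InteractionMatrix to one record per defined entry.

    Entries from targets with zero accepted replicates are excluded (and
    counted in the log) rather than imputed as zero — a zero would be a
    fabricated "no interaction" claim.  Result is ordered by rank_abs.
    """
    genes = list(matrix.gene_ids)
    rows = []
    n_missing = 0
    for i, s in enumerate(genes):
        for j, t in enumerate(genes):
            if i == j:
                continue
            v = matrix.scores[i, j]
            if not np.isfinite(v):
                n_missing += 1
                continue
            rows.append((s, t, float(v), abs(float(v))))
    if n_missing:
        log.info("edge list: %d undefined entries excluded", n_missing)
    if not rows:
        raise ValueError("interaction matrix has no defined entries")
    df = pd.DataFrame(rows, columns=["source", "target", "score", "abs_score"])
    signed_order = df.sort_values(
        ["score", "source", "target"], ascending=[False, True, True], kind="stable"
    ).index
    df.loc[signed_order, "rank_signed"] = np.arange(1, len(df) + 1)
    abs_order = df.sort_values(
        ["abs_score", "source", "target"], ascending=[False, True, True], kind="stable"
    ).index
    df.loc[abs_order, "rank_abs"] = np.arange(1, len(df) + 1)
    df = df.astype({"rank_signed": int, "rank_abs": int})
    df = df.sort_values("rank_abs", kind="stable", ignore_index=True)
    df.attrs["gene_universe"] = tuple(genes)
    return df


def _keep_attrs(df: pd.DataFrame, parent: pd.DataFrame) -> pd.DataFrame:
    df.attrs["gene_universe"] = parent.attrs.get("gene_universe", ())
    return df


def top_k_edges(edges: pd.DataFrame, k: int = 500) -> pd.DataFrame:
    """First min(k, |edges|) records by absolute interaction strength."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = edges.nsmallest(min(k, len(edges)), "rank_abs").reset_index(drop=True)
    return _keep_attrs(out, edges)


def filter_by_gene(edges: pd.DataFrame, gene: str, role: str = "either") -> pd.DataFrame:
    """Records in which ``gene`` plays the requested role; rankings kept."""
    gene = gene.upper()
    universe = edges.attrs.get("gene_universe") or tuple(
        pd.unique(pd.concat([edges["source"], edges["target"]]))
    )
    if gene not in universe:
        raise KeyError(f"gene {gene!r} is not in the matrix gene universe")
    if role == "source":
        mask = edges["source"] == gene
    elif role == "target":
        mask = edges["target"] == gene
    elif role == "either":
        mask = (edges["source"] == gene) | (edges["target"] == gene)
    else:
        raise ValueError(f"unknown role {role!r}")
    return _keep_attrs(edges[mask].reset_index(drop=True), edges)


def count_possible_interactions(n_genes: int) -> int:
    """Directed ordered pairs among n genes: n(n-1)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return n_genes * (n_genes - 1)


def summarize_distribution(edges: pd.DataFrame) -> dict:
    """Five-number summary of the scores plus the negative fraction.

    Quartiles use linear interpolation.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    s = edges["score"].to_numpy(dtype=float)
    return {
        "n": int(s.size),
        "min": float(s.min()),
        "q1": float(np.percentile(s, 25)),
        "median": float(np.percentile(s, 50)),
        "q3": float(np.percentile(s, 75)),
        "max": float(s.max()),
        "fraction_negative": float(np.mean(s < 0)),
    }


def _relation(score: float) -> str:
    if score > 0:
        return "stimulates"
    if score < 0:
        return "inhibits"
    return "neutral"


def export_network(edges: pd.DataFrame, format: str, path: str) -> str:
    """Write the edge list as SIF, GraphML or TSV.

    GraphML carries score/abs_score/sign edge attributes and each node's
    summed outgoing influence (for node sizing).  TSV round-trips via
    :func:`load_edge_list`.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    if format == "tsv":
        edges.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        n_zero = int((edges["score"] == 0).sum())
        if n_zero:
            log.warning("%d zero-score edges exported with relation 'neutral'", n_zero)
        with open(path, "w") as fh:
            for row in edges.itertuples(index=False):
                fh.write(f"{row.source}\t{_relation(row.score)}\t{row.target}\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        influence = edges.groupby("source")["score"].sum()
        nodes = set(edges["source"]) | set(edges["target"])
        for node in sorted(nodes):
            g.add_node(node, influence=float(influence.get(node, 0.0)))
        for row in edges.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                score=float(row.score),
                abs_score=float(row.abs_score),
                sign=int(np.sign(row.score)),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def load_edge_list(path: str) -> pd.DataFrame:
    """Re-import a TSV edge list written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing edge-list columns {missing}")
    df.attrs["gene_universe"] = tuple(
        pd.unique(pd.concat([df["source"], df["target"]]))
    )
    return df
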