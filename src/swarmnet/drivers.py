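"""Stage 4 — driver/receiver ranking and differential driver analysis.

A gene's driver score is the sum of the interaction weights it confers on
every target (outgoing row sum); its receiver score is the sum of weights
conferred on it (incoming column sum).  Both totals conserve the grand sum
of all defined entries.  "Influence" ranking uses the absolute summed
weight with the sign reported alongside — in a predominantly inhibitory
network all the big drivers are negative, so a signed descending order would
invert the notion of "most influential"; a signed ranking is available via
``ranking="signed"``.

Differential driver analysis compares per-gene mean driver scores between
cohort groups (e.g. adult vs paediatric): group means are unweighted across
cohorts by default, and cross-cohort gene universes are outer-joined with
explicit missingness, never silently intersected or imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DriverScores", "driver_scores", "differential_drivers"]


@dataclass
class DriverScores:
    """Per-gene summed outgoing/incoming influence with ranks, one cohort."""

    table: pd.DataFrame  # index gene; driver_score, receiver_score, ranks
    cohort_label: str

    def write_tsv(self, path: str) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.insert(0, "cohort", self.cohort_label)
        out.to_csv(path, sep="\t")


def _rank_by(values: pd.Series, mode: str) -> pd.Series:
    key = values.abs() if mode == "absolute" else values
    order = pd.DataFrame({"key": key, "gene": key.index}).sort_values(
        ["key", "gene"], ascending=[False, True], kind="stable"
    )
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order["gene"])
    return ranks.reindex(values.index)


def driver_scores(
    matrix, cohort_label: str = "", ranking: str = "absolute"
) -> DriverScores:
    """Sum each gene's outgoing and incoming interaction weights and rank."""
    if ranking not in ("absolute", "signed"):
        raise ValueError(f"unknown ranking mode {ranking!r}")
    if matrix.n_defined_entries() == 0:
        raise ValueError("interaction matrix has no defined entries")
    genes = list(matrix.gene_ids)
    s = matrix.scores
    driver = pd.Series(np.nansum(s, axis=1), index=genes)
    receiver = pd.Series(np.nansum(s, axis=0), index=genes)
    table = pd.DataFrame(
        {
            "driver_score": driver,
            "receiver_score": receiver,
            "driver_rank": _rank_by(driver, ranking),
            "receiver_rank": _rank_by(receiver, ranking),
        }
    )
    return DriverScores(table=table, cohort_label=cohort_label)


def differential_drivers(
    scoresets: list[DriverScores],
    grouping: dict[str, str],
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compare per-gene mean driver influence between two cohort groups.

    ``grouping`` maps each cohort label to one of exactly two group names.
    Group means are unweighted unless per-cohort ``weights`` (e.g. sample
    sizes) are supplied.  Returns one row per gene of the outer-joined
    universe with per-cohort scores, group means, their difference
    (first group minus second, in ``grouping`` insertion order), within-group
    ranks by absolute mean, the rank shift, and a ``missing_in`` flag.
    """
    if len(scoresets) < 2:
        raise ValueError("differential analysis needs at least 2 cohorts")
    labels = [s.cohort_label for s in scoresets]
    if len(set(labels)) != len(labels):
        raise ValueError("cohort labels must be unique")
    if set(grouping) != set(labels):
        raise ValueError("grouping must cover exactly the provided cohorts")
    groups: list[str] = []
    for g in grouping.values():
        if g not in groups:
            groups.append(g)
    if len(groups) < 2:
        raise ValueError("grouping must define at least two groups")
    if len(groups) != 2:
        raise ValueError("differential comparison is defined between exactly 2 groups")
    ga, gb = groups

    wide = pd.concat(
        {s.cohort_label: s.table["driver_score"] for s in scoresets}, axis=1
    )
    means = {}
    for grp in groups:
        cohorts = [c for c in labels if grouping[c] == grp]
        block = wide[cohorts]
        if weights:
            w = np.array([weights[c] for c in cohorts], dtype=float)
            means[grp] = (block * w).sum(axis=1, min_count=len(cohorts)) / w.sum()
        else:
            means[grp] = block.mean(axis=1, skipna=False)
    out = wide.copy()
    out[f"mean_{ga}"] = means[ga]
    out[f"mean_{gb}"] = means[gb]
    out["difference"] = means[ga] - means[gb]
    out[f"rank_{ga}"] = _rank_by(means[ga].fillna(0.0), "absolute")
    out[f"rank_{gb}"] = _rank_by(means[gb].fillna(0.0), "absolute")
    out["rank_shift"] = out[f"rank_{gb}"] - out[f"rank_{ga}"]
    out["missing_in"] = [
        ",".join(c for c in labels if pd.isna(row[c])) for _, row in wide.iterrows()
    ]
    out.index.name = "gene"
    return out
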