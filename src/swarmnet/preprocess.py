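"""Expression-matrix and gene-set I/O plus per-gene min-max normalization.

Expression matrices are genes x samples delimited text with a header row of
sample identifiers and gene symbols in the first column.  Normalization is
per gene across samples, within each dataset separately: x' = (x - min) /
(max - min), so every gene lands on [0, 1] — the scale sigmoid units train
well on.  Per-gene scaling also makes the normalize/subset order irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "LoadError",
    "read_expression",
    "write_expression",
    "minmax_normalize",
    "subset_to_genes",
    "read_gene_set",
    "write_gene_set",
]


class LoadError(ValueError):
    """Unreadable, empty or inconsistent input file."""


@dataclass
class ExpressionMatrix:
    """Genes x samples table of continuous expression values.

    ``data`` is a pandas DataFrame indexed by unique gene symbols with unique
    sample-ID columns; ``normalized`` records whether per-gene min-max
    scaling has been applied.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate gene symbols: {dups[:10]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample IDs: {dups[:10]}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise LoadError("empty expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered set of canonically uppercased gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for g in self.genes:
            g = str(g).strip().upper()
            if g and g not in seen:
                seen.add(g)
                canon.append(g)
        if not canon:
            raise LoadError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(canon))

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or self.name, self.genes + tuple(g for g in other.genes))


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(
    path: str,
    delimiter: str = "auto",
    duplicate_policy: str = "error",
    missing_policy: str = "error",
) -> ExpressionMatrix:
    """Load a genes x samples matrix from delimited text.

    ``duplicate_policy`` resolves repeated gene symbols (``error`` | ``first``
    | ``mean``); ``missing_policy`` handles rows with missing values
    (``error`` | ``drop_gene``).
    """
    if delimiter == "auto":
        sep = _sniff_delimiter(path)
    elif delimiter in ("tab", "\t"):
        sep = "\t"
    elif delimiter in ("comma", ","):
        sep = ","
    else:
        raise LoadError(f"unknown delimiter {delimiter!r}")
    # check sample IDs on the raw header line: pandas mangles duplicates
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dups: list[str] = []
    for s in header:
        if s in seen and s not in dups:
            dups.append(s)
        seen.add(s)
    if dups:
        raise LoadError(f"{path}: duplicate sample IDs {dups[:10]}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"could not parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise LoadError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str).str.strip().str.upper()
    df = df.apply(pd.to_numeric, errors="coerce")

    if df.index.duplicated().any():
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if duplicate_policy == "error":
            raise LoadError(f"{path}: duplicate gene symbols {dup_genes[:10]}")
        elif duplicate_policy == "first":
            n_before = df.shape[0]
            df = df[~df.index.duplicated(keep="first")]
            log.info("%s: kept first of %d duplicated rows", path, n_before - df.shape[0])
        elif duplicate_policy == "mean":
            order = df.index[~df.index.duplicated(keep="first")]
            df = df.groupby(level=0, sort=False).mean().loc[order]
            log.info("%s: merged duplicate gene rows by mean", path)
        else:
            raise LoadError(f"unknown duplicate_policy {duplicate_policy!r}")

    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        if missing_policy == "error":
            raise LoadError(f"{path}: missing values in genes {bad[:10]}")
        elif missing_policy == "drop_gene":
            df = df.dropna(axis=0)
            log.info("%s: dropped %d genes with missing values", path, len(bad))
            if df.shape[0] == 0:
                raise LoadError(f"{path}: all genes had missing values")
        else:
            raise LoadError(f"unknown missing_policy {missing_policy!r}")

    return ExpressionMatrix(df, normalized=False)


def write_expression(matrix: ExpressionMatrix, path: str) -> None:
    """Write as TSV with the gene column labelled ``gene`` (round-trips)."""
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def minmax_normalize(
    matrix: ExpressionMatrix, constant_gene_policy: str = "drop"
) -> ExpressionMatrix:
    """Scale each gene to [0, 1]: x' = (x - row_min) / (row_max - row_min).

    Constant genes carry no trainable signal and break the formula; they are
    dropped with a warning by default, or pinned to 0.5 with
    ``constant_gene_policy="midpoint"``.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    vals = matrix.data.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    constant = (hi == lo).ravel()
    if constant.all():
        raise ValueError("all genes are constant; nothing to normalize")
    span = np.where(constant[:, None], 1.0, hi - lo)
    scaled = (vals - lo) / span
    if constant.any():
        const_genes = [g for g, c in zip(matrix.gene_ids, constant) if c]
        if constant_gene_policy == "drop":
            log.warning("dropping %d constant genes: %s",
                        len(const_genes), const_genes[:10])
            keep = ~constant
            df = pd.DataFrame(scaled[keep], index=np.asarray(matrix.gene_ids)[keep],
                              columns=matrix.sample_ids)
            return ExpressionMatrix(df, normalized=True)
        elif constant_gene_policy == "midpoint":
            scaled[constant] = 0.5
        else:
            raise ValueError(f"unknown constant_gene_policy {constant_gene_policy!r}")
    df = pd.DataFrame(scaled, index=matrix.gene_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(df, normalized=True)


def subset_to_genes(
    matrix: ExpressionMatrix, genes: GeneSet, missing_gene_policy: str = "error"
) -> ExpressionMatrix:
    """Slice the matrix to a gene set; row order follows the set's order."""
    present = [g for g in genes if g in matrix.data.index]
    missing = [g for g in genes if g not in matrix.data.index]
    if not present:
        raise KeyError(
            f"none of the requested genes are present; first requested: "
            f"{list(genes)[:10]}"
        )
    if missing:
        if missing_gene_policy == "error":
            raise KeyError(f"genes absent from the matrix: {missing[:10]}")
        elif missing_gene_policy == "warn_skip":
            log.warning("skipping %d absent genes: %s", len(missing), missing[:10])
        else:
            raise ValueError(f"unknown missing_gene_policy {missing_gene_policy!r}")
    return ExpressionMatrix(matrix.data.loc[present].copy(), normalized=matrix.normalized)


def read_gene_set(path: str, format: str = "auto") -> GeneSet:
    """Read a gene set from plain text (one symbol per line, ``#`` comments)
    or the first record of a GMT file."""
    if format == "auto":
        format = "gmt" if str(path).lower().endswith(".gmt") else "plain"
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise LoadError(f"{path}: empty gene set file")
    if format == "plain":
        import os
        name = os.path.splitext(os.path.basename(path))[0]
        return GeneSet(name, tuple(lines))
    elif format == "gmt":
        fields = lines[0].split("\t")
        if len(fields) < 3:
            raise LoadError(f"{path}: GMT record needs name, description, members")
        return GeneSet(fields[0], tuple(fields[2:]))
    raise LoadError(f"unknown gene set format {format!r}")


def write_gene_set(genes: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {genes.name}\n")
        for g in genes:
            fh.write(g + "\n")
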