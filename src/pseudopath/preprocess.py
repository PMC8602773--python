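"""Loading, normalization, and feature selection of expression matrices.

The pipeline operates on a cells-by-genes matrix of log-scale expression
values (log2(TPM+1) or log2(FPKM+1)).  Feature selection keeps genes from a
user-supplied development-associated gene set (e.g. Gene Ontology terms such
as "cell development" or "cell differentiation") and then filters by a
per-gene dispersion ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """A cells-by-genes matrix of nonnegative expression values.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_genes)``; finite, nonnegative after
        normalization.
    cell_ids, gene_ids
        Row and column identifiers.  Cell ids must be unique; duplicate gene
        ids are resolved by :func:`load_expression` (highest-mean copy wins).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = sorted({c for c in self.cell_ids if self.cell_ids.count(c) > 1})
            raise ValueError(f"duplicate cell ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell_id")


@dataclass
class GeneSet:
    """A named set of gene identifiers (case-sensitive membership)."""

    name: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = set(map(str, self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def _dedupe_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate gene columns by keeping the highest-mean copy."""
    if df.columns.is_unique:
        return df
    means = df.mean(axis=0)
    keep: dict[str, int] = {}
    cols = list(df.columns)
    for pos, g in enumerate(cols):
        if g not in keep or means.iloc[pos] > means.iloc[keep[g]]:
            keep[g] = pos
    dupes = sorted({g for g in cols if cols.count(g) > 1})
    warnings.warn(
        f"{len(dupes)} duplicate gene id(s) (e.g. {dupes[:3]}); "
        "keeping the copy with the highest mean expression",
        stacklevel=3,
    )
    positions = sorted(keep.values())
    return df.iloc[:, positions]


def load_expression(
    path: str | Path,
    orientation: Literal["cells_by_genes", "genes_by_cells"] = "cells_by_genes",
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix from dense TSV/CSV or MatrixMarket MTX.

    Dense input must have a header row and an id column (first column).  MTX
    input requires the two sidecar id files ``genes_file`` and
    ``barcodes_file`` (one id per line); missing entries become 0.  The
    returned matrix always has cells as rows, regardless of the on-disk
    orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if path.suffix.lower() == ".mtx":
        if genes_file is None or barcodes_file is None:
            genes_file = path.with_name("genes.txt")
            barcodes_file = path.with_name("barcodes.txt")
        genes = Path(genes_file).read_text().split()
        barcodes = Path(barcodes_file).read_text().split()
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if orientation == "genes_by_cells":
            mat = mat.T
            row_ids, col_ids = barcodes, genes
        else:
            row_ids, col_ids = barcodes, genes
        if mat.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(row_ids)} barcodes, {len(col_ids)} genes)"
            )
        df = pd.DataFrame(mat, index=row_ids, columns=col_ids)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        # pandas mangles duplicate header names (gA, gA.1); restore the
        # originals so the de-duplication policy can see them
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(header) == df.shape[1]:
            df.columns = header
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric expression value at row {row!r}, column {col!r}")
        df = df.astype(float)
        if orientation == "genes_by_cells":
            df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    df = _dedupe_genes(df)
    return ExpressionMatrix.from_frame(df)


def log_transform(expr: ExpressionMatrix, already_log: bool = False) -> ExpressionMatrix:
    """Apply ``log2(x + 1)`` unless the input is flagged as already log-scale."""
    if already_log:
        return expr
    if np.any(expr.values < 0):
        raise ValueError("negative expression values; cannot log-transform")
    return ExpressionMatrix(np.log2(expr.values + 1.0), expr.cell_ids, expr.gene_ids)


def select_gene_set(expr: ExpressionMatrix, gs: GeneSet) -> ExpressionMatrix:
    """Restrict columns to members of ``gs``, preserving column order."""
    mask = [g in gs for g in expr.gene_ids]
    if not any(mask):
        raise ValueError(
            f"no overlap between the {expr.n_genes} matrix genes and the "
            f"{len(gs)} genes of set {gs.name!r}"
        )
    idx = np.flatnonzero(mask)
    return ExpressionMatrix(
        expr.values[:, idx],
        expr.cell_ids,
        [expr.gene_ids[i] for i in idx],
    )


def gene_dispersion(
    expr: ExpressionMatrix,
    statistic: Literal["var_over_mean", "cv", "inv_cv"] = "var_over_mean",
) -> np.ndarray:
    """Per-gene dispersion ratio.

    ``var_over_mean`` (default) is the sample variance divided by the mean,
    the usual scRNA-seq dispersion.  ``cv`` is sd/mean and ``inv_cv`` is
    mean/sd.  Genes with zero mean (or zero sd for ``inv_cv``) get a
    dispersion of 0 so they are always filtered out.
    """
    vals = expr.values
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1)
    disp = np.zeros(expr.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "var_over_mean":
            ok = mean > 0
            disp[ok] = var[ok] / mean[ok]
        elif statistic == "cv":
            ok = mean > 0
            disp[ok] = np.sqrt(var[ok]) / mean[ok]
        elif statistic == "inv_cv":
            sd = np.sqrt(var)
            ok = sd > 0
            disp[ok] = mean[ok] / sd[ok]
        else:
            raise ValueError(f"unknown dispersion statistic {statistic!r}")
    return disp


def dispersion_filter(
    expr: ExpressionMatrix,
    cutoff: float = 10.0,
    statistic: Literal["var_over_mean", "cv", "inv_cv"] = "var_over_mean",
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Keep genes whose dispersion ratio is at least ``cutoff``.

    Returns the filtered matrix and the full per-gene dispersion vector.
    Genes with zero mean are always dropped.
    """
    if expr.n_cells < 2:
        raise ValueError("dispersion requires at least 2 cells")
    disp = gene_dispersion(expr, statistic)
    mean = expr.values.mean(axis=0)
    keep = (disp >= cutoff) & (mean > 0)
    if not keep.any():
        raise ValueError(
            f"dispersion cutoff {cutoff} removed all {expr.n_genes} genes; "
            "try a lower cutoff"
        )
    idx = np.flatnonzero(keep)
    out = ExpressionMatrix(
        expr.values[:, idx], expr.cell_ids, [expr.gene_ids[i] for i in idx]
    )
    return out, disp


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line!r}")
        name = parts[0]
        sets[name] = GeneSet(name, set(parts[2:]) - {""})
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain one-gene-per-line list as a single gene set."""
    genes = {g.strip() for g in Path(path).read_text().split() if g.strip()}
    return GeneSet(name or Path(path).stem, genes)


def union_gene_sets(sets: Iterable[GeneSet], name: str = "union") -> GeneSet:
    merged: set[str] = set()
    for gs in sets:
        merged |= gs.genes
    return GeneSet(name, merged)
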