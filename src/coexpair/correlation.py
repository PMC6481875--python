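"""All-pairs cross-tissue correlation and edge extraction.

The central object is the j x k matrix of Pearson correlations between every
gene of one tissue and every gene of another, computed across the paired
units.  Entries are undefined (NaN) when either profile has zero variance.
Computation is blocked so memory stays bounded at the real-data scale
(j, k ~ 1e4), but correctness is defined entry-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ExpressionMatrix

__all__ = [
    "pearson_r",
    "standardize_rows",
    "CrossCorrelationMatrix",
    "cross_correlation_matrix",
    "EdgeSet",
    "significant_edges",
    "write_edges_tsv",
    "write_edges_sif",
]


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Returns NaN (the undefined marker) if either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("pearson_r expects 1-D vectors")
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center and L2-normalize each row; zero-variance rows become all-NaN.

    With rows standardized this way, ``A @ B.T`` is exactly the matrix of
    pairwise Pearson correlations.
    """
    v = np.asarray(values, dtype=float)
    centered = v - v.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    out = np.full_like(centered, np.nan)
    ok = norms > 0
    out[ok] = centered[ok] / norms[ok, None]
    return out


@dataclass
class CrossCorrelationMatrix:
    """j x k Pearson correlations between genes of two tissues."""

    tissue_a: str
    tissue_b: str
    genes_a: pd.Index
    genes_b: pd.Index
    r: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.genes_a), len(self.genes_b)):
            raise ValueError("correlation matrix shape does not match gene lists")
        defined = self.r[~np.isnan(self.r)]
        if defined.size and np.abs(defined).max() > 1 + 1e-12:
            raise ValueError("correlation entries outside [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    @property
    def n_pairs(self) -> int:
        """Total j x k pair count."""
        return self.r.size

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.r).sum())

    @property
    def n_defined(self) -> int:
        """Effective pair count: defined entries only."""
        return self.r.size - self.n_undefined

    def transpose(self) -> "CrossCorrelationMatrix":
        return CrossCorrelationMatrix(
            self.tissue_b, self.tissue_a, self.genes_b, self.genes_a,
            self.r.T.copy(), self.n_units,
        )


def cross_correlation_matrix(
    a: ExpressionMatrix, b: ExpressionMatrix, block_size: int = 4096
) -> CrossCorrelationMatrix:
    """All-pairs correlation between genes of ``a`` and genes of ``b``.

    Both matrices must share an identical unit order (run
    :func:`coexpair.core.align_paired_study` first).  Zero-variance genes
    produce undefined (NaN) rows/columns.
    """
    if a.unit_ids != b.unit_ids:
        raise ValueError(
            "unit orders differ between tissues "
            f"{a.tissue!r} and {b.tissue!r}; align the study first"
        )
    sa = standardize_rows(a.values)
    sb = standardize_rows(b.values)
    j = sa.shape[0]
    r = np.empty((j, sb.shape[0]), dtype=float)
    for start in range(0, j, block_size):
        stop = min(start + block_size, j)
        r[start:stop] = sa[start:stop] @ sb.T
    np.clip(r, -1.0, 1.0, out=r)
    return CrossCorrelationMatrix(
        a.tissue, b.tissue, a.gene_ids, b.gene_ids, r, a.n_units
    )


@dataclass
class EdgeSet:
    """Significant cross-tissue gene pairs with their correlation and eFDR."""

    tissue_a: str
    tissue_b: str
    table: pd.DataFrame  # columns: gene_a, gene_b, r, efdr
    r_threshold: float

    @property
    def n_edges(self) -> int:
        return self.table.shape[0]

    def genes(self, side: str) -> set:
        if side == self.tissue_a:
            return set(self.table["gene_a"])
        if side == self.tissue_b:
            return set(self.table["gene_b"])
        raise ValueError(f"unknown side {side!r}")


def significant_edges(
    R: CrossCorrelationMatrix,
    r_threshold: float,
    efdr_value: Optional[float] = None,
) -> EdgeSet:
    """All defined pairs with |r| strictly greater than ``r_threshold``.

    ``efdr_value`` is the empirical FDR at this threshold (annotation only).
    """
    if not 0.0 <= r_threshold <= 1.0:
        raise ValueError("r_threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        ii, jj = np.nonzero(np.abs(R.r) > r_threshold)
    table = pd.DataFrame(
        {
            "gene_a": R.genes_a[ii],
            "gene_b": R.genes_b[jj],
            "r": R.r[ii, jj],
            "efdr": np.nan if efdr_value is None else float(efdr_value),
        }
    )
    return EdgeSet(R.tissue_a, R.tissue_b, table, r_threshold)


def write_edges_tsv(edges: EdgeSet, path) -> None:
    edges.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_edges_sif(edges: EdgeSet, path) -> None:
    """SIF export for network viewers: gene_a <tab> coexpr_pos|coexpr_neg <tab> gene_b."""
    with open(path, "w") as fh:
        for row in edges.table.itertuples(index=False):
            rel = "coexpr_pos" if row.r >= 0 else "coexpr_neg"
            fh.write(f"{row.gene_a}\t{rel}\t{row.gene_b}\n")
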