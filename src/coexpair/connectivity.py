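"""Per-gene degree-of-connectivity summaries and distribution comparison.

The degree of connectivity of a gene is its number of significant
cross-tissue partners in an edge set.  Summaries are reported both over the
connected genes (degree >= 1, matching how mean/median connectivity is
usually quoted) and over the full gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import EdgeSet

__all__ = ["DegreeSummary", "degree_summary", "compare_distributions"]


@dataclass
class DegreeSummary:
    side: str
    degrees: pd.Series  # gene id -> degree, over the universe
    n_edges: int
    n_connected: int
    mean_connected: float
    median_connected: float
    mean_all: float
    median_all: float

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "n_edges": self.n_edges,
            "n_connected": self.n_connected,
            "mean_connected": self.mean_connected,
            "median_connected": self.median_connected,
            "mean_all": self.mean_all,
            "median_all": self.median_all,
        }


def degree_summary(
    edges: EdgeSet, side: str, gene_universe: Optional[Sequence] = None
) -> DegreeSummary:
    """Degree per gene of one side, over an optional gene universe.

    Genes of the universe absent from the edge set get degree 0.  The sum of
    degrees on either side equals the edge count.
    """
    if side == edges.tissue_a:
        col = "gene_a"
    elif side == edges.tissue_b:
        col = "gene_b"
    else:
        raise ValueError(
            f"side {side!r} is not one of ({edges.tissue_a!r}, {edges.tissue_b!r})"
        )
    counts = edges.table[col].value_counts()
    if gene_universe is None:
        degrees = counts.sort_index()
    else:
        degrees = counts.reindex(pd.Index(gene_universe), fill_value=0)
    degrees = degrees.astype(int)
    degrees.name = "degree"
    connected = degrees[degrees >= 1]
    return DegreeSummary(
        side=side,
        degrees=degrees,
        n_edges=edges.n_edges,
        n_connected=int((degrees >= 1).sum()),
        mean_connected=float(connected.mean()) if len(connected) else 0.0,
        median_connected=float(connected.median()) if len(connected) else 0.0,
        mean_all=float(degrees.mean()) if len(degrees) else 0.0,
        median_all=float(degrees.median()) if len(degrees) else 0.0,
    )


def compare_distributions(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    Used both for observed-vs-scrambled correlation distributions and for
    degree distributions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
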