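"""Hierarchical clustering of correlation profiles and bipartite module summaries.

Genes of one tissue are clustered by their row (or column) profiles of the
cross-tissue correlation matrix, so genes end up together when they relate
to the *other* tissue in the same way.  Cluster/term pairs are then
summarized by the number of significant edges crossing them and the mean
correlation of those edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .correlation import CrossCorrelationMatrix, EdgeSet

__all__ = [
    "ClusterAssignment",
    "ModuleSummary",
    "cluster_correlation_profiles",
    "bipartite_module_summary",
    "intersect_enriched_modules",
    "plot_correlation_heatmap",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    tissue: str
    gene_to_cluster: pd.Series  # gene id -> cluster id (1..K, contiguous)
    method: str
    metric: str
    cut: str  # human-readable record of the cut parameter

    @property
    def n_clusters(self) -> int:
        return int(self.gene_to_cluster.max()) if len(self.gene_to_cluster) else 0

    def members(self, cluster_id: int) -> set:
        s = self.gene_to_cluster
        return set(s.index[s == cluster_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_to_cluster.index,
                "tissue": self.tissue,
                "cluster_id": self.gene_to_cluster.to_numpy(),
            }
        )


def _contiguous_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids to 1..K in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def cluster_correlation_profiles(
    R: CrossCorrelationMatrix,
    axis: str = "a",
    method: str = "complete",
    metric: str = "euclidean",
    k: Optional[int] = None,
    height: Optional[float] = None,
) -> ClusterAssignment:
    """Agglomeratively cluster one tissue's genes by their correlation profiles.

    ``axis="a"`` clusters rows (genes of ``tissue_a``), ``axis="b"`` columns.
    Undefined entries are imputed as 0 for distance purposes (logged).  The
    tree is cut either at ``k`` clusters or at a ``height``; exactly one must
    be given.  Ties in the agglomeration are broken by scipy's deterministic
    lowest-index rule, so output is reproducible for a given input order.
    """
    if axis == "a":
        profiles = R.r
        genes = R.genes_a
        tissue = R.tissue_a
    elif axis == "b":
        profiles = R.r.T
        genes = R.genes_b
        tissue = R.tissue_b
    else:
        raise ValueError("axis must be 'a' or 'b'")
    if len(genes) < 1:
        raise ValueError("nothing to cluster")
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None and k > len(genes):
        raise ValueError(f"k={k} exceeds the number of genes ({len(genes)})")
    n_nan = int(np.isnan(profiles).sum())
    if n_nan:
        logger.info("imputing %d undefined correlation entries as 0", n_nan)
        profiles = np.nan_to_num(profiles, nan=0.0)
    if len(genes) == 1:
        labels = np.array([1])
    else:
        Z = hierarchy.linkage(pdist(profiles, metric=metric), method=method)
        if k is not None:
            raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        else:
            raw = hierarchy.fcluster(Z, t=height, criterion="distance")
        labels = _contiguous_labels(raw)
    return ClusterAssignment(
        tissue=tissue,
        gene_to_cluster=pd.Series(labels, index=genes, name="cluster_id"),
        method=method,
        metric=metric,
        cut=f"k={k}" if k is not None else f"height={height}",
    )


@dataclass
class ModuleSummary:
    genes_a: frozenset
    genes_b: frozenset
    n_edges: int
    mean_r: Optional[float]  # None when n_edges == 0


def bipartite_module_summary(
    edges: EdgeSet, genes_a: set, genes_b: set
) -> ModuleSummary:
    """Edge count and mean r between two gene sets (one per tissue side)."""
    if not genes_a or not genes_b:
        raise ValueError("gene sets must be non-empty")
    t = edges.table
    mask = t["gene_a"].isin(genes_a) & t["gene_b"].isin(genes_b)
    n = int(mask.sum())
    mean_r = float(t.loc[mask, "r"].mean()) if n else None
    return ModuleSummary(frozenset(genes_a), frozenset(genes_b), n, mean_r)


def intersect_enriched_modules(
    genes_by_term_a: Mapping[str, set],
    genes_by_term_b: Mapping[str, set],
    edges: EdgeSet,
) -> pd.DataFrame:
    """Cross every enriched term of side a with every enriched term of side b.

    ``genes_by_term_*`` map a term id to the genes annotated to it within
    that side's clusters (one entry per distinct term).  Rows with no
    crossing edges are omitted.
    """
    if not genes_by_term_a or not genes_by_term_b:
        raise ValueError("enrichment results required for both sides")
    rows = []
    for term_a, ga in genes_by_term_a.items():
        for term_b, gb in genes_by_term_b.items():
            if not ga or not gb:
                continue
            s = bipartite_module_summary(edges, set(ga), set(gb))
            if s.n_edges == 0:
                continue
            rows.append(
                {
                    "term_a": term_a,
                    "term_b": term_b,
                    "n_edges": s.n_edges,
                    "mean_r": s.mean_r,
                    "genes_a": ";".join(sorted(map(str, ga))),
                    "genes_b": ";".join(sorted(map(str, gb))),
                }
            )
    return pd.DataFrame(
        rows, columns=["term_a", "term_b", "n_edges", "mean_r", "genes_a", "genes_b"]
    )


def plot_correlation_heatmap(
    R: CrossCorrelationMatrix,
    assignment_a: Optional[ClusterAssignment] = None,
    assignment_b: Optional[ClusterAssignment] = None,
    path=None,
):
    """Minimal heatmap of the correlation matrix, rows/columns grouped by cluster."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    r = np.nan_to_num(R.r, nan=0.0)
    if assignment_a is not None:
        order = np.argsort(assignment_a.gene_to_cluster.to_numpy(), kind="stable")
        r = r[order]
    if assignment_b is not None:
        order = np.argsort(assignment_b.gene_to_cluster.to_numpy(), kind="stable")
        r = r[:, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(r, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel(R.tissue_b)
    ax.set_ylabel(R.tissue_a)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
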