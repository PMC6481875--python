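"""High-coexpression gene signatures and dendrogram-equivalence testing.

Given the genes participating in very strong cross-tissue correlations,
each tissue's units (pregnancies) are clustered by 1 - Pearson correlation
of their expression profiles over that tissue's own signature genes, with
complete linkage.  Whether the two unit-level distance structures agree is
tested with a Mantel permutation test; at n = 5 units the exhaustive test
enumerates all 120 relabelings, so the smallest attainable p is
1/120 ~= 0.0083.  The cophenetic correlation between the two trees is
reported as a secondary descriptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from typing import Optional

import numpy as np

from .core import ExpressionMatrix, PairedStudy
from .correlation import CrossCorrelationMatrix

__all__ = [
    "SampleDistanceMatrix",
    "MantelResult",
    "Dendrogram",
    "high_coexpression_gene_sets",
    "sample_distance_matrix",
    "hierarchical_dendrogram",
    "mantel_test",
    "cophenetic_correlation",
    "dendrogram_equivalence",
    "DendrogramEquivalence",
]


def high_coexpression_gene_sets(
    R: CrossCorrelationMatrix, r_threshold: float
) -> tuple[set, set, dict]:
    """Genes of each tissue participating in >= 1 pair with |r| > threshold.

    Returns (set_a, set_b, report) where the report counts genes exclusive
    to each side and lists identifiers appearing on both sides.
    """
    if not 0.0 <= r_threshold < 1.0:
        raise ValueError("r_threshold must lie in [0, 1)")
    with np.errstate(invalid="ignore"):
        hit = np.abs(R.r) > r_threshold
    set_a = set(R.genes_a[hit.any(axis=1)])
    set_b = set(R.genes_b[hit.any(axis=0)])
    shared = sorted(map(str, set_a & set_b))
    report = {
        "tissue_a": R.tissue_a,
        "tissue_b": R.tissue_b,
        "r_threshold": r_threshold,
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_exclusive_a": len(set_a) - len(shared),
        "n_exclusive_b": len(set_b) - len(shared),
        "shared": shared,
    }
    return set_a, set_b, report


@dataclass
class SampleDistanceMatrix:
    """Unit x unit distances, d = 1 - Pearson r of unit expression profiles."""

    unit_ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.unit_ids), len(self.unit_ids)):
            raise ValueError("distance matrix shape does not match unit ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if d.min() < -1e-12 or d.max() > 2 + 1e-12:
            raise ValueError("1 - r distances must lie in [0, 2]")
        self.d = d

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n_units, k=1)
        return self.d[iu]

    def reorder(self, unit_order: list) -> "SampleDistanceMatrix":
        idx = [self.unit_ids.index(u) for u in unit_order]
        return SampleDistanceMatrix(list(unit_order), self.d[np.ix_(idx, idx)])


def sample_distance_matrix(
    m: ExpressionMatrix, gene_subset: Optional[set] = None
) -> SampleDistanceMatrix:
    """1 - correlation distances between units over a gene subset."""
    if gene_subset is not None:
        keep = m.gene_ids.isin(set(gene_subset))
        if keep.sum() < 2:
            raise ValueError(
                f"fewer than 2 genes of tissue {m.tissue!r} in the subset"
            )
        values = m.values[keep]
    else:
        if m.n_genes < 2:
            raise ValueError("need at least 2 genes")
        values = m.values
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [str(m.unit_ids[i]) for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance unit profile(s): {bad}")
    corr = np.corrcoef(values, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return SampleDistanceMatrix(m.unit_ids, d)


@dataclass
class Dendrogram:
    """Agglomerative tree over units, stored as a scipy linkage matrix."""

    unit_ids: list
    linkage: np.ndarray
    method: str

    def cophenetic(self) -> np.ndarray:
        from scipy.cluster.hierarchy import cophenet

        return cophenet(self.linkage)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        from scipy.cluster.hierarchy import to_tree

        tree = to_tree(self.linkage)

        def walk(node, parent_height) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.unit_ids[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        if tree.is_leaf():
            return f"({self.unit_ids[tree.id]}:0);"
        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_dendrogram(
    dm: SampleDistanceMatrix, method: str = "complete"
) -> Dendrogram:
    """Complete-linkage (by default) agglomeration of the unit distances.

    Units are first put in lexicographic id order so that scipy's
    lowest-index tie-break becomes a lexicographic tie-break.
    """
    from scipy.cluster.hierarchy import linkage

    order = sorted(dm.unit_ids, key=str)
    dm_sorted = dm.reorder(order)
    Z = linkage(dm_sorted.condensed(), method=method)
    return Dendrogram(order, Z, method)


@dataclass
class MantelResult:
    statistic: float
    p: float
    n_permutations: int
    exhaustive: bool

    def __post_init__(self) -> None:
        if self.exhaustive and self.p < 1.0 / self.n_permutations - 1e-15:
            raise ValueError("exhaustive p cannot undercut 1/n!")


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc * xc).sum()) * float((yc * yc).sum()))
    if denom == 0:
        raise ValueError("degenerate (constant) distance matrix")
    return float((xc * yc).sum() / denom)


def mantel_test(
    d1: SampleDistanceMatrix,
    d2: SampleDistanceMatrix,
    n_permutations: int = 9999,
    seed: Optional[int] = None,
    exhaustive_limit: int = 5040,
) -> MantelResult:
    """Mantel correlation between two unit distance matrices, one-sided (>=).

    ``d2`` is aligned to ``d1``'s unit order by id.  When ``n_units!`` does
    not exceed ``exhaustive_limit`` all relabelings (identity included) are
    enumerated and ``p = count / n!``; otherwise ``n_permutations`` random
    relabelings give ``p = (count + 1) / (n_permutations + 1)``.
    """
    if set(d1.unit_ids) != set(d2.unit_ids):
        raise ValueError("unit sets differ between the two distance matrices")
    d2 = d2.reorder(d1.unit_ids)
    x = _upper(d1.d)
    observed = _corr(x, _upper(d2.d))
    n = d1.n_units
    n_fact = math.factorial(n)
    if n_fact <= exhaustive_limit:
        count = 0
        for perm in iter_permutations(range(n)):
            stat = _corr(x, _upper(d2.d[np.ix_(perm, perm)]))
            if stat >= observed - 1e-12:
                count += 1
        return MantelResult(observed, count / n_fact, n_fact, True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        stat = _corr(x, _upper(d2.d[np.ix_(perm, perm)]))
        if stat >= observed - 1e-12:
            count += 1
    return MantelResult(
        observed, (count + 1) / (n_permutations + 1), n_permutations, False
    )


def cophenetic_correlation(t1: Dendrogram, t2: Dendrogram) -> float:
    """Pearson correlation of the two trees' cophenetic distances (matched by unit id)."""
    if set(t1.unit_ids) != set(t2.unit_ids):
        raise ValueError("unit sets differ between the two trees")
    from scipy.spatial.distance import squareform

    c1 = squareform(t1.cophenetic())
    idx = [t2.unit_ids.index(u) for u in t1.unit_ids]
    c2 = squareform(t2.cophenetic())[np.ix_(idx, idx)]
    return _corr(_upper(c1), _upper(c2))


@dataclass
class DendrogramEquivalence:
    tree_a: Dendrogram
    tree_b: Dendrogram
    mantel: MantelResult
    cophenetic_r: float


def dendrogram_equivalence(
    study: PairedStudy,
    tissue_a: str,
    tissue_b: str,
    set_a: set,
    set_b: set,
    method: str = "complete",
    n_permutations: int = 9999,
    seed: Optional[int] = None,
    exhaustive_limit: int = 5040,
) -> DendrogramEquivalence:
    """Do two tissues' signature genes order the pregnancies the same way?

    Builds each tissue's unit distance matrix from its own gene set, runs the
    Mantel test between the two, and reports the cophenetic correlation of
    the resulting dendrograms.
    """
    dm_a = sample_distance_matrix(study[tissue_a], set_a)
    dm_b = sample_distance_matrix(study[tissue_b], set_b)
    mantel = mantel_test(
        dm_a, dm_b, n_permutations=n_permutations, seed=seed,
        exhaustive_limit=exhaustive_limit,
    )
    tree_a = hierarchical_dendrogram(dm_a, method)
    tree_b = hierarchical_dendrogram(dm_b, method)
    return DendrogramEquivalence(
        tree_a, tree_b, mantel, cophenetic_correlation(tree_a, tree_b)
    )
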