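"""Gene-set over-representation with BH adjustment and bootstrap validation.

Enrichment of a test gene list is judged against the expressed-gene
background of the same tissue with a one-sided hypergeometric tail; when
per-gene bias weights are supplied (e.g. transcript length), the
noncentral Wallenius variant weights the sampling odds instead.  Raw
p-values are BH-adjusted across the gene sets tested.  A bootstrap then
asks how often a *random* test list of the same size achieves a lower FDR
for each set: the reported bootstrap probability is the proportion of
randomized rounds whose FDR is strictly lower than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "enrichment_test",
    "bh_adjust",
    "bootstrap_enrichment_validation",
    "results_to_frame",
]


@dataclass
class GeneSetCollection:
    """Named gene sets: set id -> (description, member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {set_id!r} has duplicate members")

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def members(self, set_id: str) -> set:
        return set(self.sets[set_id][1])

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set id <tab> description <tab> member genes...)."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: need id, description, >=1 gene")
            set_id, desc = parts[0], parts[1]
            members = tuple(dict.fromkeys(g for g in parts[2:] if g))
            if set_id in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size_in_background: int
    n_test: int
    n_background: int
    p: float
    fdr: float
    bootstrap_probability: Optional[float] = None


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _bh_columns(p: np.ndarray) -> np.ndarray:
    """Vectorized BH over the columns of an (m x rounds) p-value matrix.

    Equivalent to applying :func:`bh_adjust` per column; used on the
    bootstrap path where thousands of rounds are adjusted at once.
    """
    m, rounds = p.shape
    order = np.argsort(p, axis=0)
    ranked = np.take_along_axis(p, order, axis=0)
    scaled = ranked * (m / np.arange(1, m + 1)[:, None])
    adj = np.minimum.accumulate(scaled[::-1], axis=0)[::-1]
    np.clip(adj, 0.0, 1.0, out=adj)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=0)
    return out


def _hypergeom_p(overlap, n_background, set_size, n_test):
    """Upper-tail P(X >= overlap) for the central hypergeometric law."""
    return stats.hypergeom.sf(np.asarray(overlap) - 1, n_background, set_size, n_test)


def enrichment_test(
    test_genes: set,
    background: set,
    collection: GeneSetCollection,
    bias_weights: Optional[Mapping[str, float]] = None,
) -> list[EnrichmentResult]:
    """One-sided over-representation of ``test_genes`` within ``background``.

    Sets with no background intersection are skipped.  With ``bias_weights``
    the Wallenius noncentral hypergeometric tail is used, the odds being the
    mean weight of in-set background genes over the mean weight of the rest.
    """
    test_genes = set(test_genes)
    background = set(background)
    if not test_genes:
        raise ValueError("test gene set is empty")
    if len(background) < 2:
        raise ValueError("background needs at least 2 genes")
    stray = sorted(map(str, test_genes - background))
    if stray:
        raise ValueError(f"test genes absent from background: {stray}")
    N = len(background)
    n = len(test_genes)
    results = []
    for set_id in collection.set_ids:
        members_bg = collection.members(set_id) & background
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & test_genes)
        if bias_weights is None:
            p = float(_hypergeom_p(k, N, K, n))
        else:
            w = {g: float(bias_weights[g]) for g in background}
            w_in = np.mean([w[g] for g in members_bg])
            rest = background - members_bg
            w_out = np.mean([w[g] for g in rest]) if rest else w_in
            odds = w_in / w_out
            if abs(odds - 1.0) < 1e-12:
                p = float(_hypergeom_p(k, N, K, n))
            else:
                p = float(stats.nchypergeom_wallenius.sf(k - 1, N, K, n, odds))
        p = min(1.0, max(p, np.nextafter(0, 1)))
        results.append(
            EnrichmentResult(set_id, k, K, n, N, p, fdr=np.nan)
        )
    fdrs = bh_adjust([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results


def bootstrap_enrichment_validation(
    observed: Sequence[EnrichmentResult],
    n_test_genes: int,
    background: set,
    collection: GeneSetCollection,
    rounds: int = 2000,
    seed: Optional[int] = None,
) -> dict[str, float]:
    """Probability that a random test list of the same size beats each set's FDR.

    For each round, ``n_test_genes`` genes are drawn uniformly without
    replacement from the background and the enrichment + BH procedure is
    rerun; the bootstrap probability of a set is the proportion of rounds
    whose FDR for that set is strictly lower than the observed FDR.  A value
    of 0.0 means no round beat the observation (report as "< 1/rounds").
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    bg = sorted(map(str, background))
    N = len(bg)
    if n_test_genes > N:
        raise ValueError("n_test_genes exceeds the background size")
    observed_by_id = {r.set_id: r for r in observed}
    set_ids = [s for s in collection.set_ids if s in observed_by_id]
    if not set_ids:
        raise ValueError("no observed results match the collection")
    bg_index = {g: i for i, g in enumerate(bg)}
    membership = np.zeros((len(set_ids), N), dtype=np.float64)
    for row, set_id in enumerate(set_ids):
        idx = [bg_index[g] for g in collection.members(set_id) if g in bg_index]
        membership[row, idx] = 1.0
    K = membership.sum(axis=1).astype(int)
    rng = np.random.default_rng(seed)
    overlaps = np.empty((len(set_ids), rounds), dtype=np.int64)
    for b in range(rounds):
        draw = rng.choice(N, size=n_test_genes, replace=False)
        indicator = np.zeros(N)
        indicator[draw] = 1.0
        overlaps[:, b] = (membership @ indicator).astype(np.int64)
    p = _hypergeom_p(overlaps, N, K[:, None], n_test_genes)
    np.clip(p, np.nextafter(0, 1), 1.0, out=p)
    fdr = _bh_columns(p)
    out: dict[str, float] = {}
    for row, set_id in enumerate(set_ids):
        obs_fdr = observed_by_id[set_id].fdr
        out[set_id] = float(np.mean(fdr[row] < obs_fdr))
    return out


def results_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "overlap": r.overlap,
                "set_size_in_background": r.set_size_in_background,
                "n_test": r.n_test,
                "n_background": r.n_background,
                "p": r.p,
                "fdr": r.fdr,
                "bootstrap_probability": r.bootstrap_probability,
            }
            for r in results
        ]
    )
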