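"""Scrambled-pairing null and the empirical FDR (eFDR) curve.

Significance of observed cross-tissue correlations is judged against a null
built by permuting the unit (pregnancy) index of ONE tissue, which breaks
the biological pairing while leaving each tissue's expression profiles
intact.  For B sampled non-identity permutations the full cross-correlation
matrix is recomputed, and the eFDR at a threshold t is the smoothed null
tail proportion

    eFDR(t) = (#{ scrambled |r| >= t } + 1) / (pair_count * B + 1),

a non-increasing function of t with floor 1/(pair_count*B + 1).  Undefined
(zero-variance) pairs are excluded on both the observed and the scrambled
side, and the effective defined-pair count replaces j*k in the denominator.

An optional classical "ratio" variant (mean null exceedance count divided by
the observed exceedance count) is provided for users expecting an FDR in the
discoveries-denominated sense; the tail-proportion form above is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice, permutations
from typing import Optional, Sequence

import numpy as np

from .core import PairedStudy
from .correlation import EdgeSet, standardize_rows

__all__ = [
    "PermutationNull",
    "EFDRCurve",
    "scramble_pairing",
    "null_correlations",
    "null_tail_counts",
    "efdr_curve",
    "efdr_curve_from_counts",
    "threshold_for_efdr",
    "efdr_at",
    "reoccurrence_rate",
    "default_threshold_grid",
    "ratio_efdr",
]


def default_threshold_grid() -> np.ndarray:
    """0.00..1.00 step 0.01 plus the usual high operating points."""
    grid = np.round(np.arange(0, 101) / 100.0, 2)
    return np.unique(np.concatenate([grid, [0.95, 0.99, 0.999, 0.9999]]))


@dataclass
class PermutationNull:
    """B distinct non-identity unit permutations applied to one tissue."""

    permutations: list[tuple[int, ...]]
    permuted_tissue: str
    B: int
    seed: Optional[int]
    unit_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.unit_ids) if self.unit_ids else (
            len(self.permutations[0]) if self.permutations else 0
        )
        identity = tuple(range(n))
        seen = set()
        for p in self.permutations:
            if p == identity:
                raise ValueError("the identity permutation does not break pairing")
            if p in seen:
                raise ValueError("permutations must be pairwise distinct")
            seen.add(p)
        if len(self.permutations) != self.B:
            raise ValueError("B does not match the number of permutations")

    def as_unit_sequences(self) -> list[list]:
        """Permutations expressed as unit-id sequences (for the log)."""
        return [[self.unit_ids[i] for i in p] for p in self.permutations]


def _sample_permutations(
    n: int, B: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    n_fact = math.factorial(n)
    if B > n_fact - 1:
        raise ValueError(
            f"B={B} exceeds the number of non-identity permutations "
            f"of {n} units ({n_fact - 1})"
        )
    identity = tuple(range(n))
    if n_fact <= 50_000:
        pool = [p for p in permutations(range(n)) if p != identity]
        idx = rng.choice(len(pool), size=B, replace=False)
        return [pool[i] for i in idx]
    # large n: rejection-sample distinct non-identity permutations
    chosen: list[tuple[int, ...]] = []
    seen = set()
    while len(chosen) < B:
        p = tuple(rng.permutation(n).tolist())
        if p == identity or p in seen:
            continue
        seen.add(p)
        chosen.append(p)
    return chosen


def scramble_pairing(
    study: PairedStudy, permuted_tissue: str, B: int, seed: Optional[int] = None
) -> PermutationNull:
    """Sample B distinct non-identity unit permutations for one tissue.

    Sampling is uniform without replacement; with ``B = n_units! - 1`` the
    enumeration is exhaustive, so two seeds then yield the same set.
    """
    if permuted_tissue not in study.matrices:
        raise ValueError(f"tissue {permuted_tissue!r} not in study")
    rng = np.random.default_rng(seed)
    perms = _sample_permutations(study.n_units, B, rng)
    return PermutationNull(perms, permuted_tissue, B, seed, list(study.pairing))


def _standardized_pair(study: PairedStudy, permuted_tissue: str, other_tissue: str):
    for t in (permuted_tissue, other_tissue):
        if t not in study.matrices:
            raise ValueError(f"tissue {t!r} not in study")
    sa = standardize_rows(study[permuted_tissue].values)
    sb = standardize_rows(study[other_tissue].values)
    return sa[~np.isnan(sa[:, 0])], sb[~np.isnan(sb[:, 0])]


def null_correlations(
    study: PairedStudy,
    permuted_tissue: str,
    other_tissue: str,
    null: PermutationNull,
) -> np.ndarray:
    """Pooled absolute correlations from all B scrambled matrices.

    Zero-variance genes are dropped before pooling, so the pool holds
    ``defined_pairs * B`` values.  For very large studies prefer
    :func:`null_tail_counts`, which streams counts instead of pooling.
    """
    sa, sb = _standardized_pair(study, permuted_tissue, other_tissue)
    pools = []
    for p in null.permutations:
        r = sa[:, list(p)] @ sb.T
        np.clip(np.abs(r, out=r), 0.0, 1.0, out=r)
        pools.append(r.ravel())
    return np.concatenate(pools) if pools else np.empty(0)


def null_tail_counts(
    study: PairedStudy,
    permuted_tissue: str,
    other_tissue: str,
    null: PermutationNull,
    thresholds: Sequence[float],
) -> tuple[np.ndarray, int]:
    """Streaming version of the pooled null: counts of |r| >= t per threshold.

    Returns ``(counts, total)`` where ``total = defined_pairs * B``; memory
    stays at one scrambled matrix regardless of B.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    sa, sb = _standardized_pair(study, permuted_tissue, other_tissue)
    edges = np.concatenate([thresholds, [np.inf]])
    counts = np.zeros(len(thresholds), dtype=np.int64)
    total = 0
    for p in null.permutations:
        r = sa[:, list(p)] @ sb.T
        np.clip(np.abs(r, out=r), 0.0, 1.0, out=r)
        hist, _ = np.histogram(r.ravel(), bins=edges)
        counts += hist[::-1].cumsum()[::-1]
        total += r.size
    return counts, total


@dataclass
class EFDRCurve:
    """Empirical FDR as a function of the |r| threshold."""

    thresholds: np.ndarray
    efdr: np.ndarray
    pair_count: int
    B: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.efdr = np.asarray(self.efdr, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if np.any(np.diff(self.efdr) > 0):
            raise ValueError("eFDR must be non-increasing in the threshold")
        floor = 1.0 / (self.pair_count * self.B + 1)
        if self.efdr.min() < floor - 1e-15 or self.efdr.max() > 1 + 1e-15:
            raise ValueError("eFDR values outside [floor, 1]")

    @property
    def floor(self) -> float:
        return 1.0 / (self.pair_count * self.B + 1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"threshold": self.thresholds, "efdr": self.efdr})


def efdr_curve(
    null_abs_r: np.ndarray,
    pair_count: int,
    B: int,
    thresholds: Optional[Sequence[float]] = None,
) -> EFDRCurve:
    """eFDR(t) = (#{null |r| >= t} + 1) / (pair_count*B + 1) over a grid."""
    null_abs_r = np.asarray(null_abs_r, dtype=float)
    if null_abs_r.size == 0:
        raise ValueError("empty null pool")
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    pool = np.sort(null_abs_r)
    # count of values >= t  ==  N - first index where pool >= t
    counts = pool.size - np.searchsorted(pool, thresholds, side="left")
    efdr = (counts + 1.0) / (pair_count * B + 1.0)
    return EFDRCurve(thresholds, efdr, pair_count, B)


def efdr_curve_from_counts(
    tail_counts: np.ndarray,
    pair_count: int,
    B: int,
    thresholds: Sequence[float],
) -> EFDRCurve:
    """Build the curve from streamed tail counts (see :func:`null_tail_counts`)."""
    efdr = (np.asarray(tail_counts, dtype=float) + 1.0) / (pair_count * B + 1.0)
    return EFDRCurve(np.asarray(thresholds, dtype=float), efdr, pair_count, B)


def threshold_for_efdr(curve: EFDRCurve, target: float) -> Optional[float]:
    """Smallest grid threshold with eFDR <= target, or None if unattainable."""
    if not 0 < target <= 1:
        raise ValueError("target must lie in (0, 1]")
    ok = np.nonzero(curve.efdr <= target)[0]
    if ok.size == 0:
        return None
    return float(curve.thresholds[ok[0]])


def efdr_at(curve: EFDRCurve, t: float) -> float:
    """eFDR at the largest grid threshold <= t (step-function lookup)."""
    idx = np.searchsorted(curve.thresholds, t, side="right") - 1
    if idx < 0:
        raise ValueError(f"threshold {t} below the grid")
    return float(curve.efdr[idx])


def ratio_efdr(
    observed_abs_r: np.ndarray,
    null_abs_r: np.ndarray,
    B: int,
    t: float,
) -> float:
    """Classical variant: (null exceedances / B) / observed exceedances.

    Provided for users expecting an FDR denominated in discoveries; not used
    by the default pipeline.
    """
    n_obs = int((np.abs(observed_abs_r) >= t).sum())
    if n_obs == 0:
        return float("nan")
    n_null = int((np.asarray(null_abs_r) >= t).sum())
    return min(1.0, (n_null / B) / n_obs)


def reoccurrence_rate(
    study: PairedStudy,
    edges: EdgeSet,
    null: PermutationNull,
    r_threshold: float,
) -> tuple[np.ndarray, float]:
    """How often observed-significant pairs stay significant after scrambling.

    For each permutation, the fraction of the edge pairs whose scrambled |r|
    exceeds ``r_threshold``; returns the per-permutation vector and its mean.
    """
    if edges.n_edges == 0:
        raise ValueError("edge set is empty")
    a = study[null.permuted_tissue]
    other = edges.tissue_b if edges.tissue_a == null.permuted_tissue else edges.tissue_a
    b = study[other]
    if edges.tissue_a == null.permuted_tissue:
        genes_perm, genes_fix = edges.table["gene_a"], edges.table["gene_b"]
    else:
        genes_perm, genes_fix = edges.table["gene_b"], edges.table["gene_a"]
    sa = standardize_rows(a.values)[a.gene_ids.get_indexer(genes_perm)]
    sb = standardize_rows(b.values)[b.gene_ids.get_indexer(genes_fix)]
    rates = np.empty(len(null.permutations))
    for i, p in enumerate(null.permutations):
        r = (sa[:, list(p)] * sb).sum(axis=1)
        with np.errstate(invalid="ignore"):
            rates[i] = np.mean(np.abs(r) > r_threshold)
    return rates, float(rates.mean())
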