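"""Synthetic paired multi-tissue expression studies with planted coexpression.

The generator emulates the structure of a paired day-18 pregnancy study:
a small number of biological units (pregnancies) sampled in several tissues,
with cross-tissue coexpression produced by unit-level latent factors.

Generative model (log2 scale)
-----------------------------
Each module ``d`` owns one latent factor ``u_i ~ N(0, 1)`` per unit ``i``,
shared by every tissue.  A module gene ``g`` in tissue ``t`` has

    log2 x_gi = alpha_g + s_t * beta_g * u_i + eps_gi,
    eps_gi ~ N(0, noise_sd^2)

with ``|beta_g|`` drawn uniformly from ``loading_range``.  For a
*negative* module the sign ``s_t`` is +1 in the first tissue and -1 in every
other tissue, so cross-tissue correlations are negative while the module
stays coherent within each endometrial compartment.  Null genes are
``alpha_g + eps_gi`` with independent noise.  On the log2 scale the expected
cross-tissue correlation of two genes in one module is

    rho = s * beta_1 * beta_2 / sqrt((beta_1^2 + sd^2)(beta_2^2 + sd^2)).

Values are exponentiated (base 2) to an FPKM-like positive, right-skewed
scale unless ``log2_scale`` is set, in which case the log2 matrix is emitted
directly (planted correlations are exact there, approximate after
exponentiation).  A configurable fraction of the null genes is generated
below the expression filter (baseline well under FPKM 1) to exercise
filtering.  All randomness flows through one ``numpy.random.Generator``
(PCG64), so a fixed seed reproduces the study byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, PairedStudy

__all__ = [
    "SimulationConfig",
    "generate_paired_study",
    "write_truth_table",
    "read_truth_table",
    "module_gene_ids",
]

TRUTH_COLUMNS = ["gene_id", "tissue", "module_id", "loading", "baseline"]


@dataclass
class SimulationConfig:
    """Conditions for one synthetic paired study.

    Defaults reproduce the structure of the motivating study: 3 tissues
    (extraembryonic, caruncular, intercaruncular) x 5 paired pregnancies,
    ~12,000 genes per tissue of which ~10,000 pass the FPKM > 1 in >= 4
    units filter.
    """

    n_units: int = 5
    tissues: Sequence[str] = ("EET", "CAR", "ICAR")
    n_modules: int = 20
    genes_per_module_per_tissue: int = 25
    loading_range: tuple[float, float] = (0.5, 1.0)
    negative_fraction: float = 0.3
    noise_sd: float = 0.5
    n_null_genes_per_tissue: int = 11500
    subthreshold_fraction: float = 0.15
    log2_scale: bool = False
    unit_prefix: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("n_units must be >= 3")
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")
        if self.n_modules < 0 or self.genes_per_module_per_tissue < 0:
            raise ValueError("counts must be >= 0")
        if self.n_null_genes_per_tissue < 0:
            raise ValueError("counts must be >= 0")
        total = (
            self.n_modules * self.genes_per_module_per_tissue
            + self.n_null_genes_per_tissue
        )
        if total == 0:
            raise ValueError("configuration generates zero genes")
        for frac in (self.negative_fraction, self.subthreshold_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.loading_range
        if not 0 <= lo <= hi:
            raise ValueError("loading_range must satisfy 0 <= lo <= hi")

    @property
    def n_negative_modules(self) -> int:
        return int(round(self.n_modules * self.negative_fraction))

    def module_is_negative(self, d: int) -> bool:
        """Modules are assigned signs deterministically: the first ones flip."""
        return d < self.n_negative_modules


def module_gene_ids(cfg: SimulationConfig, tissue: str, module: int) -> list[str]:
    """Gene ids planted in ``module`` (0-based) for ``tissue``."""
    return [
        f"{tissue}_M{module:02d}_{g:03d}"
        for g in range(cfg.genes_per_module_per_tissue)
    ]


def generate_paired_study(
    cfg: SimulationConfig,
) -> tuple[PairedStudy, pd.DataFrame]:
    """Generate one paired study plus its ground-truth table.

    Returns the study and a truth table with one row per (gene, tissue):
    ``gene_id, tissue, module_id`` (``"null"`` for independent genes),
    signed ``loading`` and log2 ``baseline``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_units
    units = [f"{cfg.unit_prefix}{i + 1}" for i in range(n)]

    # latent unit-level factors, one per module, shared by all tissues
    factors = rng.standard_normal((cfg.n_modules, n))

    matrices: dict[str, ExpressionMatrix] = {}
    truth_rows: list[tuple] = []
    for t_idx, tissue in enumerate(cfg.tissues):
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for d in range(cfg.n_modules):
            sign = -1.0 if (cfg.module_is_negative(d) and t_idx > 0) else 1.0
            ids = module_gene_ids(cfg, tissue, d)
            n_g = len(ids)
            beta = rng.uniform(*cfg.loading_range, size=n_g) * sign
            alpha = rng.normal(3.0, 2.0, size=n_g)
            eps = rng.normal(0.0, cfg.noise_sd, size=(n_g, n))
            rows.append(alpha[:, None] + beta[:, None] * factors[d] + eps)
            gene_ids.extend(ids)
            for g in range(n_g):
                truth_rows.append(
                    (ids[g], tissue, f"M{d:02d}", beta[g], alpha[g])
                )
        n_null = cfg.n_null_genes_per_tissue
        if n_null:
            ids = [f"{tissue}_N{g:05d}" for g in range(n_null)]
            n_sub = int(round(cfg.subthreshold_fraction * n_null))
            alpha = rng.normal(3.0, 2.0, size=n_null)
            if n_sub:
                # baselines far below FPKM 1 so the expression filter drops them
                alpha[:n_sub] = rng.uniform(-6.0, -2.0, size=n_sub)
            eps = rng.normal(0.0, cfg.noise_sd, size=(n_null, n))
            rows.append(alpha[:, None] + eps)
            gene_ids.extend(ids)
            for g in range(n_null):
                truth_rows.append((ids[g], tissue, "null", 0.0, alpha[g]))
        log2_values = np.vstack(rows)
        values = log2_values if cfg.log2_scale else np.exp2(log2_values)
        df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=units)
        matrices[tissue] = ExpressionMatrix(
            tissue, df, scale="log2" if cfg.log2_scale else "fpkm"
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return PairedStudy(matrices, units), truth


def expected_module_correlation(
    beta_1: float, beta_2: float, noise_sd: float
) -> float:
    """Expected log2-scale cross-tissue correlation of two genes sharing a factor."""
    s2 = noise_sd**2
    return beta_1 * beta_2 / np.sqrt((beta_1**2 + s2) * (beta_2**2 + s2))


def write_truth_table(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table as TSV (lossless round trip)."""
    if truth.shape[0] == 0:
        raise ValueError("truth table is empty")
    truth.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=[],
        dtype={"gene_id": str, "tissue": str, "module_id": str},
    )
    df["loading"] = df["loading"].astype(float)
    df["baseline"] = df["baseline"].astype(float)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return df[TRUTH_COLUMNS]
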