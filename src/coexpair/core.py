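"""Data model and I/O for paired multi-tissue expression studies.

A study consists of one genes x units expression matrix per tissue, where
the units are biological pairing keys (here: pregnancies) shared across
tissues.  Values are on the FPKM scale unless a matrix is explicitly marked
as log2.  Pairing is always by unit *identifier*, never by column position,
so reordered or scrambled input files are safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "PairedStudy",
    "read_expression_table",
    "write_expression_table",
    "filter_expressed",
    "align_paired_study",
    "load_study_manifest",
]


@dataclass
class ExpressionMatrix:
    """Genes x units expression matrix for one tissue.

    Parameters
    ----------
    tissue:
        Short tissue label (e.g. ``"EET"``, ``"CAR"``).
    data:
        DataFrame indexed by gene id with one column per unit id.
    scale:
        ``"fpkm"`` (default; values must be non-negative) or ``"log2"``
        (log2 of FPKM-like values; may be negative).
    """

    tissue: str
    data: pd.DataFrame
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("fpkm", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate unit ids: {dups}")
        if len(cols) < 3:
            raise ValueError(f"need at least 3 units, got {len(cols)}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {idx[r]!r}, unit {cols[c]!r}"
            )
        if self.scale == "fpkm" and values.size and values.min() < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {idx[r]!r}, unit {cols[c]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def unit_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def reorder_units(self, unit_order: Sequence) -> "ExpressionMatrix":
        """Return a copy with columns in ``unit_order`` (must be the same set)."""
        if set(unit_order) != set(self.data.columns):
            raise ValueError("unit_order is not a permutation of the unit ids")
        return ExpressionMatrix(self.tissue, self.data.loc[:, list(unit_order)], self.scale)


@dataclass
class PairedStudy:
    """A set of per-tissue expression matrices sharing one unit (pregnancy) index."""

    matrices: dict[str, ExpressionMatrix]
    pairing: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValueError("a paired study needs at least 2 tissues")
        for tissue, m in self.matrices.items():
            if m.unit_ids != list(self.pairing):
                raise ValueError(
                    f"tissue {tissue!r} unit order {m.unit_ids} does not match "
                    f"the shared pairing {list(self.pairing)}"
                )

    @property
    def tissues(self) -> list[str]:
        return list(self.matrices)

    @property
    def n_units(self) -> int:
        return len(self.pairing)

    def __getitem__(self, tissue: str) -> ExpressionMatrix:
        return self.matrices[tissue]


def read_expression_table(path, tissue_label: str, scale: str = "fpkm") -> ExpressionMatrix:
    """Read a tab-separated expression table (first column gene ids, header unit ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric cell at gene {gene!r}, unit {col!r}"
            )
    df.index = df.index.astype(str)
    return ExpressionMatrix(tissue_label, df.astype(float), scale=scale)


def write_expression_table(m: ExpressionMatrix, path) -> None:
    """Write the matrix as the TSV dialect read by :func:`read_expression_table`."""
    out = m.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def filter_expressed(
    m: ExpressionMatrix, min_level: float = 1.0, min_units: int = 4
) -> ExpressionMatrix:
    """Keep genes with expression strictly above ``min_level`` in >= ``min_units`` units.

    This is the standard expressed-gene filter for FPKM matrices
    (default: FPKM > 1 in at least 4 samples).  The unit set and the order
    of surviving genes are unchanged; the filter is idempotent.
    """
    if min_units > m.n_units:
        raise ValueError(
            f"min_units={min_units} exceeds the number of units ({m.n_units})"
        )
    keep = (m.data.to_numpy() > min_level).sum(axis=1) >= min_units
    if not keep.any():
        warnings.warn(
            f"filter_expressed removed every gene of tissue {m.tissue!r}",
            stacklevel=2,
        )
    out = ExpressionMatrix(m.tissue, m.data.loc[keep], m.scale)
    return out


def align_paired_study(matrices: Iterable[ExpressionMatrix]) -> PairedStudy:
    """Reorder all matrices to one canonical unit order and record the pairing.

    The canonical order is the first matrix's unit order.  All matrices must
    share the same *set* of unit ids; a mismatch raises with the symmetric
    difference.
    """
    mats = list(matrices)
    if len(mats) < 2:
        raise ValueError("need at least 2 tissues to build a paired study")
    pairing = mats[0].unit_ids
    ref = set(pairing)
    aligned: dict[str, ExpressionMatrix] = {}
    for m in mats:
        diff = ref.symmetric_difference(m.unit_ids)
        if diff:
            raise ValueError(
                f"unit sets differ between {mats[0].tissue!r} and {m.tissue!r}: "
                f"symmetric difference {sorted(map(str, diff))}"
            )
        if m.tissue in aligned:
            raise ValueError(f"duplicate tissue label {m.tissue!r}")
        aligned[m.tissue] = m.reorder_units(pairing)
    return PairedStudy(aligned, pairing)


def load_study_manifest(path) -> PairedStudy:
    """Load a study from a YAML manifest: a list of ``{tissue, path}`` entries.

    Relative paths are resolved against the manifest's directory.  An optional
    top-level ``unit_order`` overrides the canonical order.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    entries = manifest["tissues"] if isinstance(manifest, dict) else manifest
    mats = []
    for entry in entries:
        p = Path(entry["path"])
        if not p.is_absolute():
            p = path.parent / p
        mats.append(read_expression_table(p, entry["tissue"]))
    study = align_paired_study(mats)
    if isinstance(manifest, dict) and manifest.get("unit_order"):
        order = [str(u) for u in manifest["unit_order"]]
        study = PairedStudy(
            {t: m.reorder_units(order) for t, m in study.matrices.items()}, order
        )
    return study
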