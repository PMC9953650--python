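"""Expression-table I/O, unit conversion, pseudobulk aggregation and
expressed-gene extraction.

The central container is :class:`ExpressionMatrix`, a gene × sample table of
non-negative values carrying a unit tag (counts, TPM, FPKM or RPKM), a species
identifier and a sample → organ labelling.  All downstream stages (homolog
screening, projection, overlap partitioning, QC) consume this type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "GeneLengths",
    "CellCountMatrix",
    "read_expression_table",
    "read_organ_map",
    "read_lengths",
    "read_cell_counts",
    "counts_to_tpm",
    "counts_to_fpkm",
    "pseudobulk",
    "expressed_genes",
    "aggregate_by_organ",
]

#: Relative tolerance for the TPM column-sum invariant.
_TPM_RTOL = 1e-6


class Unit(str, Enum):
    """Expression scale tag.

    FPKM and RPKM share one formula and are distinguished by tag only.
    """

    COUNTS = "counts"
    TPM = "tpm"
    FPKM = "fpkm"
    RPKM = "rpkm"

    @classmethod
    def parse(cls, text: str | "Unit") -> "Unit":
        if isinstance(text, Unit):
            return text
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown expression unit {text!r}; expected one of "
                f"{[u.value for u in cls]}"
            ) from None


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with unit, species and organ labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id (rows) with sample ids as columns.
    unit
        Expression scale of ``values``.
    species
        Free-form species identifier.
    organ_of
        Mapping from every sample id to an organ label.
    """

    values: pd.DataFrame
    unit: Unit
    species: str = ""
    organ_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unit = Unit.parse(self.unit)
        self.values = self.values.astype(float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite and numeric")
        if (arr < 0).any():
            raise ValueError("negative expression values are not allowed")
        missing = [s for s in v.columns if s not in self.organ_of]
        if missing:
            raise ValueError(f"samples without an organ label: {missing}")
        if self.unit is Unit.TPM and v.shape[0] > 0:
            sums = arr.sum(axis=0)
            bad = ~np.isclose(sums, 1e6, rtol=_TPM_RTOL, atol=0.0)
            if bad.any():
                samples = v.columns[bad].tolist()
                raise ValueError(
                    f"TPM columns must sum to 1e6 (rel tol {_TPM_RTOL}); "
                    f"violated by samples {samples[:5]}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def organs(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.organ_of[s], None)
        return list(seen)

    def samples_of_organ(self, organ: str) -> list[str]:
        out = [s for s in self.values.columns if self.organ_of[s] == organ]
        if not out:
            raise KeyError(f"unknown organ label {organ!r} "
                           f"(known: {self.organs})")
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneLengths:
    """Effective transcript (exon) length per gene, in bases."""

    length_of: dict[str, int]

    def __post_init__(self) -> None:
        bad = {g: l for g, l in self.length_of.items() if l <= 0}
        if bad:
            raise ValueError(f"non-positive gene lengths: {dict(list(bad.items())[:5])}")

    def vector_for(self, genes: Iterable[str]) -> np.ndarray:
        genes = list(genes)
        missing = [g for g in genes if g not in self.length_of]
        if missing:
            raise KeyError(f"genes without a length: {missing[:5]} "
                           f"({len(missing)} total)")
        return np.array([self.length_of[g] for g in genes], dtype=float)


@dataclass
class CellCountMatrix:
    """Gene × cell-barcode integer count matrix (single-cell)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("cell counts must be finite")
        if (arr < 0).any():
            raise ValueError("negative cell counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("cell counts must be integers")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicated gene ids in cell matrix")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_organ_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>organ`` table (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" in cols and "organ" in cols:
        df.columns = cols
    else:
        # headerless: first row was data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["sample_id", "organ"])
    if df.shape[1] < 2:
        raise ValueError(f"organ map {path} must have two columns")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicated sample ids in organ map {path}")
    return dict(zip(df["sample_id"], df["organ"]))


def read_expression_table(
    path: str | Path,
    unit: str | Unit,
    species: str = "",
    organ_map_path: str | Path | None = None,
    organ_of: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression table (first column gene ids, header sample ids).

    Exactly one of ``organ_map_path`` / ``organ_of`` supplies sample → organ
    labels.  Duplicated gene ids, negative or non-numeric cells and unlabelled
    samples are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if organ_map_path is not None:
        labels = read_organ_map(organ_map_path)
    elif organ_of is not None:
        labels = dict(organ_of)
    else:
        raise ValueError("an organ map is required")
    return ExpressionMatrix(values=df, unit=Unit.parse(unit),
                            species=species, organ_of=labels)


def read_lengths(path: str | Path) -> GeneLengths:
    """Read a ``gene_id<TAB>length_bp`` table."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if "gene_id" in cols and "length_bp" in cols:
        df.columns = cols
        pairs = zip(df["gene_id"], df["length_bp"])
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length_bp"],
                         dtype={0: str})
        pairs = zip(df["gene_id"], df["length_bp"])
    return GeneLengths({g: int(l) for g, l in pairs})


def read_cell_counts(path: str | Path) -> CellCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellCountMatrix(df.astype(float))


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def _require_counts(m: ExpressionMatrix) -> None:
    if m.unit is not Unit.COUNTS:
        raise ValueError(f"expected a counts matrix, got unit {m.unit.value!r}")


def _check_nonzero_columns(m: ExpressionMatrix) -> None:
    sums = m.values.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero count column(s): {zero}; "
                         "normalization undefined")


def counts_to_tpm(m: ExpressionMatrix, lengths: GeneLengths) -> ExpressionMatrix:
    """Convert raw counts to TPM using effective transcript lengths.

    Per column: ``TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j)``.  Every
    output column sums to 1e6.
    """
    _require_counts(m)
    _check_nonzero_columns(m)
    L = lengths.vector_for(m.genes)
    rate = m.values.to_numpy() / L[:, None]
    tpm = 1e6 * rate / rate.sum(axis=0, keepdims=True)
    out = pd.DataFrame(tpm, index=m.genes, columns=m.samples)
    return ExpressionMatrix(out, Unit.TPM, m.species, dict(m.organ_of))


def counts_to_fpkm(
    m: ExpressionMatrix, lengths: GeneLengths, tag: Unit = Unit.FPKM
) -> ExpressionMatrix:
    """Convert raw counts to FPKM (or RPKM under that tag; same formula).

    Per column: ``FPKM_g = 1e9 * c_g / (L_g * N)`` with ``N`` the column sum.
    """
    if tag not in (Unit.FPKM, Unit.RPKM):
        raise ValueError("tag must be FPKM or RPKM")
    _require_counts(m)
    _check_nonzero_columns(m)
    L = lengths.vector_for(m.genes)
    c = m.values.to_numpy()
    N = c.sum(axis=0, keepdims=True)
    fpkm = 1e9 * c / (L[:, None] * N)
    out = pd.DataFrame(fpkm, index=m.genes, columns=m.samples)
    return ExpressionMatrix(out, tag, m.species, dict(m.organ_of))


def pseudobulk(
    cells: CellCountMatrix, sample_id: str = "pseudobulk",
    organ: str = "pseudobulk", species: str = ""
) -> ExpressionMatrix:
    """Sum single-cell counts per gene into one bulk-like counts column."""
    if cells.counts.shape[1] == 0:
        raise ValueError("cell matrix has no cells")
    sums = cells.counts.sum(axis=1)
    out = sums.to_frame(name=sample_id)
    return ExpressionMatrix(out, Unit.COUNTS, species, {sample_id: organ})


# ---------------------------------------------------------------------------
# Expressed genes
# ---------------------------------------------------------------------------

ALL_ORGANS = "ALL"
_RULES = ("mean", "any", "all")


def aggregate_by_organ(m: ExpressionMatrix, organ: str) -> pd.Series:
    """Mean expression over an organ's replicate samples (per gene)."""
    return m.values[m.samples_of_organ(organ)].mean(axis=1)


def expressed_genes(
    m: ExpressionMatrix,
    threshold: float,
    organ: str = ALL_ORGANS,
    rule: str = "mean",
) -> set[str]:
    """Genes strictly above ``threshold`` over the selected samples.

    ``rule`` controls replicate handling: ``mean`` thresholds the sample mean,
    ``any``/``all`` threshold per sample and combine.  Thresholds are strict
    (boundary values excluded).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}")
    if organ == ALL_ORGANS:
        sub = m.values
    else:
        sub = m.values[m.samples_of_organ(organ)]
    if rule == "mean":
        mask = sub.mean(axis=1) > threshold
    elif rule == "any":
        mask = (sub > threshold).any(axis=1)
    else:
        mask = (sub > threshold).all(axis=1)
    return set(sub.index[mask])
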