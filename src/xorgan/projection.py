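"""OSG projection onto a target organ panel and atlas-based similarity index.

Two per-organ statistics are computed through homolog maps:

* **similarity ratio** — of the focal organ's OSGs with a target-species
  homolog, the fraction whose homolog is expressed (strictly above a TPM
  threshold, default 1) in each target organ;
* **similarity index** — for each atlas tissue's enriched-gene set, the
  fraction whose focal-species homolog is expressed strictly above a
  threshold (default FPKM 5) in the focal organ.

Tissue-enriched sets follow an inclusive fold rule: a gene belongs to tissue
``t`` when its expression there is at least ``fold`` times (default 4) the
maximum over every other tissue, and at least ``floor`` (default 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix, Unit, aggregate_by_organ
from .homology import HomologMap
from .specificity import OSGResult

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityProfile",
    "TissueEnrichedSets",
    "SimilarityIndexProfile",
    "DenominatorMode",
    "similarity_ratio",
    "call_tissue_enriched",
    "similarity_index",
]


class DenominatorMode(str, Enum):
    MAPPED = "mapped"
    FULL_SET = "full_set"


@dataclass
class SimilarityProfile:
    """Per-organ expressed-homolog ratios with explicit counts."""

    ratio_of: dict[str, float]
    expressed_count_of: dict[str, int]
    mapped_total: int
    threshold: float
    unit: Unit

    def __post_init__(self) -> None:
        for organ, r in self.ratio_of.items():
            k = self.expressed_count_of[organ]
            if not 0 <= k <= self.mapped_total:
                raise ValueError(f"count out of range for {organ}")
            if not math.isclose(r, k / self.mapped_total):
                raise ValueError(f"ratio inconsistent with counts for {organ}")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"organ_or_tissue": o, "ratio_or_index": r,
             "numerator": self.expressed_count_of[o],
             "denominator": self.mapped_total}
            for o, r in self.ratio_of.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class TissueEnrichedSets:
    """Per-tissue enriched gene sets under the max-versus-rest fold rule.

    Disjoint by construction: a gene can dominate at most one tissue.
    """

    sets: dict[str, set[str]]
    fold: float = 4.0
    floor: float = 1.0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tissue, genes in self.sets.items():
            overlap = seen & genes
            if overlap:
                raise ValueError(
                    f"gene(s) enriched in more than one tissue: "
                    f"{sorted(overlap)[:5]}")
            seen |= genes

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tissue in self.sets:
                genes = "\t".join(sorted(self.sets[tissue]))
                fh.write(f"{tissue}\tenriched>= {self.fold}x\t{genes}\n")


@dataclass
class SimilarityIndexProfile:
    """Per-tissue positive-homolog fractions; missing denominators omitted."""

    index_of: dict[str, float | None]
    positive_count_of: dict[str, int]
    denominator_of: dict[str, int]
    denominator_mode: DenominatorMode
    threshold: float = 5.0

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for tissue, idx in self.index_of.items():
            rows.append({
                "organ_or_tissue": tissue,
                "ratio_or_index": "" if idx is None else idx,
                "numerator": self.positive_count_of[tissue],
                "denominator": self.denominator_of[tissue],
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def ranked(self) -> list[tuple[str, float]]:
        pairs = [(t, i) for t, i in self.index_of.items() if i is not None]
        return sorted(pairs, key=lambda p: (-p[1], p[0]))


def similarity_ratio(
    osgs: OSGResult | list[str],
    map_to_target: HomologMap,
    target: ExpressionMatrix,
    threshold: float = 1.0,
) -> SimilarityProfile:
    """Fraction of mapped OSG homologs expressed in each target organ.

    The denominator is the number of OSGs with a target homolog; OSGs
    without one are excluded (not counted as unexpressed).
    """
    if target.unit is not Unit.TPM:
        logger.warning("target matrix unit is %s, expected TPM",
                       target.unit.value)
    osg_ids = osgs.osgs if isinstance(osgs, OSGResult) else list(osgs)
    mapped = [(g, map_to_target[g]) for g in osg_ids if g in map_to_target]
    if not mapped:
        raise ValueError("no OSG has a target homolog; ratio undefined")
    n = len(mapped)
    ratio_of: dict[str, float] = {}
    count_of: dict[str, int] = {}
    for organ in target.organs:
        expr = aggregate_by_organ(target, organ)
        k = sum(1 for _, h in mapped
                if h in expr.index and float(expr[h]) > threshold)
        count_of[organ] = k
        ratio_of[organ] = k / n
    return SimilarityProfile(ratio_of, count_of, n, threshold, target.unit)


def call_tissue_enriched(
    atlas: ExpressionMatrix,
    fold: float = 4.0,
    floor: float = 1.0,
) -> TissueEnrichedSets:
    """Classify atlas genes as tissue-enriched under the fold rule.

    ``atlas`` must carry one consensus column per tissue.  Gene ``g`` is
    enriched in tissue ``t`` iff ``expr(g,t) >= fold * max_other`` and
    ``expr(g,t) >= floor``; when every other tissue is 0 only the floor
    applies.  Both comparisons are inclusive.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if atlas.values.shape[1] < 2:
        raise ValueError("atlas needs at least two tissues")
    vals = atlas.values.to_numpy()
    tissues = list(atlas.samples)
    order = np.argsort(vals, axis=1)
    top_idx = order[:, -1]
    rows = np.arange(vals.shape[0])
    top = vals[rows, top_idx]
    second = vals[rows, order[:, -2]]
    enriched = (top >= floor) & ((second == 0) | (top >= fold * second))
    sets: dict[str, set[str]] = {t: set() for t in tissues}
    genes = np.asarray(atlas.genes)
    for gi in np.nonzero(enriched)[0]:
        sets[tissues[top_idx[gi]]].add(str(genes[gi]))
    return TissueEnrichedSets(sets=sets, fold=fold, floor=floor)


def similarity_index(
    enriched: TissueEnrichedSets,
    map_to_focal: HomologMap,
    focal: ExpressionMatrix,
    focal_organ: str,
    threshold: float = 5.0,
    denominator_mode: DenominatorMode = DenominatorMode.MAPPED,
) -> SimilarityIndexProfile:
    """Per-tissue fraction of enriched-gene homologs expressed in the focal organ.

    Positives are enriched genes whose focal homolog is strictly above
    ``threshold``.  The denominator is either the mapped-enriched count
    (default) or the full enriched-set size.  Tissues with a zero
    denominator get ``None`` (missing), never 0.
    """
    if focal.unit not in (Unit.FPKM, Unit.RPKM):
        logger.warning("focal matrix unit is %s, expected FPKM",
                       focal.unit.value)
    expr = aggregate_by_organ(focal, focal_organ)
    index_of: dict[str, float | None] = {}
    pos_of: dict[str, int] = {}
    den_of: dict[str, int] = {}
    mode = DenominatorMode(denominator_mode)
    for tissue, genes in enriched.sets.items():
        mapped = {g: map_to_focal[g] for g in genes if g in map_to_focal}
        pos = sum(1 for h in mapped.values()
                  if h in expr.index and float(expr[h]) > threshold)
        den = len(mapped) if mode is DenominatorMode.MAPPED else len(genes)
        pos_of[tissue] = pos
        den_of[tissue] = den
        index_of[tissue] = (pos / den) if den > 0 else None
    return SimilarityIndexProfile(index_of, pos_of, den_of, mode, threshold)
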