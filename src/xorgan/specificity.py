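"""Organ-specific gene (OSG) calling.

A focal gene is an OSG of the focal organ when (i) it has a homolog in the
reference species, (ii) that homolog stays at or below a ceiling
(default 0.5) in every non-excluded reference organ, and (iii) the focal
gene itself is strictly above a floor (default 1.0) in the focal organ.
Both thresholds are strict ("larger than"), so boundary values fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exprio import ExpressionMatrix, aggregate_by_organ
from .homology import HomologMap

logger = logging.getLogger(__name__)

__all__ = ["OSGConfig", "OSGEvidence", "OSGResult", "call_osgs"]


@dataclass
class OSGConfig:
    reference_max: float = 0.5
    focal_min: float = 1.0
    excluded_reference_organs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.reference_max < 0:
            raise ValueError("reference_max must be non-negative")
        if self.focal_min <= 0:
            raise ValueError("focal_min must be positive")
        self.excluded_reference_organs = frozenset(self.excluded_reference_organs)


@dataclass(frozen=True)
class OSGEvidence:
    focal_expr: float
    max_ref_expr: float
    ref_organ_of_max: str
    reference_gene: str


@dataclass
class OSGResult:
    """Ordered OSG list (descending focal expression) with per-gene evidence.

    ``unscreened`` holds focal genes that had no homolog and therefore could
    not be screened against the reference panel; ``n_candidates`` and
    ``n_eliminated`` record the screening bookkeeping.
    """

    osgs: list[str]
    evidence: dict[str, OSGEvidence]
    config: OSGConfig
    unscreened: list[str] = field(default_factory=list)
    n_candidates: int = 0
    n_eliminated: int = 0

    def __post_init__(self) -> None:
        missing = [g for g in self.osgs if g not in self.evidence]
        if missing:
            raise ValueError(f"OSGs without evidence: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.osgs)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "gene_id": g,
                "reference_gene": e.reference_gene,
                "focal_expr": e.focal_expr,
                "max_ref_expr": e.max_ref_expr,
                "ref_organ_of_max": e.ref_organ_of_max,
            }
            for g in self.osgs
            for e in (self.evidence[g],)
        ]
        pd.DataFrame(
            rows,
            columns=["gene_id", "reference_gene", "focal_expr",
                     "max_ref_expr", "ref_organ_of_max"],
        ).to_csv(path, sep="\t", index=False)


def call_osgs(
    focal: ExpressionMatrix,
    focal_organ: str,
    reference: ExpressionMatrix,
    homolog_map: HomologMap,
    cfg: OSGConfig | None = None,
) -> OSGResult:
    """Call OSGs of ``focal_organ`` against the reference organ panel.

    Candidates are the focal genes present in ``homolog_map``.  A candidate
    is eliminated when its reference homolog's replicate-mean expression is
    strictly above ``cfg.reference_max`` in any non-excluded reference organ;
    survivors are kept when the focal-organ replicate mean is strictly above
    ``cfg.focal_min``.  Raw scales are compared directly; mixing units
    (e.g. FPKM focal vs RPKM reference) logs a warning but proceeds.
    """
    cfg = cfg or OSGConfig()
    if len(homolog_map) == 0:
        raise ValueError("homolog map is empty; no candidates to screen")
    # triggers KeyError with known organs if absent
    focal.samples_of_organ(focal_organ)
    if focal.unit is not reference.unit:
        logger.warning(
            "comparing mixed units without conversion: focal=%s reference=%s",
            focal.unit.value, reference.unit.value)

    ref_organs = [o for o in reference.organs
                  if o not in cfg.excluded_reference_organs]
    ref_agg = pd.DataFrame(
        {o: aggregate_by_organ(reference, o) for o in ref_organs})
    focal_expr = aggregate_by_organ(focal, focal_organ)

    candidates = [g for g in focal.genes if g in homolog_map]
    n_eliminated = 0
    kept: list[tuple[str, OSGEvidence]] = []
    for g in candidates:
        ref_gene = homolog_map[g]
        if ref_gene in ref_agg.index and ref_organs:
            ref_vals = ref_agg.loc[ref_gene]
            max_ref = float(ref_vals.max())
            organ_of_max = str(ref_vals.idxmax())
        else:
            # homolog absent from the reference table: nothing measured
            # above the ceiling, so it survives elimination
            max_ref = 0.0
            organ_of_max = ""
        if max_ref > cfg.reference_max:
            n_eliminated += 1
            continue
        fx = float(focal_expr.get(g, 0.0))
        if fx > cfg.focal_min:
            kept.append((g, OSGEvidence(fx, max_ref, organ_of_max, ref_gene)))

    kept.sort(key=lambda t: (-t[1].focal_expr, t[0]))
    unscreened = [g for g in focal.genes if g not in homolog_map]
    return OSGResult(
        osgs=[g for g, _ in kept],
        evidence=dict(kept),
        config=cfg,
        unscreened=unscreened,
        n_candidates=len(candidates),
        n_eliminated=n_eliminated,
    )
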