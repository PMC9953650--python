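"""Shared / organ-only expressed-gene partitions and over-representation tests.

``partition_expressed`` splits the expressed genes of two organs into
shared homolog pairs and single-organ remainders through an injective
homolog map.  ``enrich`` is a self-contained over-representation test:
one-sided hypergeometric upper tail per annotation term, Benjamini–Hochberg
adjusted across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .homology import HomologMap, MapMode

__all__ = [
    "OverlapPartition",
    "AnnotationSets",
    "EnrichmentRow",
    "partition_expressed",
    "read_gmt",
    "enrich",
    "bh_adjust",
]


@dataclass
class OverlapPartition:
    shared_pairs: list[tuple[str, str]]
    focal_only: set[str]
    reference_only: set[str]
    expression_threshold: float = 1.0

    def __post_init__(self) -> None:
        shared_focal = {a for a, _ in self.shared_pairs}
        shared_ref = {b for _, b in self.shared_pairs}
        if len(shared_focal) != len(self.shared_pairs):
            raise ValueError("focal gene repeated in shared pairs")
        if len(shared_ref) != len(self.shared_pairs):
            raise ValueError("reference gene repeated in shared pairs")
        if shared_focal & self.focal_only:
            raise ValueError("gene in both shared and focal_only")
        if shared_ref & self.reference_only:
            raise ValueError("gene in both shared and reference_only")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared_pairs),
            "focal_only": len(self.focal_only),
            "reference_only": len(self.reference_only),
        }

    def write(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        with open(prefix + "shared_pairs.tsv", "w", encoding="utf-8") as fh:
            fh.write("focal_gene\treference_gene\n")
            for a, b in sorted(self.shared_pairs):
                fh.write(f"{a}\t{b}\n")
        for name, genes in (("focal_only", self.focal_only),
                            ("reference_only", self.reference_only)):
            with open(f"{prefix}{name}.txt", "w", encoding="utf-8") as fh:
                fh.write("\n".join(sorted(genes)) + ("\n" if genes else ""))
        pd.DataFrame([self.counts]).to_csv(
            prefix + "summary.tsv", sep="\t", index=False)


def partition_expressed(
    focal_expressed: set[str],
    reference_expressed: set[str],
    homolog_map: HomologMap,
    expression_threshold: float = 1.0,
) -> OverlapPartition:
    """Partition two expressed-gene sets via an injective homolog map.

    A pair is shared iff both sides are expressed; everything else expressed
    lands in its species' `only` set (including unmapped genes).
    """
    if homolog_map.mode is MapMode.BEST_HIT:
        refs = list(homolog_map.pairs.values())
        if len(refs) != len(set(refs)):
            raise ValueError(
                "partition requires an injective map (unique or reciprocal); "
                "this best-hit map has many-to-one collisions")
    shared = [
        (a, homolog_map[a])
        for a in sorted(focal_expressed)
        if a in homolog_map and homolog_map[a] in reference_expressed
    ]
    shared_f = {a for a, _ in shared}
    shared_r = {b for _, b in shared}
    return OverlapPartition(
        shared_pairs=shared,
        focal_only=focal_expressed - shared_f,
        reference_only=reference_expressed - shared_r,
        expression_threshold=expression_threshold,
    )


@dataclass
class AnnotationSets:
    """Term id → (description, gene set); GMT-style annotation."""

    descriptions: dict[str, str]
    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty annotation sets: {empty[:5]}")


def read_gmt(path: str | Path) -> AnnotationSets:
    """Read GMT: one term per line — id, description, tab-separated genes."""
    descriptions: dict[str, str] = {}
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicated term {term!r}")
            geneset = {g for g in genes if g}
            if not geneset:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            descriptions[term] = desc
            sets[term] = geneset
    return AnnotationSets(descriptions=descriptions, sets=sets)


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    description: str
    k: int  # overlap of query with term set
    K: int  # term-set size within background
    n: int  # query size
    N: int  # background size
    p: float
    q: float


def bh_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, preserving input order.

    ``q_(i) = min_{j>=i} min(1, p_(j) * m / j)`` on the sorted scale.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query: set[str],
    annotation: AnnotationSets,
    background: set[str],
    min_term_size: int = 3,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation across annotation terms.

    Term sets are intersected with the background first; terms with fewer
    than ``min_term_size`` background genes are skipped.  Rows are sorted by
    ascending p (ties by term id); q is BH across all tested terms.
    """
    if not background:
        raise ValueError("background is empty")
    if not query:
        raise ValueError("query is empty")
    if not query <= background:
        extra = sorted(query - background)
        raise ValueError(f"query genes outside background: {extra[:5]}")
    N = len(background)
    n = len(query)
    tested: list[tuple[str, int, int, float]] = []
    for term, genes in annotation.sets.items():
        term_bg = genes & background
        K = len(term_bg)
        if K < min_term_size:
            continue
        k = len(term_bg & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        # guard float underflow at extreme tails; p must stay in (0, 1]
        p = min(1.0, max(p, np.finfo(float).tiny))
        tested.append((term, k, K, p))
    if not tested:
        return []
    pvals = [t[3] for t in tested]
    qvals = bh_adjust(pvals)
    rows = [
        EnrichmentRow(term=term, description=annotation.descriptions.get(term, ""),
                      k=k, K=K, n=n, N=N, p=p, q=float(q))
        for (term, k, K, p), q in zip(tested, qvals)
    ]
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def enrichment_to_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, sep="\t", index=False)
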