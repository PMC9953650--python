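"""One-to-one homolog maps from pairwise protein-alignment hit tables.

Hit tables are 12-column tab-separated files (the common tabular alignment
dialect: query, subject, identity, length, mismatches, gap opens, qstart,
qend, sstart, send, e-value, bitscore).  Three map modes are supported:
one-way best hit, best hit restricted to an injective (unique) pairing, and
reciprocal (mutual) best hit between two directed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

__all__ = [
    "AlignmentHit",
    "MapMode",
    "HomologMap",
    "parse_hits",
    "best_hit_map",
    "restrict_unique",
    "reciprocal_map",
    "read_map",
]


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    pct_identity: float
    align_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.align_len <= 0:
            raise ValueError("align_len must be positive")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.bitscore <= 0:
            raise ValueError("bitscore must be positive")


class MapMode(str, Enum):
    BEST_HIT = "best_hit"
    UNIQUE = "unique"
    RECIPROCAL = "reciprocal"


@dataclass
class HomologMap:
    """Focal → reference gene correspondence with retained-hit bitscores."""

    pairs: dict[str, str]
    mode: MapMode
    score_of: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in self.pairs if g not in self.score_of]
        if missing:
            raise ValueError(f"pairs without a recorded score: {missing[:5]}")
        if self.mode in (MapMode.UNIQUE, MapMode.RECIPROCAL):
            refs = list(self.pairs.values())
            if len(refs) != len(set(refs)):
                raise ValueError(
                    f"{self.mode.value} map must be injective on reference ids")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, gene: str) -> bool:
        return gene in self.pairs

    def __getitem__(self, gene: str) -> str:
        return self.pairs[gene]

    def inverse(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs.items()}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("focal_gene\treference_gene\tbitscore\tmode\n")
            for a, b in sorted(self.pairs.items()):
                fh.write(f"{a}\t{b}\t{self.score_of[a]:g}\t{self.mode.value}\n")


def parse_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12+-column tabular alignment file; `#` lines are comments.

    Malformed rows raise with their line number; an empty file yields [].
    """
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                hits.append(AlignmentHit(
                    query=parts[0],
                    subject=parts[1],
                    pct_identity=float(parts[2]),
                    align_len=int(parts[3]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    return hits


def _hit_rank(h: AlignmentHit) -> tuple:
    # higher bitscore, then lower evalue, then higher identity, then
    # lexicographically smallest subject id — fully deterministic.
    return (-h.bitscore, h.evalue, -h.pct_identity, h.subject)


def best_hit_map(
    hits: list[AlignmentHit],
    exclude_self: bool = True,
    min_bitscore: float = 0.0,
    max_evalue: float | None = None,
) -> HomologMap:
    """Retain the top hit per query (bitscore, then e-value, identity, id)."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if exclude_self and h.query == h.subject:
            continue
        if h.bitscore < min_bitscore:
            continue
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        cur = best.get(h.query)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query] = h
    return HomologMap(
        pairs={q: h.subject for q, h in best.items()},
        mode=MapMode.BEST_HIT,
        score_of={q: h.bitscore for q, h in best.items()},
    )


def restrict_unique(m: HomologMap) -> HomologMap:
    """Resolve many-to-one collisions, keeping the highest-scoring pair.

    Ties on bitscore fall to the lexicographically smallest focal gene so the
    result is deterministic.  Idempotent; output is injective.
    """
    if m.mode is MapMode.RECIPROCAL:
        raise ValueError("reciprocal maps are already injective")
    by_ref: dict[str, list[str]] = {}
    for a, b in m.pairs.items():
        by_ref.setdefault(b, []).append(a)
    pairs: dict[str, str] = {}
    scores: dict[str, float] = {}
    for b, focals in by_ref.items():
        winner = min(focals, key=lambda a: (-m.score_of[a], a))
        pairs[winner] = b
        scores[winner] = m.score_of[winner]
    return HomologMap(pairs=pairs, mode=MapMode.UNIQUE, score_of=scores)


def reciprocal_map(
    hits_ab: list[AlignmentHit],
    hits_ba: list[AlignmentHit],
    exclude_self: bool = True,
) -> HomologMap:
    """Mutual-best-hit pairing from two directed hit tables."""
    fwd = best_hit_map(hits_ab, exclude_self=exclude_self)
    rev = best_hit_map(hits_ba, exclude_self=exclude_self)
    pairs = {a: b for a, b in fwd.pairs.items() if rev.pairs.get(b) == a}
    return HomologMap(
        pairs=pairs,
        mode=MapMode.RECIPROCAL,
        score_of={a: fwd.score_of[a] for a in pairs},
    )


def read_map(path: str | Path) -> HomologMap:
    """Read a map written by :meth:`HomologMap.to_tsv`."""
    pairs: dict[str, str] = {}
    scores: dict[str, float] = {}
    mode = MapMode.BEST_HIT
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("focal_gene"):
            raise ValueError(f"{path}: missing homolog-map header")
        for line in fh:
            if not line.strip():
                continue
            a, b, score, mode_s = line.rstrip("\n").split("\t")
            pairs[a] = b
            scores[a] = float(score)
            mode = MapMode(mode_s)
    return HomologMap(pairs=pairs, mode=mode, score_of=scores)
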