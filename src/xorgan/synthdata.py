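"""Synthetic two-species organ-expression datasets with planted ground truth.

The generator emits four expression matrices (focal organ with replicates,
reference organ panel, target organ panel, tissue atlas), one-to-one homolog
maps between the species, tabular alignment hits that round-trip through the
homology module, and a :class:`SimTruth` record holding everything an
acceptance test needs to verify recovery:

* planted organ-specific genes, built to clear the calling thresholds with a
  configurable margin (focal high, every reference organ low);
* non-planted mapped genes, built to fail the thresholds (either focal too
  low or some reference organ too high);
* per-target-organ expressed fractions — each mapped planted homolog is
  drawn expressed independently with the configured probability, and the
  realized draw is recorded;
* per-tissue enriched sets satisfying the fold rule at a margin.

All randomness flows from one integer-seeded generator; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix, GeneLengths, Unit
from .homology import AlignmentHit

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_dataset",
           "simulate_hits", "write_hits", "simulate_counts"]

_DEFAULT_REFERENCE_ORGANS = [
    "oral_siphon", "atrial_siphon", "neural_complex", "heart", "ovary",
    "pharynx", "stomach", "proximal_intestine", "middle_intestine",
    "distal_intestine", "body_wall",
]
_DEFAULT_TARGET_ORGANS = [
    "gill", "head_kidney", "brain", "tail", "spleen", "skin", "muscle",
    "liver", "heart", "thymus", "thyroid", "eye",
]


def _default_atlas_tissues() -> list[str]:
    return [f"tissue_{i:02d}" for i in range(1, 28)]


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Margins must respect the calling thresholds they are planted around:
    ``focal_high_range[0]`` must exceed ``focal_min`` and
    ``reference_low_max`` must stay below ``reference_max``.
    """

    n_genes_focal: int = 6000
    n_genes_reference: int = 6000
    n_genes_target: int = 6000
    focal_organ: str = "focal_organ"
    n_focal_replicates: int = 3
    reference_organs: list[str] = field(
        default_factory=lambda: list(_DEFAULT_REFERENCE_ORGANS))
    target_organs: list[str] = field(
        default_factory=lambda: list(_DEFAULT_TARGET_ORGANS))
    atlas_tissues: list[str] = field(default_factory=_default_atlas_tissues)
    ortholog_fraction: float = 0.6
    target_mapped_fraction: float = 1.0
    atlas_mapped_fraction: float = 0.9
    n_planted_osgs: int = 150
    meanlog: float = 1.0
    sdlog: float = 1.0
    focal_high_range: tuple[float, float] = (5.0, 50.0)
    reference_low_max: float = 0.3
    # thresholds the margins are validated against (the calling defaults)
    focal_min: float = 1.0
    reference_max: float = 0.5
    expressed_fraction_of: dict[str, float] | None = None
    expressed_fraction_default: float = 0.5
    n_enriched_per_tissue: int = 50
    n_atlas_background: int = 1000
    enrichment_fold_margin: float = 6.0
    enrichment_fold: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focal_high_range[0] <= self.focal_min:
            raise ValueError(
                "focal_high_range minimum must exceed focal_min "
                f"({self.focal_high_range[0]} <= {self.focal_min})")
        if self.reference_low_max >= self.reference_max:
            raise ValueError(
                "reference_low_max must stay below reference_max "
                f"({self.reference_low_max} >= {self.reference_max})")
        if self.enrichment_fold_margin < self.enrichment_fold:
            raise ValueError("enrichment_fold_margin below the fold rule")
        if not 0 < self.ortholog_fraction <= 1:
            raise ValueError("ortholog_fraction must lie in (0, 1]")
        fractions = self.expressed_fraction_of or {}
        for organ, f in fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"expressed fraction out of [0,1] for {organ}")
            if organ not in self.target_organs:
                raise ValueError(f"unknown target organ {organ!r}")
        n_mappable = int(round(self.ortholog_fraction * self.n_genes_focal))
        if self.n_planted_osgs > n_mappable:
            raise ValueError("more planted OSGs than mappable focal genes")

    def fraction_for(self, organ: str) -> float:
        if self.expressed_fraction_of and organ in self.expressed_fraction_of:
            return self.expressed_fraction_of[organ]
        return self.expressed_fraction_default


@dataclass
class SimTruth:
    """Ground-truth record: the oracle every recovery test reads."""

    planted_osg_ids: set[str]
    map_focal_reference: dict[str, str]
    map_focal_target: dict[str, str]
    map_atlas_focal: dict[str, str]
    expressed_fraction_of: dict[str, float]
    realized_expressed: dict[str, set[str]]  # target organ -> focal OSG ids
    enriched_sets: dict[str, set[str]]
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_osg_ids": sorted(self.planted_osg_ids),
            "map_focal_reference": self.map_focal_reference,
            "map_focal_target": self.map_focal_target,
            "map_atlas_focal": self.map_atlas_focal,
            "expressed_fraction_of": self.expressed_fraction_of,
            "realized_expressed": {o: sorted(g)
                                   for o, g in self.realized_expressed.items()},
            "enriched_sets": {t: sorted(g)
                              for t, g in self.enriched_sets.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_osg_ids=set(d["planted_osg_ids"]),
            map_focal_reference=d["map_focal_reference"],
            map_focal_target=d["map_focal_target"],
            map_atlas_focal=d["map_atlas_focal"],
            expressed_fraction_of=d["expressed_fraction_of"],
            realized_expressed={o: set(g)
                                for o, g in d["realized_expressed"].items()},
            enriched_sets={t: set(g) for t, g in d["enriched_sets"].items()},
            seed=d.get("seed", 0),
        )


@dataclass
class SimDataset:
    focal: ExpressionMatrix
    reference: ExpressionMatrix
    target: ExpressionMatrix
    atlas: ExpressionMatrix
    hits_focal_reference: list[AlignmentHit]
    hits_focal_target: list[AlignmentHit]
    hits_atlas_focal: list[AlignmentHit]
    truth: SimTruth


def _noisy(rng: np.random.Generator, values: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return values
    return values * rng.lognormal(mean=0.0, sigma=sd, size=values.shape)


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate the full synthetic dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)

    focal_genes = [f"SC_g{i:06d}" for i in range(cfg.n_genes_focal)]
    ref_genes = [f"CR_g{i:06d}" for i in range(cfg.n_genes_reference)]
    target_genes = [f"DR_g{i:06d}" for i in range(cfg.n_genes_target)]

    # --- orthology: one-to-one partial maps -----------------------------
    n_map = int(round(cfg.ortholog_fraction * cfg.n_genes_focal))
    n_map = min(n_map, cfg.n_genes_reference)
    mapped_focal = sorted(rng.choice(cfg.n_genes_focal, size=n_map,
                                     replace=False))
    ref_partners = rng.choice(cfg.n_genes_reference, size=n_map, replace=False)
    map_fr = {focal_genes[i]: ref_genes[j]
              for i, j in zip(mapped_focal, ref_partners)}

    planted_idx = rng.choice(len(mapped_focal), size=cfg.n_planted_osgs,
                             replace=False)
    planted = {focal_genes[mapped_focal[i]] for i in planted_idx}
    nonplanted_mapped = [g for g in map_fr if g not in planted]

    # --- focal matrix (FPKM, replicated focal organ) --------------------
    base_focal = rng.lognormal(cfg.meanlog, cfg.sdlog, size=cfg.n_genes_focal)
    focal_col = pd.Series(base_focal, index=focal_genes)
    lo, hi = cfg.focal_high_range
    focal_col[sorted(planted)] = rng.uniform(lo, hi, size=len(planted))
    # non-planted mapped genes must fail at least one OSG condition:
    # half are silenced in the focal organ, half stay expressed but get a
    # hot reference organ (below)
    silent = np.asarray(
        rng.random(len(nonplanted_mapped)) < 0.5)
    silenced_genes = [g for g, s in zip(nonplanted_mapped, silent) if s]
    hot_ref_genes = [g for g, s in zip(nonplanted_mapped, silent) if not s]
    focal_col[silenced_genes] = rng.uniform(
        0.0, 0.5 * cfg.focal_min, size=len(silenced_genes))

    focal_samples = [f"focal_rep{i+1}" for i in range(cfg.n_focal_replicates)]
    focal_vals = pd.DataFrame(
        {s: _noisy(rng, focal_col.to_numpy(), cfg.noise_sd)
         for s in focal_samples},
        index=focal_genes)
    focal = ExpressionMatrix(
        focal_vals, Unit.FPKM, species="focal",
        organ_of={s: cfg.focal_organ for s in focal_samples})

    # --- reference matrix (RPKM, one sample per organ) ------------------
    ref_vals = pd.DataFrame(
        rng.lognormal(cfg.meanlog, cfg.sdlog,
                      size=(cfg.n_genes_reference, len(cfg.reference_organs))),
        index=ref_genes, columns=[f"ref_{o}" for o in cfg.reference_organs])
    planted_ref = sorted(map_fr[g] for g in planted)
    ref_vals.loc[planted_ref] = rng.uniform(
        0.0, cfg.reference_low_max,
        size=(len(planted_ref), len(cfg.reference_organs)))
    # genes paired to focal-expressed non-planted genes: one hot organ each
    hot_ref_ids = [map_fr[g] for g in hot_ref_genes]
    hot_organ = rng.integers(0, len(cfg.reference_organs),
                             size=len(hot_ref_ids))
    hot_vals = rng.uniform(2.0 * cfg.reference_max, 10.0,
                           size=len(hot_ref_ids))
    for gid, oi, v in zip(hot_ref_ids, hot_organ, hot_vals):
        ref_vals.iloc[ref_vals.index.get_loc(gid), oi] = v
    ref_vals = pd.DataFrame(_noisy(rng, ref_vals.to_numpy(), cfg.noise_sd),
                            index=ref_vals.index, columns=ref_vals.columns)
    reference = ExpressionMatrix(
        ref_vals, Unit.RPKM, species="reference",
        organ_of={f"ref_{o}": o for o in cfg.reference_organs})

    # --- target matrix (TPM) with planted expressed fractions -----------
    n_target_map = int(round(cfg.target_mapped_fraction * len(planted)))
    planted_sorted = sorted(planted)
    target_mapped_osgs = [planted_sorted[i] for i in sorted(
        rng.choice(len(planted_sorted), size=n_target_map, replace=False))]
    target_partner_idx = rng.choice(cfg.n_genes_target, size=n_target_map,
                                    replace=False)
    map_ft = {g: target_genes[j]
              for g, j in zip(target_mapped_osgs, target_partner_idx)}

    fractions = {o: cfg.fraction_for(o) for o in cfg.target_organs}
    target_cols = {}
    realized: dict[str, set[str]] = {}
    planted_positions = {target_genes[j]: j for j in target_partner_idx}
    for organ in cfg.target_organs:
        col = rng.lognormal(cfg.meanlog, cfg.sdlog, size=cfg.n_genes_target)
        f = fractions[organ]
        draws = rng.random(n_target_map) < f
        realized[organ] = {g for g, d in zip(target_mapped_osgs, draws) if d}
        expr_vals = rng.uniform(5.0, 50.0, size=n_target_map)
        silent_vals = rng.uniform(0.0, 0.3, size=n_target_map)
        for g, d, ev, sv in zip(target_mapped_osgs, draws, expr_vals,
                                silent_vals):
            col[planted_positions[map_ft[g]]] = ev if d else sv
        col = _noisy(rng, col, cfg.noise_sd)
        # rescale only non-planted genes so the column sums to exactly 1e6
        # while the planted values (and their threshold margins) stay put
        mask = np.ones(cfg.n_genes_target, dtype=bool)
        mask[list(planted_positions.values())] = False
        planted_sum = col[~mask].sum()
        rest_sum = col[mask].sum()
        if planted_sum >= 1e6 or rest_sum <= 0:
            raise ValueError("cannot normalize target column to TPM scale")
        col[mask] *= (1e6 - planted_sum) / rest_sum
        target_cols[f"tgt_{organ}"] = col
    target = ExpressionMatrix(
        pd.DataFrame(target_cols, index=target_genes),
        Unit.TPM, species="target",
        organ_of={f"tgt_{o}": o for o in cfg.target_organs})

    # --- atlas with planted enriched sets -------------------------------
    tissues = cfg.atlas_tissues
    n_enr = cfg.n_enriched_per_tissue * len(tissues)
    atlas_genes = [f"HS_g{i:06d}" for i in range(n_enr + cfg.n_atlas_background)]
    atlas_vals = np.zeros((len(atlas_genes), len(tissues)))
    enriched_sets: dict[str, set[str]] = {t: set() for t in tissues}
    row = 0
    for ti, tissue in enumerate(tissues):
        for _ in range(cfg.n_enriched_per_tissue):
            others = rng.uniform(0.1, 2.0, size=len(tissues))
            peak = cfg.enrichment_fold_margin * others.max()
            others[ti] = max(peak, 1.0)
            atlas_vals[row] = others
            enriched_sets[tissue].add(atlas_genes[row])
            row += 1
    # background genes: top two tissues tied, so no tissue dominates
    for _ in range(cfg.n_atlas_background):
        vals = rng.uniform(1.0, 5.0, size=len(tissues))
        a, b = rng.choice(len(tissues), size=2, replace=False)
        high = rng.uniform(8.0, 12.0)
        vals[a] = high
        vals[b] = high
        atlas_vals[row] = vals
        row += 1
    atlas = ExpressionMatrix(
        pd.DataFrame(atlas_vals, index=atlas_genes, columns=tissues),
        Unit.FPKM,  # consensus abundance scale
        species="atlas",
        organ_of={t: t for t in tissues})

    # --- atlas -> focal homologs ----------------------------------------
    enriched_all = [g for t in tissues for g in sorted(enriched_sets[t])]
    n_am = int(round(cfg.atlas_mapped_fraction * len(enriched_all)))
    chosen = sorted(rng.choice(len(enriched_all), size=n_am, replace=False))
    focal_partner_idx = rng.choice(cfg.n_genes_focal, size=n_am, replace=False)
    map_af = {enriched_all[i]: focal_genes[j]
              for i, j in zip(chosen, focal_partner_idx)}

    truth = SimTruth(
        planted_osg_ids=planted,
        map_focal_reference=map_fr,
        map_focal_target=map_ft,
        map_atlas_focal=map_af,
        expressed_fraction_of=fractions,
        realized_expressed=realized,
        enriched_sets=enriched_sets,
        seed=cfg.seed,
    )
    hit_seed = int(rng.integers(0, 2 ** 31))
    return SimDataset(
        focal=focal, reference=reference, target=target, atlas=atlas,
        hits_focal_reference=simulate_hits(map_fr, n_decoys=3,
                                           seed=hit_seed),
        hits_focal_target=simulate_hits(map_ft, n_decoys=3,
                                        seed=hit_seed + 1),
        hits_atlas_focal=simulate_hits(map_af, n_decoys=3,
                                       seed=hit_seed + 2),
        truth=truth,
    )


def simulate_hits(
    true_map: dict[str, str],
    n_decoys: int = 0,
    seed: int = 0,
    reciprocal: bool = False,
) -> list[AlignmentHit] | tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Fabricate alignment hits whose best-hit map is exactly ``true_map``.

    Every true pair gets the strictly highest bitscore among its query's
    hits; ``n_decoys`` lower-scoring decoy hits per query are added against
    random other subjects.  With ``reciprocal=True`` two directed tables are
    returned so mutual-best pairing also recovers the map.
    """
    rng = np.random.default_rng(seed)
    subjects = sorted(set(true_map.values()))
    fwd: list[AlignmentHit] = []
    rev: list[AlignmentHit] = []

    def _mk(query: str, subject: str, bit: float) -> AlignmentHit:
        return AlignmentHit(
            query=query, subject=subject,
            pct_identity=float(np.round(rng.uniform(35.0, 99.9), 2)),
            align_len=int(rng.integers(80, 900)),
            evalue=float(10.0 ** (-bit / 10.0)),
            bitscore=float(np.round(bit, 1)),
        )

    subject_index = {s: i for i, s in enumerate(subjects)}
    for q in sorted(true_map):
        s = true_map[q]
        top = float(rng.uniform(200.0, 500.0))
        fwd.append(_mk(q, s, top))
        if reciprocal:
            rev.append(_mk(s, q, top))
        if n_decoys and len(subjects) > 1:
            k = min(n_decoys, len(subjects) - 1)
            # sample decoy indices from the pool excluding the true subject:
            # draw from [0, n-2] and shift past the true index
            idx = rng.choice(len(subjects) - 1, size=k, replace=False)
            idx = np.where(idx >= subject_index[s], idx + 1, idx)
            for ds in (subjects[i] for i in idx):
                # cap decoys below every possible true-hit score so both
                # directions recover the truth in reciprocal mode
                bit = float(rng.uniform(20.0, 180.0))
                fwd.append(_mk(q, ds, bit))
                if reciprocal:
                    rev.append(_mk(ds, q, bit))
    return (fwd, rev) if reciprocal else fwd


def write_hits(hits: list[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular alignment layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# query\tsubject\tpident\tlength\tmismatch\tgapopen\t"
                 "qstart\tqend\tsstart\tsend\tevalue\tbitscore\n")
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pct_identity}\t{h.align_len}\t"
                f"0\t0\t1\t{h.align_len}\t1\t{h.align_len}\t"
                f"{h.evalue:.3g}\t{h.bitscore}\n")


def simulate_counts(
    n_genes: int,
    n_samples: int,
    mean: float = 50.0,
    dispersion: float = 0.3,
    seed: int = 0,
    organ: str = "organ",
    species: str = "sim",
) -> tuple[ExpressionMatrix, GeneLengths]:
    """Negative-binomial count matrix plus random gene lengths.

    Companion generator for the counts → TPM/FPKM pathway.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    mu = rng.lognormal(np.log(mean), 1.0, size=(n_genes, 1))
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p, size=(n_genes, n_samples))
    samples = [f"s{j}" for j in range(n_samples)]
    m = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=genes, columns=samples),
        Unit.COUNTS, species=species,
        organ_of={s: organ for s in samples})
    lengths = GeneLengths(
        {g: int(l) for g, l in zip(genes, rng.integers(200, 5000,
                                                       size=n_genes))})
    return m, lengths
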