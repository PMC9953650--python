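"""End-to-end orchestration from one YAML config.

``run_all`` wires the stages in order — unit handling, homolog mapping, OSG
calling, target projection, atlas index, overlap partition (+ optional
enrichment), QC — writing every stage's TSV outputs under the configured
output directory plus a machine-readable JSON report with input checksums,
thresholds and stage counts.  Analysis stages are deterministic; randomness
only enters through an optional built-in simulation step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .exprio import ExpressionMatrix, expressed_genes, read_expression_table
from .homology import HomologMap, best_hit_map, parse_hits, restrict_unique
from .overlap import enrich, enrichment_to_tsv, partition_expressed, read_gmt
from .projection import (DenominatorMode, call_tissue_enriched,
                         similarity_index, similarity_ratio)
from .qc import pca_scores, sample_correlation
from .specificity import OSGConfig, call_osgs
from .synthdata import SimConfig, simulate_dataset, write_hits

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the failing stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_DEFAULT_THRESHOLDS = {
    "reference_max": 0.5,
    "focal_min": 1.0,
    "projection": 1.0,
    "index": 5.0,
    "expressed": 1.0,
    "fold": 4.0,
    "enrichment_floor": 1.0,
}


@dataclass
class RunConfig:
    output_dir: Path
    focal_organ: str
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    excluded_reference_organs: list[str] = field(default_factory=list)
    overlap_reference_organ: str | None = None
    denominator_mode: str = "mapped"
    seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None
    annotation_gmt: Path | None = None
    qc_components: int = 2

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        merged = dict(_DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for name, value in self.thresholds.items():
            if value <= 0:
                raise ValueError(f"threshold {name!r} must be positive")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either 'simulate' or 'inputs'")
        if self.inputs is not None:
            required = ("focal", "reference", "target", "atlas",
                        "hits_focal_reference", "hits_focal_target",
                        "hits_atlas_focal")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input entries: {missing}")
            for key in required:
                entry = self.inputs[key]
                path = Path(entry["path"] if isinstance(entry, dict) else entry)
                if not path.exists():
                    raise ValueError(f"input path does not exist: {path}")
        if self.annotation_gmt is not None:
            self.annotation_gmt = Path(self.annotation_gmt)
            if not self.annotation_gmt.exists():
                raise ValueError(
                    f"annotation file does not exist: {self.annotation_gmt}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            output_dir=raw["output_dir"],
            focal_organ=raw["focal_organ"],
            thresholds=raw.get("thresholds", {}),
            excluded_reference_organs=raw.get("excluded_reference_organs", []),
            overlap_reference_organ=raw.get("overlap_reference_organ"),
            denominator_mode=raw.get("denominator_mode", "mapped"),
            seed=raw.get("seed", 0),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            annotation_gmt=raw.get("annotation_gmt"),
            qc_components=raw.get("qc_components", 2),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_matrix(entry: dict[str, Any]) -> ExpressionMatrix:
    return read_expression_table(
        entry["path"], unit=entry["unit"],
        species=entry.get("species", ""),
        organ_map_path=entry["organ_map"],
    )


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, exc) from exc
        return wrapper
    return decorate


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return (and write) the run report."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": dict(cfg.thresholds),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    t = cfg.thresholds

    # -- stage: inputs ----------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        if cfg.simulate is not None:
            sim_kwargs = dict(cfg.simulate)
            sim_kwargs.setdefault("seed", cfg.seed)
            sim_cfg = SimConfig(**sim_kwargs)
            ds = simulate_dataset(sim_cfg)
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            ds.focal.to_tsv(sim_dir / "focal.tsv")
            ds.reference.to_tsv(sim_dir / "reference.tsv")
            ds.target.to_tsv(sim_dir / "target.tsv")
            ds.atlas.to_tsv(sim_dir / "atlas.tsv")
            write_hits(ds.hits_focal_reference, sim_dir / "hits_fr.tsv")
            write_hits(ds.hits_focal_target, sim_dir / "hits_ft.tsv")
            write_hits(ds.hits_atlas_focal, sim_dir / "hits_af.tsv")
            ds.truth.to_json(sim_dir / "truth.json")
            checksums = {p.name: _sha256(p) for p in sorted(sim_dir.iterdir())}
            return (ds.focal, ds.reference, ds.target, ds.atlas,
                    ds.hits_focal_reference, ds.hits_focal_target,
                    ds.hits_atlas_focal, checksums)
        inputs = cfg.inputs
        assert inputs is not None
        focal = _load_matrix(inputs["focal"])
        reference = _load_matrix(inputs["reference"])
        target = _load_matrix(inputs["target"])
        atlas = _load_matrix(inputs["atlas"])
        hits_fr = parse_hits(inputs["hits_focal_reference"])
        hits_ft = parse_hits(inputs["hits_focal_target"])
        hits_af = parse_hits(inputs["hits_atlas_focal"])
        checksums = {}
        for key in ("focal", "reference", "target", "atlas"):
            checksums[key] = _sha256(Path(inputs[key]["path"]))
        for key in ("hits_focal_reference", "hits_focal_target",
                    "hits_atlas_focal"):
            checksums[key] = _sha256(Path(inputs[key]))
        return (focal, reference, target, atlas, hits_fr, hits_ft, hits_af,
                checksums)

    (focal, reference, target, atlas,
     hits_fr, hits_ft, hits_af, checksums) = load_inputs()
    report["input_checksums"] = checksums

    # -- stage: homology --------------------------------------------------
    @_stage("homology")
    def build_maps() -> tuple[HomologMap, HomologMap, HomologMap]:
        map_fr = restrict_unique(best_hit_map(hits_fr))
        map_ft = restrict_unique(best_hit_map(hits_ft))
        map_af = restrict_unique(best_hit_map(hits_af))
        map_fr.to_tsv(out / "map_focal_reference.tsv")
        map_ft.to_tsv(out / "map_focal_target.tsv")
        map_af.to_tsv(out / "map_atlas_focal.tsv")
        return map_fr, map_ft, map_af

    map_fr, map_ft, map_af = build_maps()
    report["stages"]["homology"] = {
        "pairs_focal_reference": len(map_fr),
        "pairs_focal_target": len(map_ft),
        "pairs_atlas_focal": len(map_af),
    }

    # -- stage: specificity -----------------------------------------------
    @_stage("specificity")
    def call_stage():
        osg_cfg = OSGConfig(
            reference_max=t["reference_max"],
            focal_min=t["focal_min"],
            excluded_reference_organs=frozenset(cfg.excluded_reference_organs),
        )
        res = call_osgs(focal, cfg.focal_organ, reference, map_fr, osg_cfg)
        res.to_tsv(out / "osg.tsv")
        return res

    osg = call_stage()
    report["stages"]["specificity"] = {
        "candidates": osg.n_candidates,
        "eliminated": osg.n_eliminated,
        "survivors": osg.n_candidates - osg.n_eliminated,
        "osgs": len(osg),
        "unscreened": len(osg.unscreened),
    }

    # -- stage: projection ------------------------------------------------
    @_stage("projection")
    def project_stage():
        profile = similarity_ratio(osg, map_ft, target,
                                   threshold=t["projection"])
        profile.to_tsv(out / "similarity_ratio.tsv")
        enriched = call_tissue_enriched(atlas, fold=t["fold"],
                                        floor=t["enrichment_floor"])
        enriched.to_gmt(out / "tissue_enriched.gmt")
        index = similarity_index(
            enriched, map_af, focal, cfg.focal_organ,
            threshold=t["index"],
            denominator_mode=DenominatorMode(cfg.denominator_mode))
        index.to_tsv(out / "similarity_index.tsv")
        return profile, enriched, index

    profile, enriched, index = project_stage()
    report["stages"]["projection"] = {
        "mapped_osgs": profile.mapped_total,
        "ratios": dict(profile.ratio_of),
        "expressed_counts": dict(profile.expressed_count_of),
        "enriched_set_sizes": {tt: len(s) for tt, s in enriched.sets.items()},
        "indices": {tt: i for tt, i in index.index_of.items()},
    }

    # -- stage: overlap ---------------------------------------------------
    @_stage("overlap")
    def overlap_stage():
        ref_organ = cfg.overlap_reference_organ or reference.organs[0]
        focal_expr = expressed_genes(focal, t["expressed"], cfg.focal_organ)
        ref_expr = expressed_genes(reference, t["expressed"], ref_organ)
        part = partition_expressed(focal_expr, ref_expr, map_fr,
                                   expression_threshold=t["expressed"])
        part.write(out / "overlap_")
        result = {"reference_organ": ref_organ, **part.counts}
        if cfg.annotation_gmt is not None:
            annotation = read_gmt(cfg.annotation_gmt)
            annotated = set().union(*annotation.sets.values())
            background = set(focal.genes) & annotated
            shared_focal = {a for a, _ in part.shared_pairs}
            for label, genes in (("shared", shared_focal),
                                 ("focal_only", part.focal_only)):
                query = genes & background
                if not query:
                    continue
                rows = enrich(query, annotation, background)
                enrichment_to_tsv(rows, out / f"enrich_{label}.tsv")
                result[f"enrich_{label}_terms"] = len(rows)
        return result

    report["stages"]["overlap"] = overlap_stage()

    # -- stage: qc --------------------------------------------------------
    @_stage("qc")
    def qc_stage():
        if focal.values.shape[1] < 2:
            return {"skipped": "fewer than two focal samples"}
        corr = sample_correlation(focal)
        corr.to_tsv(out / "qc_correlation.tsv")
        k = min(cfg.qc_components, focal.values.shape[1] - 1,
                focal.values.shape[0])
        pca = pca_scores(focal, n_components=k)
        pca.write(out / "qc_pca_")
        return {
            "n_samples": focal.values.shape[1],
            "min_correlation": float(corr.values.min().min()),
            "pca_components": k,
            "explained_variance": [float(v)
                                   for v in pca.explained_variance_ratio],
        }

    report["stages"]["qc"] = qc_stage()

    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
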