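# xorgan

Cross-species organ-transcriptome comparison toolkit.

Given gene × sample expression tables for two (or more) species and pairwise
protein-alignment hit tables, `xorgan`:

- builds one-to-one **homolog maps** (one-way best hit, unique, or reciprocal
  best hit) from 12-column tabular alignment files;
- calls **organ-specific genes (OSGs)** for a focal organ: candidates are
  mapped focal genes, eliminated when their reference homolog exceeds a
  ceiling (default 0.5) in any reference organ, kept when focal expression
  exceeds a floor (default 1.0) — both thresholds strict;
- projects OSGs onto a target species' organ panel and reports the per-organ
  **similarity ratio** (fraction of mapped homologs with TPM > 1);
- classifies **tissue-enriched genes** in a consensus atlas (≥ 4-fold above
  every other tissue, inclusive) and scores each tissue's **similarity
  index** against the focal organ (fraction of enriched-gene homologs with
  FPKM > 5);
- partitions two organs' expressed genes into **shared / organ-only** sets
  through an injective homolog map and runs a self-contained hypergeometric
  over-representation test with Benjamini–Hochberg FDR;
- converts counts → TPM / FPKM / RPKM, aggregates single-cell counts to
  pseudobulk, and computes sample-correlation / PCA QC summaries;
- generates **synthetic two-species datasets** with planted OSGs, planted
  per-organ expressed fractions, planted enriched sets and a machine-readable
  truth record, used by the test suite as recovery oracles.

## CLI

Every stage is a subcommand; `xorgan run` composes them from one YAML config.

```bash
# simulate a dataset with planted truth
xorgan simulate --seed 1 --out-dir sim/

# unit conversion and pseudobulk
xorgan convert --in counts.tsv --unit counts --to tpm \
    --lengths len.tsv --organ-map organs.tsv --out m.tpm.tsv
xorgan pseudobulk --in cells.tsv --out bulk.tsv

# homolog maps from tabular alignment hits
xorgan homologs --hits ab.tsv --mode unique --out map.tsv
xorgan homologs --hits ab.tsv --hits-reverse ba.tsv --mode reciprocal --out map.tsv

# OSG calling, projection, atlas index
xorgan osg --focal focal.tsv --focal-organ-map fo.tsv --focal-organ endostyle \
    --reference ref.tsv --reference-organ-map ro.tsv --map map.tsv --out osg.tsv
xorgan project --osg osg.tsv --map map2.tsv --target target.tsv \
    --target-organ-map to.tsv --out ratio.tsv
xorgan enriched --atlas atlas.tsv --atlas-organ-map ao.tsv --out sets.gmt
xorgan index --atlas atlas.tsv --atlas-organ-map ao.tsv --map map3.tsv \
    --focal focal.tsv --focal-organ-map fo.tsv --focal-organ endostyle --out index.tsv

# overlap partition + enrichment, QC
xorgan overlap --focal focal.tsv --focal-organ-map fo.tsv --focal-organ endostyle \
    --reference ref.tsv --reference-organ-map ro.tsv --reference-organ pharynx \
    --map map.tsv --out-prefix ov_
xorgan enrich --genes list.txt --gmt anno.gmt --background bg.txt --out enrich.tsv
xorgan qc --in m.tsv --organ-map organs.tsv --out-prefix qc_

# full pipeline
xorgan run --config run.yaml
```

A minimal `run.yaml` (simulation-backed; replace `simulate:` with an
`inputs:` block to run on real tables):

```yaml
output_dir: out/
focal_organ: focal_organ
seed: 1
simulate:
  n_genes_focal: 6000
  n_genes_reference: 6000
  n_genes_target: 6000
  n_planted_osgs: 150
thresholds:
  reference_max: 0.5
  focal_min: 1.0
  projection: 1.0
  index: 5.0
  expressed: 1.0
  fold: 4.0
```

The run writes every stage's TSV outputs plus `report.json` with input
checksums, thresholds and stage counts.

## File formats

- **Expression TSV** — first column `gene_id`, remaining columns samples.
- **Organ map TSV** — columns `sample_id`, `organ`.
- **Lengths TSV** — columns `gene_id`, `length_bp`.
- **Alignment hits** — tab-separated, ≥ 12 columns (query, subject, identity,
  length, mismatches, gap opens, qstart, qend, sstart, send, evalue,
  bitscore); `#` lines ignored.
- **Annotation** — GMT (term, description, tab-separated gene ids).

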