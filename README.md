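# tfcrkit

Analysis toolkit for **TFBS-clustered regions (TFCRs)**: kernel-density
clustering of transcription-factor binding sites, complexity scoring,
developmental gain/loss dynamics, genome-size-normalized cross-species
comparison, a per-gene regulatory synchronization score, and an explainable
tree-ensemble regressor for that score.

## What it does

- **`tfcrkit.genomic_io`** — readers/writers for FIMO TSV, BED, gene-model
  TSV, expression TSV, chrom.sizes and homolog maps; interval algebra;
  chromosome- and length-preserving shuffle nulls. Coordinates are 0-based
  half-open everywhere internally.
- **`tfcrkit.synthetic`** — synthetic genomes, gene models, clustered TFBS
  placement (promoter-enriched + background), multi-stage gain/loss
  dynamics with a configurable activation burst, and expression whose rank
  correlation with promoter cluster size is calibrated to a target.
- **`tfcrkit.caller`** — TFCR calling: unnormalized Gaussian KDE
  (bandwidth 300 bp, kernel K(0)=1) over TFBS centers, one TFCR per strict
  local maximum; a TFBS contributes when its kernel value at the summit is
  ≥ 0.1 (≈ within 644 bp); complexity = contributor count after merging
  overlapping same-family hits; decile groups 0 (low) to 9 (high).
- **`tfcrkit.annotation`** — promoter/exon/intron/intergenic categories
  (promoter = TSS ± 2 kb, priority promoter first), nearest gene,
  distances, promoter fractions, genome-size-normalized distance mode.
- **`tfcrkit.dynamics`** — stable/gained/lost classification by ≥ 1 bp
  overlap with the previous/next stage, gained/lost fractions, and a
  one-sided permutation test for promoter-fraction differences.
- **`tfcrkit.evolution`** — top/bottom selection of round(50·N) TFCRs by
  complexity (N = genome size as a multiple of yeast) and gene-association
  fractions.
- **`tfcrkit.regscore`** — synchronization score
  `(G_tfcr/9)·(G_expr/9)·exp(−|G_tfcr−G_expr|/5)` over complexity and
  expression deciles; per-gene tables; species-specific/conserved gene
  sets over homolog maps; species clustering by 1 − Spearman with complete
  linkage; hypergeometric enrichment.
- **`tfcrkit.ml`** — one-hot sequence + distance features (promoter window
  4000 nt, TFCR window 11113 nt, zero-padded), an 11-method regressor
  registry (gradient-boosted trees as the reference), 80/20 splits, 5-fold
  CV, pooled 30 000-per-species resampled training sets, five evaluation
  metrics, and permutation loss-change importance.
- **`tfcrkit.treeshap`** — exact per-sample Shapley attributions for
  scikit-learn tree ensembles (path-dependent polynomial-time algorithm),
  with the local-accuracy identity base + Σφ = prediction; tested against
  a brute-force subset-enumeration oracle.
- **`tfcrkit.pipeline` / `tfcrkit.cli`** — end-to-end orchestration with a
  single seed fanned out per module and a checksummed output manifest.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (score-grid
analytics, selection-rule counts, feature-window arithmetic, task/pool
bookkeeping, caller-vs-brute-force oracle equivalence, activation-burst
recovery, distance-dominance recovery through the Shapley pipeline, and
permutation-test calibration). The full suite runs in ~2.5 minutes.

## CLI

```bash
tfcr synth --seed 1 --outdir data/            # synthetic inputs + FASTA
tfcr call --hits data/hits_stage0.bed --format bed --out tfcrs.bed
tfcr annotate --tfcrs tfcrs.bed --genes data/genes.tsv --out anno.tsv
tfcr dynamics --tfcrs s0.bed --tfcrs s1.bed --out dynamics.tsv
tfcr regscore --tfcrs tfcrs.bed --genes data/genes.tsv \
    --expression data/expression_stage0.tsv --out gene_table.tsv
tfcr run --config cfg.yaml                    # full pipeline, manifest.json
```

Pipeline config (YAML): `seed`, `outdir`, `synth` (SynthConfig fields),
`caller` (bandwidth/threshold), `run_dynamics`, `run_regscore`, `run_ml`,
`ml_params`.

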