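# loyscan

Arm-level copy-number indices and mosaic Y-chromosome-loss (LoY) analysis for
segmented tumor data, with the downstream association battery and a built-in
synthetic cohort generator so the whole pipeline is testable offline.

## What it does

- **`loyscan.cn_index`** — parses SEG files (1-based inclusive, converted to
  0-based half-open internally), computes length-weighted average linear
  copy-number indices per chromosome arm, a purity-adjusted Y index over the
  male-specific region (pseudoautosomal regions masked, GRCh37 coordinates
  packaged), and a total autosomal aneuploidy index
  (sum over included arms of `|2 − index|`; acrocentric short arms
  13p/14p/15p/22p excluded, 21p optionally). Purity adjustment inverts the
  two-component mixture `observed = p·tumor + (1−p)·normal`, floored at 0.
- **`loyscan.loy_call`** — fits a Gaussian KDE to the Y-index distribution,
  locates the two dominant modes, and labels samples LOY / RETAINED /
  UNCERTAIN by position relative to the peaks. Also implements the
  array-based caller: female-background expression ratios per probe followed
  by PCA and the same bimodal classification on PC1 scores.
- **`loyscan.expression`** — CPM normalization (library-size or TMM),
  Spearman screening of genes tracking the Y index, filter-based differential
  expression (|FC| ≥ 1.5, p threshold, CPM > 1 in at least the smaller group
  size), sex-concordance checking, and hypergeometric gene-set enrichment
  with BH adjustment.
- **`loyscan.assoc_stats`** — Kaplan–Meier, log-rank, Cox (Efron ties, via
  lifelines), Kruskal–Wallis, Wilcoxon rank-sum, Spearman, and two-sided
  Fisher's exact test.
- **`loyscan.synthetic`** — seed-deterministic generator of matched
  segmented copy-number, clinical, RNA-seq count, and array-intensity data
  with known latent truth (LoY state, arm events, purity), including the
  LoY–aneuploidy coupling, LoY survival hazard, Y-gene dosage effects, and
  immune/redox expression structure.
- **`loyscan.pipeline`** — orchestrates the per-HPV-stratum run
  (indices → bimodal fit → calls → survival/association tests → DE →
  enrichment) and writes a TSV + JSON report.

## CLI

```bash
loyscan simulate --out data/ --seed 1            # synthetic cohort
loyscan index --seg data/segments.seg --scale log2ratio --out idx/
loyscan call --indices idx/sample_indices.tsv --out calls/
loyscan call-array --intensity int.tsv --samples samples.tsv --out calls/
loyscan de --counts counts.tsv --groups groups.tsv --p 0.01 --out de.tsv
loyscan enrich --hits hits.txt --universe universe.txt --gmt sets.gmt --out enr.tsv
loyscan survival --clinical clinical.tsv --calls calls/loy_calls.tsv --out surv/
loyscan run --config config.yaml                 # full pipeline
```

The `run` config is YAML with keys matching `loyscan.pipeline.PipelineConfig`
(`seg`, `clinical`, optional `counts`/`gmt`, `value_scale`, `bandwidth`,
`min_separation`, per-stratum DE p-thresholds, `out_dir`, `seed`).

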