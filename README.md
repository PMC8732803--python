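# cinwgs

Chromosome-instability (CIN) scoring from low-pass whole-genome sequencing
(LPWGS) read depth, plus the cohort statistics used to relate CIN status to
clinical variables in a BRCA1-mutated breast cancer cohort.

The pipeline:

1. **Bin** per-base depth (or pre-binned counts) onto a fixed 200-kb tiling
   of the hg19 chromosome arms (`cinwgs.genome`, `cinwgs.coverage`).
2. **Normalize** each tumor bin against a panel of controls:
   `z = (cov_tumor − mean(cov_controls)) / sd(cov_controls)`, after scaling
   every profile to unit mean depth (`cinwgs.coverage`).
3. **Segment** the normalized profile per arm with circular binary
   segmentation — max-t arc statistic, within-arm permutation p-values,
   recursive splitting at `p < 0.05` (`cinwgs.segmentation`).
4. **Score**: per-arm Z-scores, `CIN = Σ_arms length_Mb × |Z_arm|`, High/Low
   classification at a cutoff of 4000, and a TP53 copy-loss call at
   `Z_TP53 ≤ −3` (`cinwgs.cin`).
5. **Cohort statistics**: Fisher exact, chi-square, Cochran–Armitage trend,
   Kaplan–Meier, log-rank, and Cox proportional hazards (`cinwgs.stats`).

A synthetic-data module (`cinwgs.synthetic`) generates control/tumor bin
counts (negative-binomial with shared lognormal bin baselines, injected CNA
segments, tumor purity, optional focal TP53 deletion) and clinical cohorts
with known effect sizes, so every stage is testable offline. Transcriptions
of the source cohort tables (per-risk-group mutation counts; the 32-case
profiled cohort) ship under `cinwgs/data/`.

## CLI

```bash
# simulated inputs on the built-in toy genome
cinwgs simulate --out sim/ --n-controls 20 --seed 3 --cna 1q:10:40:0.5 --tp53-deleted

# full pipeline (equivalently: bin -> normalize -> segment piped manually)
cinwgs run sim/tumor.tsv sim/control-*.tsv --out results/ --toy-genome --seed 1

# individual stages
cinwgs normalize sim/tumor.tsv sim/control-*.tsv --out norm.tsv --toy-genome
cinwgs segment norm.tsv --out segments.seg --toy-genome --seed 1
cinwgs score sim/tumor.tsv sim/control-*.tsv --toy-genome
cinwgs tp53 sim/tumor.tsv sim/control-*.tsv --toy-genome

# packaged cohort tables: recompute the headline statistics
cinwgs reproduce
cinwgs cohort-stats my_cohort.tsv
```

Defaults (200-kb bins, CIN cutoff 4000, TP53 threshold −3, alpha 0.05,
1000 permutations) live in `RunConfig` and can be set via `--config
config.yaml` with per-flag overrides. Exit code is 0 on success, 2 on
validation errors.

## Layout

```
src/cinwgs/
  genome.py        arms, bin grids, loci (packaged hg19 arm table)
  coverage.py      binning, control panel, Z-normalization, depth QC
  segmentation.py  circular binary segmentation (from scratch)
  cin.py           arm Z-scores, CIN score, TP53 call
  stats.py         Fisher / chi-square / trend / KM / log-rank / Cox
  synthetic.py     simulators with analytic ground truth
  fixtures.py      packaged cohort tables + reproduction report
  pipeline.py      end-to-end per-sample run
  cli.py           click-based CLI
  config.py        RunConfig (YAML)
```
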