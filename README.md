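# mrmed

Two-sample Mendelian randomisation (MR) toolkit for estimating causal
effects of cardiometabolic risk factors on a binary outcome from GWAS
summary statistics, decomposing them into direct and mediated components
with multivariable MR, and following up instruments with eQTL-based pathway
over-representation and drug (ATC) annotation.

## What it does

- **`mrmed.summary_data`** — read/validate GWAS summary-statistics tables
  (TSV/CSV, configurable column maps, gzip), align effect alleles across
  traits (palindromic variants kept and aligned by letters; no proxies),
  select instruments at p < 5×10⁻⁸ with greedy LD clumping at r² < 0.001,
  and report per-variant F statistics and variance explained.
- **`mrmed.univariable_mr`** — Wald ratios, multiplicative random-effects
  IVW (the main analysis), weighted median with parametric-bootstrap SE,
  MR-Egger (slope + directional-pleiotropy intercept test), MR-PRESSO
  (simulation-based global test, outlier flagging, corrected IVW,
  distortion test). Significance labels use the 0.005 Bonferroni / 0.05
  suggestive rule.
- **`mrmed.mvmr_mediation`** — multivariable MR with the intercept fixed to
  zero (outcome-precision weights), difference-method decomposition
  (indirect = total − direct), proportion mediated with
  propagation-of-error SEs and symmetric normal CIs, per-unit rescaling,
  and an all-pairs exposure×mediator grid.
- **`mrmed.enrichment`** — instrument→gene mapping through a cis-eQTL table
  (q < 0.05, any-tissue rule by default), one-sided hypergeometric
  over-representation against GMT gene sets with Benjamini–Hochberg FDR,
  and drug/ATC annotation of FDR-significant pathways.
- **`mrmed.synthetic_data`** — seeded generator of three-trait summary
  statistics (exposure → mediator → binary outcome on the log-odds scale)
  with configurable instrument strength, LD blocks, outliers, and
  balanced/directional/correlated pleiotropy; ships a named scenario suite
  used throughout the tests.
- **`mrmed.pipeline`** — YAML-driven end-to-end runs with a JSON manifest;
  deterministic given config + seed.

## CLI

All commands are under the `mr` entry point:

```sh
# generate a synthetic study with known mediation structure
mr simulate --scenario mediation_half --seed 7 --out sim/

# univariable MR with all estimators
mr run --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
      --ld sim/ld.tsv --methods ivw,median,egger,presso --seed 7 --out results/

# one mediation decomposition
mr mediate --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
      --outcome sim/outcome.tsv --ld sim/ld.tsv --scale 1 --out med.tsv

# instrument report, full grid, enrichment, end-to-end run
mr instruments --exposure sim/exposure.tsv --ld sim/ld.tsv --out inst.tsv
mr grid --config run.yaml
mr enrich --instruments inst.tsv --eqtl eqtl.tsv --gmt pathways.gmt \
      --drugs drugmap.tsv --out enrich.tsv
mr full --config run.yaml
```

A `run.yaml` mirrors the CLI flags (`exposures`, `outcome`, `ld`,
`methods`, `p_select`, `r2_threshold`, `unit_scalings`, `seed`, `out_dir`,
optional `eqtl`/`gmt`/`drugs`); the config is echoed into the output
manifest for provenance.

### Negative-control outcomes

Population-stratification checks against a negative-control outcome (e.g.
self-reported tanning ability) need no special mode: run `mr run` with the
control trait's summary-statistics file as `--outcome` and inspect the
significance labels.

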