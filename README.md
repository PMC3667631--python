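# platescreen

Two-stage hit calling for 96-well siRNA secretion screens, implemented as a
reusable, fully tested pipeline:

1. **Synthetic screen generation** — 96-well plates (8×12), triplicate
   measurements, mock controls at two levels (±secretagogue), multiplicative
   plate effects, row/column gradients, lognormal well noise, and spiked
   hypo-/hyper-secretory genes with a ground-truth table.
2. **B-score plate normalization** — two-way median polish of each plate
   (least-squares-initialized alternating median sweeps), residuals scaled by
   1.4826 × MAD of the sample-well residuals.
3. **Rank-product aggregation** — per-replicate ranks in both tails, geometric
   mean rank product per gene, permutation p-values and expected
   false-positive proportions (annotations only; they never gate hits).
4. **Primary selection** — median B-score across replicates with a strict
   ±1.5 threshold (hyposecretory / hypersecretory / none), plus an optional
   case-insensitive annotation-category blocklist filter.
5. **Validation screen** — platewise z-scores, z = (xᵢ − mean)/SD over each
   plate's measured wells; a gene validates when its mean z lies outside
   mean(mock z) ± 2 SD(mock z).
6. **Quantification helpers** — loading-control ratios, fold change of
   condition means against a reference, mean ± SEM summaries, and a
   housekeeping-normalized expression/regulation filter (Welch test).

## CLI

All stages are exposed as subcommands of `platescreen`; tables are plain CSV
(dialects documented in `platescreen.io`).

```bash
# full pipeline from a config file (all keys optional; see RunConfig)
platescreen run-all --config config.yaml --outdir results/run1

# or stage by stage
platescreen simulate --config config.yaml --outdir results/sim
platescreen bscore   --wells results/sim/wells.csv --out results/bscores.csv
platescreen rankprod --bscores results/bscores.csv --out results/rankprod.csv --seed 1
platescreen select   --bscores results/bscores.csv --out results/hits.csv \
                     --rankprod results/rankprod.csv
platescreen validate --wells results/run1/validation_wells.csv --out results/validated.csv
platescreen quantify --intensities intensities.csv --reference nonstarved --out summary.csv
```

Example `config.yaml`:

```yaml
seed: 1
n_genes: 2000
hypo_fraction: 0.05
hyper_fraction: 0.02
hypo_effect: 0.25
hyper_effect: 2.5
noise_cv: 0.1
primary_threshold: 1.5
validation_n_sd: 2.0
n_perm: 100
```

Every run is a pure function of its config: identical config + seed gives
byte-identical outputs, and each CSV embeds the seed and config hash in a
header comment. `report.json` summarizes the hit funnel, degenerate plates,
and (for simulated screens) sensitivity/FDR per stage against the truth
table.

## Conventions worth knowing

- Controls sit in column 12; sample wells fill the 8×11 region diagonally so
  partially filled plates stay evenly covered in rows and columns.
- The median polish fits on all measured wells (samples + controls); the MAD
  uses sample wells only. Both are conventions — the source procedure does
  not specify them.
- On pure-noise plates B-scores have SD ≈ 1.3–1.4, not 1.0: median sweeps
  flatten the centre of the residual distribution, so the MAD under-scales
  relative to the SD. Thresholds are therefore slightly conservative in SD
  units.
- Threshold comparisons are strict: a median B-score of exactly ±1.5 is not
  a hit.
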