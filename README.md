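# strainfate

Tools for predicting and measuring the fate of a focal yeast strain in
serially propagated strain communities:

- **`strainfate.dynamics`** — multigenotype frequency model: each strain `i`
  carries a fitness `w_i = 1 - s_i` relative to the focal strain and
  frequencies update as `x_i(t+1) = x_i w_i / Σ_k x_k w_k`. Deterministic
  400-generation forecasts, stochastic serial-transfer simulation (1:500
  dilution ⇒ `log2(500) ≈ 9` generations per transfer, multinomial bottleneck
  at ~1.19e4 founder cells), and fixation/extinction classification (>99% /
  <1% at ≥3 consecutive recorded points).
- **`strainfate.fitness`** — selection coefficients from flow-cytometry
  competition counts: `t = ln(X_f/X_i)` generations of the fluorescent
  reference, `S/g = ln(R_f/R_i)/t`; replicate aggregation (mean ± 2 SEM) and
  community fitness change between ancestral and evolved assays.
- **`strainfate.growth`** — maximum growth rate from OD600 microplate series
  by sliding-window log-linear regression (default 9-point window, r² ≥ 0.95
  gate), OD→cell conversion (OD 1.0 ≈ 2.97e7 cells/ml) and normalized rates.
- **`strainfate.variants`** — naive variant filter over samtools-mpileup text
  (mapping quality ≥ 20, base quality ≥ 30, ≥80% support, ≥5 quality reads,
  both strands, forward/reverse bias strictly inside (0.2, 5.0)), minimal VCF
  output, and partitioned pairwise SNP/kb distance matrices
  (nuclear / mitochondrial / mating region).
- **`strainfate.synth`** — generators for every input above with known ground
  truth: logistic growth curves with truncated-Gaussian reader noise,
  competition counts that invert the fitness estimator exactly, drifting
  frequency trajectories, and pileups with planted SNPs, sequencing errors
  and strand-bias decoys.
- **`strainfate.cli`** — one entry point for the whole pipeline.

## CLI

```sh
strainfate --help
strainfate simulate-data -s 0.18 -s -0.05 --community community.yaml --seed 1 --out-dir simdata
strainfate growth simdata/growth_curves.csv --background 0
strainfate fitness simdata/competition_counts.csv
strainfate predict community.yaml            # deterministic 400-generation forecast
strainfate simulate community.yaml --seed 1  # bottleneck simulation, 6 replicates
strainfate classify simulate_out/simulated.csv
strainfate compare predict_out/predicted.csv simulate_out/simulated.csv
strainfate call-variants sample.pileup
strainfate distances s1.vcf s2.vcf --comparable-bases nuclear=12500000,mitochondrial=20000
```

A community config is a small YAML file:

```yaml
strains: [focalRFP, rivalA, rivalB]
focal: focalRFP
selection_vs_focal:
  rivalA: -0.05
  rivalB: 0.18
initial_focal_frequency: 0.5
```

Every run writes its artifacts, a `run.log`, and a machine-readable
`summary.json` into `--out-dir`:

```json
{
  "tool": "strainfate",
  "version": "...",
  "command": "<subcommand>",
  "config": { "<every resolved parameter>": "..." },
  "results": { "<command-specific outputs and paths>": "..." }
}
```

Same config + same seed ⇒ byte-identical outputs.

### Defaults (single source of truth)

| parameter | default |
|---|---|
| serial-transfer dilution | 500 (⇒ 8.97 generations/transfer) |
| bottleneck founder census | 11,880 cells (saturated 200 µl well / 500) |
| forecast horizon | 400 generations |
| fixation / extinction thresholds | 0.99 / 0.01 at ≥3 consecutive points |
| growth-rate window | 9 points (3 h at 20-min sampling) |
| variant filter | MQ ≥ 20, BQ ≥ 30, support ≥ 0.80, reads ≥ 5, bias ∈ (0.2, 5.0) |
| cytometer events per sample | 10,000 |

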