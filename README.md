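# dielmet

Analysis pipeline for diel (24-h) oscillations of particulate metabolites in
microbial communities, with paired transcript linkage. The package covers the
full chain from raw LC-MS peak-area tables to ecological conclusions:

- **`dielmet.synthetic`** — generator of complete synthetic studies
  (triplicate casts every 4 h over two multi-day periods, sinusoidal 24-h
  signals with exact fold-change parameterization, lognormal replicate noise,
  shared per-sample injection factors, matrix ion suppression, covariates,
  taxon×KO transcript series, ground truth).
- **`dielmet.quantify`** — best-matched internal standard (BMIS)
  normalization scored on pooled-QC RSD, plus three quantification modes:
  isotopologue ratio, standard additions (x-intercept), and matrix-matched
  external calibration with ion-suppression correction; extraction-blank
  flagging.
- **`dielmet.rhythm`** — nonparametric umbrella rank test for 24-h
  periodicity (exact dynamic-programming null for n ≤ 30, exhaustive
  enumeration for small tied samples, tie-corrected normal approximation
  otherwise; Bonferroni across candidate peak phases), Benjamini–Hochberg
  FDR, cosinor peak/amplitude estimation, and daily peak-to-trough fold
  changes over 24-h windows.
- **`dielmet.budget`** — %POC/%PN composition fractions, daily net turnover
  fluxes in carbon/nitrogen units, cell-quota pool attribution per taxon,
  the diazotroph trehalose→N₂-fixation energy budget (ATP/electron
  constraints, oxygen-drawdown adjustment), and reduced-major-axis (type II)
  regression.
- **`dielmet.linkage`** — taxon×KO transcript aggregation, metabolite↔KO
  joins via a curated offline link table, circular peak-lag analysis and
  peak-time association (Pearson plus a circular-correlation robustness
  check).
- **`dielmet.multivariate`** — z-score/Bray–Curtis dissimilarities and a
  rank-based permutational ANOSIM (with exhaustive mode for small n), plus
  pairwise time-of-day comparisons with BH correction.
- **`dielmet.io` / `dielmet.pipeline` / `dielmet.cli`** — schema-validated
  CSV/TSV readers, a flat YAML config, and an end-to-end pipeline with a
  reproducibility manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (null calibration of
the rhythm test, power/recovery on the emulated field design, exact-oracle
equivalence, worked stoichiometry, and the quantification round trip). All
fixtures are generated at test time by `dielmet.synthetic`; no downloads.

## CLI

```sh
# generate a complete synthetic study
dielmet simulate --out study/ --seed 1

# write a config (paths relative to the config file)
cat > config.yaml <<EOF
input_dir: study
out_dir: results
links: links.tsv
seed: 1
EOF

# full pipeline: quantify -> rhythm -> budget -> linkage -> multivariate
dielmet run --config config.yaml

# or individual stages
dielmet quantify --config config.yaml
dielmet rhythm --config config.yaml
dielmet budget --config config.yaml
dielmet link --config config.yaml
dielmet multivariate --config config.yaml
```

Outputs land in `out_dir`: `concentrations.csv`, `rhythm_results.csv`,
`rhythm_transcripts.csv`, `flux.csv`, `budget.csv`, `attribution.csv`,
`linkage.csv`, `lags.csv`, `anosim.csv`, `pairwise_anosim.csv` and
`manifest.json` (versions, seed, parameter hash, per-stage status).

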