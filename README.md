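# dilitree

Screening drugs for drug-induced liver injury (DILI) risk from simple
constitutional molecular descriptors — centered on the *average molecular
weight* (AMW = molecular weight / total atom count, hydrogens included)
threshold rule **AMW ≥ 7.4 → DILI-positive**, with a from-scratch CART
decision-tree learner, the full evaluation/validation machinery, and a
calibrated synthetic-cohort generator so every stage is testable offline.

## What's inside

| Module | Purpose |
| --- | --- |
| `dilitree.chem` | Formula/SMILES parsing, desalting + neutralization, organic-element exclusion rule, AMW / H% / MW descriptors on an explicit, overridable atomic-weight table, pluggable Moriguchi-style logP |
| `dilitree.cart` | Binary CART with Gini impurity, count-weighted impurity decrease, Mean-Decrease-in-Gini importance, CV depth selection, the published two-node screening rule (AMW ≥ 7.4; MLOGP < −0.454), lossless JSON model serialization |
| `dilitree.metrics` | Confusion-matrix statistics (accuracy, sensitivity, specificity, balanced accuracy, MCC), ROC/AUC, subclass-by-threshold contingency reports, ATC-first-level stratified reports, per-year AMW trend summaries |
| `dilitree.protocols` | Stratified splitting, nested 3-group/10-repeat cross-validation, final-model construction with inner 5-fold CV, seed-chained determinism |
| `dilitree.chemspace` | Near-zero-variance and linear-combination descriptor filters, mean-centered PCA with a fixed sign convention |
| `dilitree.synth` | Synthetic cohorts (defaults: 432 DILI : 220 no-DILI, class AMW means 7.99 / 7.49, operating point 0.64 / 0.71 at threshold 7.4), ATC strata with controllable separability, random molecular formula generation |
| `dilitree.cli` | `dilitree` command with subcommands for every stage |
| `dilitree.reference` | Published reference counts used as regression fixtures |

## CLI

```sh
# synthesize a cohort, fit the final tree, evaluate it
dilitree simulate --seed 1 --out runs/sim
dilitree train    --input runs/sim/drugs.csv --descriptors runs/sim/descriptors.csv \
                  --out runs/model --seed 1
dilitree evaluate --model runs/model/model.json --input runs/sim/drugs.csv \
                  --descriptors runs/sim/descriptors.csv --out runs/eval

# descriptor computation and threshold screening on your own drug table
dilitree descriptors --input drugs.csv --out runs/desc
dilitree screen      --input runs/desc/descriptors.csv --out runs/screen

# reports
dilitree contingency --input drugs.csv --descriptors runs/desc/descriptors.csv --out runs/ct
dilitree atc-report  --input drugs.csv --descriptors runs/desc/descriptors.csv --out runs/atc
dilitree trend       --input drugs.csv --descriptors runs/desc/descriptors.csv --out runs/trend
dilitree nested-cv   --input drugs.csv --descriptors runs/desc/descriptors.csv \
                     --config protocol.cfg --out runs/ncv
dilitree pca         --input runs/desc/descriptors.csv --out runs/pca
```

Drug tables are CSV/TSV with columns
`id,name,smiles,formula,dili_class,atc_codes,year,peptide_flag,nucleic_acid_flag`
(`dili_class` ∈ Most/Less/No; Most/Less count as DILI-positive; `atc_codes`
semicolon-separated).  Every run writes a `manifest.json` (config echo, seed,
version, input checksums); outputs are byte-reproducible for a fixed seed.
Exit codes: 0 ok, 1 usage error, 2 data error.

## Notes

- The atomic-weight table (IUPAC conventional values) is explicit and
  swappable (`MassTable.with_overrides(...)`) because near-threshold AMW
  values can flip with a different mass convention.
- The boundary value itself classifies positive ("7.4 or larger").
- Metrics with zero denominators are reported as *undefined*, never 0.
- MLOGP is treated as an opaque numeric feature: a precomputed input column
  always wins over the built-in calculator.
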