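# lipscreen

Analytics for an image-based lipophagy compound screen and its companion
nested case-control study, exercised end to end on synthetic data with
known ground truth.

The screen uses a tandem GFP–mCherry lipid-droplet reporter: GFP is
quenched at lysosomal pH while mCherry persists, so lipophagy shows up as
GFP loss over mCherry-positive droplet area. Per well, the pipeline counts
BFP-labelled nuclei, segments the mCherry-positive region, integrates GFP
and mCherry fluorescence there, and scores
`(mCherry total − GFP total) / cell count`. Scores are converted against a
vehicle-only (DMSO) plate at the same well position to remove positional
artifacts, standardized as robust Z = (x − median) / (1.4826 · MAD) over
the pooled compound wells, gated for toxicity (cell count < 80% of the
DMSO median), and called as hits at Z > 3 (strict).

The epidemiology half filters a patient registry (complete data, no heart
failure NYHA II–IV, age 20–80), matches exposed subjects 1:1 to controls
(exact on sex and atrial fibrillation; age/BMI nearest-neighbor within
calipers), and summarizes the exposure–outcome association with
prevalences, a Pearson chi-square, and the Mantel–Haenszel stratified
test with its common odds-ratio estimator.

## Modules

| Module | Purpose |
| --- | --- |
| `lipscreen.synthetic_data` | Ground-truth generators: plate layouts, 3-channel well images, flow-event tables, patient registries with a controlled odds ratio |
| `lipscreen.image_quant` | Nucleus counting, mCherry segmentation, fluorescence integration, lipophagy score |
| `lipscreen.screen_stats` | DMSO positional conversion, robust Z, toxicity gate, hit calling, fold change |
| `lipscreen.cytometry` | Event-table gating: generic gates, dual-reporter lipophagy fraction, surface-marker positive fraction |
| `lipscreen.epi_casecontrol` | Cohort filters, 1:1 matching, 2×2 tests (chi-square, Mantel–Haenszel), covariate balance |
| `lipscreen.assay_metrics` | Closed-form conversions: insulin ng/ml → µIU/mL (×26), HOMA-IR (/405), FAO activity (×12.96) |
| `lipscreen.pipeline_cli` | Orchestration and the `lipscreen` command-line interface |

## CLI

```sh
# simulate a plate (map, truth table, per-well 3-channel TIFFs)
lipscreen simulate-plate --n-compounds 352 --n-dmso 32 --n-actives 5 \
    --seed 1 --out-dir scratch/plate

# quantify it, and score against a DMSO-plate quantification table
lipscreen quantify --plate-map scratch/plate/plate_map.csv \
    --image-dir scratch/plate/images --out scratch/quant.tsv
lipscreen score --quant scratch/quant.tsv --dmso-quant scratch/dmso.tsv \
    --out-dir scratch/scored

# registry simulation and the nested case-control analysis
lipscreen simulate-registry --n 100000 --odds-ratio 0.58 --seed 1 \
    --out scratch/registry.csv
lipscreen analyze --registry scratch/registry.csv --out-dir scratch/epi
```

Exit codes: 0 success, 2 input error, 3 degenerate statistics (e.g. zero
MAD). Python entry points `run_synthetic_screen`, `run_screen` and
`run_casecontrol` in `lipscreen.pipeline_cli` expose the same flows.

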