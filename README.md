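# visearch

Generation, simulation and analysis of oriented line-segment visual-search
experiments: split-half and "jumbled" (1/f²-textured) search arrays, a
parametric scanpath simulator producing flat fixation reports, the
fixation-classification / search-efficiency pipeline, and group-level
inference with a parameter-recovery harness.

## Modules

| module               | role |
|----------------------|------|
| `visearch.stimgen`   | Search-array generation: 1/f² noise fields, histogram equalisation to a U-shaped parabolic reference, per-cell difficulties, orientation sampling, target placement, PNG/JSON export. |
| `visearch.observers` | Experiment designs (exp1: horizontal split-half; exp2: four mixed conditions), parametric observers (`w_het`, upper-field bias, detection radii, give-up budget), trial simulation and the tab-delimited fixation report. |
| `visearch.pipeline`  | Report reading/validation, out-of-bounds marking, split-half (30-px central strip) and jumbled (difficulty-threshold) fixation classification, efficiency score over fixations 2–6 of correct target-absent trials, accuracy/RT tables and exclusion rules. |
| `visearch.inference` | Per-fixation-index strategy curves, cluster-bootstrap interval estimates of P(fixation heterogeneous) by task × configuration, log₂-RT correlation matrices with Fisher-z intervals, and the end-to-end `recovery_experiment` / `coverage_simulation` harnesses. |

## CLI

A single entry point `visearch` with four subcommands:

```bash
# stimuli (PNG + JSON metadata)
visearch generate-stimuli --condition jumbled --n 5 --seed 1 --out stims/

# simulate a cohort -> fixation_report.tsv + observers.json
visearch simulate --experiment exp1 --n-participants 5 --seed 1 --out sim/

# classify + summarise a fixation report
visearch analyze --report sim/fixation_report.tsv --experiment exp1 --out analysis/

# parameter recovery of w_het through the full pipeline
visearch recover --condition split_half --w-grid 0.1,0.5,0.9 --seed 1 --out recovery/
```

## Conventions

Pixel origin top-left, x rightward, y downward, half-open pixel intervals;
cell indices 0-based `(col, row)`; fixation indices 1-based with index 1 the
trial-initiation fixation at the array centre. Orientations are radians
counter-clockwise from horizontal-rightward, stored modulo π; the target is
π/4 and distractors are sampled uniformly around π/4 + π/2 with a width that
grows linearly (π/6 → 2π/3) with local difficulty.
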