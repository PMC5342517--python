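# hormscreen

Dose-response quantification and biomarker association for small drug
screens whose samples can show *hormetic* (non-monotonous) responses —
enhanced growth at low doses before decline.

Given per-replicate cell-count tables over a dose grid, the pipeline

1. **quantifies** response per sample with four measures: per-replicate
   trapezoid AUC and interpolated IC50 (medianized across replicates), and
   AUC/IC50 of a five-parameter fitted curve — a decreasing two-parameter
   sigmoid plus a scaled normal-density peak — estimated by bounded
   nonlinear least squares with a minimum-RSS random-restart fallback for
   degenerate (very steep) responders;
2. **classifies** samples as monotonous vs non-monotonous (fitted viability
   ≥ 1.5× control at the lowest nonzero dose) and compares the groups with
   per-gene chi-square tests and empirical-Bayes moderated t-statistics;
3. **prepares features**: filters mutation records to coding non-silent
   classes, binarizes per gene, applies germline overrides, drops
   non-recurrent genes, groups collinear mutations (identical mutation
   pattern) with hypermutant-only / large-group flags; mean-centers and
   variance-filters expression;
4. **associates** features with all four measures (Welch t-tests with
   per-measure Benjamini-Hochberg adjustment at FDR 0.25 for mutation
   groups; Pearson |r| ≥ 0.5 for expression), reporting only features
   significant for ≥ 2 of 4 measures, plus hypermutant/subtype tests and a
   pairwise-complete drug-panel correlation screen against a focal drug.

A seeded synthetic-cohort generator (`hormscreen.synth`) plants known
curves, mutation effects, expression/drug correlations and collinear
groups, so every stage is testable end to end without external data.

## CLI

```bash
# full seeded pipeline on a synthetic cohort
hormscreen run-all --out report/ --seed 7

# stage by stage
hormscreen simulate --config cohort.yaml --out sim/ --seed 7
hormscreen quantify --counts sim/counts.tsv --grid "0,0.5,1,2,3,4,6,8" \
    --out measures.tsv --seed 7
hormscreen features --mutations sim/mutations.tsv --annotations sim/annotations.tsv \
    --expression sim/expression.tsv --out feat/
hormscreen phenotype --measures measures.tsv --grid "0,0.5,1,2,3,4,6,8" \
    --mutations feat/mutation_matrix.tsv --expression feat/expression_filtered.tsv \
    --annotations sim/annotations.tsv --out phenotype.tsv
hormscreen associate --measures measures.tsv --groups feat/groups.tsv \
    --expression feat/expression_filtered.tsv --drugs sim/drugs.tsv \
    --annotations sim/annotations.tsv --out report/
```

All interchange files are UTF-8 TSV with a header row, `NA` for missing
values, and `#`-prefixed metadata lines (config hash, seed).  Counts are
long-format (`sample`, `replicate`, `dose_uM`, `count`); expression and
drug panels are rectangular matrices with sample-ID headers.  Identical
config + seed reproduces byte-identical outputs.

## Package layout

| module | role |
| --- | --- |
| `hormscreen.doseresponse` | viability curves, hormetic model, fitting, the four measures |
| `hormscreen.synth` | seeded synthetic cohorts with planted ground truth |
| `hormscreen.features` | mutation binarization/grouping, expression preparation |
| `hormscreen.phenotype` | monotonicity calls, chi-square, moderated t |
| `hormscreen.assoc` | association tests, BH adjustment, robustness rule, drug correlations |
| `hormscreen.pipeline` / `hormscreen.cli` | orchestration, config, seeding, CLI |
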