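# pdxtrial

Analysis toolkit for **1×1×1 patient-derived xenograft (PDX) trials** —
pre-clinical drug trials in which each patient's tumor is transplanted
into mice and exactly one mouse per patient receives drug and one
receives vehicle. The package covers the full computational chain of
such a trial of a cytotoxic compound in metastatic melanoma PDXs:

1. **Tumor-growth response scoring.** Caliper readings are converted to
   volumes, `V = d_short² · d_long / 2` (mm³), and each model is scored
   as a treated-over-control percentage

   `T/C (%) = 100 · (T_i − T_0) / (C_i − C_0)`

   with subscript *i* the end of treatment and 0 the treatment start.
   Models are classified **progression** (T/C > 50 %), **suppression**
   (0 % ≤ T/C ≤ 50 %) or **regression** (T/C < 0 %), and summarized as a
   waterfall plot and per-group growth speeds.
2. **Doubling-time progression-free survival.** The event is the first
   measured day a treated tumor reaches twice its baseline volume;
   groups are compared with Kaplan–Meier curves and the k-sample
   log-rank (Mantel–Cox) test.
3. **Graft/host read disambiguation.** Reads aligned to a combined
   human+mouse reference are kept if human-only, dropped if mouse-only,
   and dual mappers are kept only when the primary alignment is to the
   human reference.
4. **Sensitive variant calling + retention cascade.** A threshold pileup
   caller (min coverage 2, min supporting reads 2, min VAF 0.01, min
   average quality 15, all inclusive), per-sample/pooled call-set
   merging, and an ordered annotation-driven cascade (coding region →
   non-synonymous → not in non-flagged dbSNP → COSMIC-only for
   oncogenes, population-database-clean for novel tumor-suppressor
   variants → homopolymer/read-end context for novel calls), with
   low-confidence flagging and oncoprint construction.
5. **Expression biomarker.** Median-of-ratios normalization, binning of
   a resistance marker (e.g. *ABCB1*, the p-glycoprotein efflux pump)
   into low (0–99), mid (100–1000) and high (>1000 normalized reads),
   and a stratified-permutation two-group differential-expression test
   with Benjamini–Hochberg control.

Because trials like this rarely deposit raw animal data, the package
ships first-class synthetic-data generators (`pdxtrial.synthetic`) that
emulate every input with known ground truth — exponential xenograft
growth with a three-component treatment-effect mixture, reads of known
species origin, variant records constructed to trip exactly one cascade
rule, and negative-binomial counts with batch structure and a planted
marker gene.

## Worked example

Simulate a 31-model cohort, score it, and run the survival comparison:

```sh
pdx synth growth --seed 1 --out cohort
pdx response --measurements cohort/measurements.tsv --out resp
pdx survival --measurements cohort/measurements.tsv \
             --response resp/waterfall.tsv --out surv
```

which prints

```
wrote 837 measurements for 31 models
{"progression": 32, "suppression": 42, "regression": 26}
{"chi2": 25.95017709234857, "df": 2, "p": 2.3173447172497254e-06, "groups": ["progression", "regression", "suppression"]}
```

Line 2 is the rounded percentage of models in each response class — a
10/13/8 split of 31 models: 32 % progressed under treatment, 42 % were
growth-suppressed, 26 % regressed. Line 3 is the log-rank comparison of
doubling-time progression-free survival between the three classes: with
the generator's clearly separated treatment effects the classes differ
strongly (χ² = 25.95 on 2 df). `resp/` also contains the waterfall
table/plot and per-group mean ± SEM growth speeds.

The same pattern works for the other stages (`pdx synth
reads|variants|counts`, `pdx reads-filter`, `pdx call`, `pdx filter`,
`pdx oncoprint`, `pdx de`, `pdx bin`), or from Python:

```python
from pdxtrial import CohortSpec, gen_growth_cohort, score_cohort

measurements, truth = gen_growth_cohort(CohortSpec(seed=1))
calls = score_cohort(measurements)
```

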