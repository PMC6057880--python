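# Methods

This note documents the models, conventions and numerical choices behind
`pdxtrial`, and what the synthetic generators do and do not emulate.

## Trial design and growth model

The package models a 1×1×1 PDX trial: each patient sample is
transplanted into three mice; xenografts are measured three times weekly
with calipers, and a mouse enters the trial when its tumor volume
reaches the 50–100 mm³ inclusion window. The first mouse to qualify is
assigned to the treated arm, the second to vehicle, the third is
excluded (ties on the entry day resolve to the lower mouse index, which
keeps the assignment deterministic). Treatment runs for 18 days
(configurable horizon).

Tumor volume follows the standard two-diameter ellipsoid approximation
`V = d_short² · d_long / 2`. The growth model throughout is exponential,
`V(t) = V₀ e^{g t}` — the simplest model with a well-defined doubling
time `ln 2 / g`, which the survival endpoint needs.

### T/C scoring conventions

`T/C (%) = 100 (T_i − T_0)/(C_i − C_0)` leaves two choices open at
thrice-weekly sampling, resolved as:

* **Baseline (T₀/C₀):** the measurement on the day closest to day 0,
  ties to the earlier day.
* **Endpoint (T_i/C_i):** each arm's own last measurement at or before
  the horizon. No extrapolation is performed.
* **Shrinking vehicle tumors** (`C_i − C_0 ≤ 0`) make the ratio
  sign-flip meaninglessly; such models are flagged invalid, excluded
  from the waterfall with a warning, and carry no class.
* Reported percentages round to the nearest integer, halves away from
  zero (an 8/13/10 split of 31 models prints 26/42/32).

The classification `>50 / [0,50] / <0` partitions the finite reals;
boundary values 50 and 0 belong to suppression.

**Growth speed** is the secant slope over the full observation window
(mm³/day); an OLS regression slope is available via
`growth_speed(..., method="regression")` but is not the default, since
"average growth speed" most plainly means total change over elapsed
time.

## Doubling-time survival

The progression event is the first *measured* day on which the treated
tumor reaches twice its baseline volume — no interpolation between
measurement days, since volumes between calipered days are unobserved.
Records without a doubling by the horizon are censored there. Estimation
uses the Kaplan–Meier product-limit estimator and the k-sample log-rank
test (df = k − 1); both delegate to `lifelines` behind the package's
interface, with the standard convention that events precede censorings
at tied times. One caveat worth knowing: adding a horizon-censored
record *does* change the estimate at earlier times (it enlarges every
at-risk set); what is invariant is the exact time of a censoring that
falls after the last event.

## Read disambiguation

The species rule is a pure function of three per-read flags
(maps-human, maps-mouse, primary-alignment-is-human): human-only reads
are kept, mouse-only dropped, and dual mappers kept only when their
primary alignment is to the human reference. The package consumes
per-read flag tables by default; a SAM adapter derives the flags from a
combined-reference alignment using configurable contig-name prefixes
(`hg19_`/`mm10_` by default), collapsing multi-mapping within a species
to a single flag, because the rule only inspects species and primacy.

## Variant calling and the retention cascade

The caller is a minimal threshold caller over pileup columns with the
sensitive settings appropriate for low-input RNA data: inclusive
thresholds min-coverage 2, min-reads2 2, min-var-freq 0.01,
min-avg-qual 15. Dialect choices: depth counts every observation;
support counts observations at or above a separate per-observation
quality floor (`min_base_quality`, default 0, so all observations
support by default); VAF = support/depth; the average-quality threshold
applies to the supporting observations. Per-sample and pooled call sets
merge on (sample, chrom, pos, ref, alt), collisions keeping the record
with more supporting reads (ties keep the earlier record); the merge is
idempotent and order-insensitive.

The cascade is an ordered, pure per-record function; the verdict names
the *first* failing rule (ordering is observable only in the verdict
label, not in the retained set):

1. region ∉ {exonic, splicing} → drop;
2. synonymous → drop;
3. non-flagged dbSNP entry → drop;
4. oncogene: retain only known COSMIC variants;
5. tumor suppressor: retain COSMIC variants; novel ones only if absent
   from ESP6500 and 1000 Genomes (loss-of-function in suppressors is
   plausibly novel, hence the asymmetry);
6. no oncogene/tumor-suppressor role → drop;
7. novel (non-COSMIC) survivors with a homopolymer-adjacent context or
   supported only at read ends → drop (homopolymer slippage and
   read-end misalignment are the dominant artifact modes for novel
   RNA-seq calls).

`homopolymer_adjacent` is inclusive: a run of ≥ 5 identical bases
(configurable) starting or ending within 1 bp of the variant — or
containing it — triggers the flag. `end_of_read_only` is true when every
supporting read places the variant within 5 bp of a read end; it is
normally consumed as an annotation flag, with an optional computation
from per-read offsets. The gene-role table is an input with a packaged
default covering common melanoma panel genes. A manual-rescue whitelist
of (sample, chrom, pos, ref, alt) keys bypasses the cascade; rescued
calls and any call with ≤ 2 supporting reads are flagged low
confidence. Oncoprints order samples progression → suppression →
regression and collapse multiple variants per cell to the highest
confidence state.

## Expression biomarker

Normalization is DESeq-style median-of-ratios (factors over genes
nonzero in all samples, relative to the geometric-mean
pseudo-reference), after dropping genes with zero total count. Marker
binning uses fixed cut-points on normalized reads: low < 100,
100 ≤ mid ≤ 1000, high > 1000 (the 1000 boundary is mid because "high"
is strict).

The two-group test deliberately does **not** re-implement a NB-GLM Wald
test: effect sizes are differences of batch-adjusted group means in
log2(normalized + 1) space, with per-batch mean-centering as the batch
adjustment, and significance comes from a two-sided permutation test of
the group labels **stratified by batch** (default budget 10,000; when
the exact number of distinct within-batch label assignments fits the
budget they are enumerated and the p-value is exact, including the
observed assignment). A batch containing only one group makes the
stratified null degenerate and is rejected. q-values are
Benjamini–Hochberg. The structural findings this targets — a marker
highly expressed in a subset of one response group — are robust to this
substitution; genuinely NB-distributed tail behavior is not modeled.

## Synthetic generators: what they emulate, and what not

All generators are deterministic given their seed (same seed ⇒
byte-identical tables), and their truth tables are sufficient to score
every downstream stage without re-deriving truth.

**Growth cohort.** Per model, one growth rate
`g ~ LogNormal(ln(ln2/4), 0.25)` — a four-day median vehicle doubling
time, typical of serially passaged melanoma xenografts in
immunodeficient mice. Three mice get implant volumes `U(5, 45)` mm³;
their ordering determines arm assignment. Baselines are drawn
`U(50, 100)` mm³ at day 0. The treatment effect comes from a
three-component mixture with weights 10/13/8 over 31 (converted to
exact per-class counts by largest remainder): progression and
suppression components draw a target T/C uniformly in (70, 145) % and
(13, 38) % respectively and invert the T/C formula for the treated
rate; the regression component draws a horizon shrink fraction
`U(0.25, 0.75)` of baseline. The bands sit clear of the 0/50 boundaries
so that 3 % multiplicative caliper noise (log-normal on each diameter,
independently) leaves the intended class recoverable — verified exact
on 999 of 1000 seeds. Diameters come from inverting the volume formula
at a fixed aspect ratio 1.3 (`d_short = (2V/r)^{1/3}`), which round-trips
to the analytic volume within 1e−9 mm³ at zero noise. Not emulated:
measurement-day jitter, inter-mouse growth-rate heterogeneity within a
model, engraftment failure, or body-weight effects — so passing tests
show the scoring chain is correct, not that real cohorts are this
clean.

**Reads.** Species proportions 0.7/0.1/0.2 human/mouse/ambiguous by
default; ambiguous reads get a fair-coin human-primary flag. No
sequence-level realism — the generator emits decision-rule inputs, not
alignments.

**Variants.** Each failing record starts from a retained archetype
(COSMIC oncogene, COSMIC tumor suppressor, or clean novel tumor
suppressor) and flips exactly one annotation, so every cascade rule is
exercised in isolation and verdicts are checkable against truth by
construction.

**Counts.** Negative-binomial (dispersion 0.1) with log-normal per-gene
means (median 100), a log-additive batch offset (0.5 log2 units per
batch step), optional known per-sample depth factors, an optional
planted DE gene, and a marker gene drawn around 5000 normalized reads
in designated "high" samples versus 20 elsewhere.

## Problem sizes and tolerances

Default analysis scales: 31-model cohorts, 10⁴ simulated reads, 24
variant records (one archetype per rule plus retained), 150–2000 genes
for expression work; the exhaustive Kaplan–Meier cross-check runs all
time-multiset/event configurations with ≤ 6 records, and permutation
null-uniformity checks use 1000 label permutations (log-rank) and exact
enumeration over 252 splits (expression), judged by Kolmogorov–Smirnov
at α = 0.01. Floating-point comparisons in tests use relative tolerances
of 1e−6 to 1e−12 depending on whether a quantity is analytic or passes
through noise.

## Known limitations

* T/C is undefined for non-growing vehicle tumors; such models simply
  drop out of classification rather than being re-scored by another
  criterion.
* The doubling event uses measured days only; with sparse schedules the
  recorded event time overestimates the true doubling time by up to one
  inter-measurement gap.
* The permutation DE test's resolution is limited by the number of
  distinct label assignments (minimum attainable p = 1/N in exact mode);
  small designs cannot reach small q-values over many genes.
* The cascade treats annotations as given; it does not re-derive them
  from sequence except for the optional homopolymer/read-end helpers.
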