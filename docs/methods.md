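# Methods

## Sampling model

The countable unit of MRD is the gDNA template: one input genome copy of a
rearrangement entering the assay. Diploid loci carry one productive
rearrangement per cell, so a sample with an expected malignant-cell input
*c* contributes, for each tracked rearrangement independently, a template
count distributed Poisson(*c*). This independence across rearrangements of
the same clone is what makes multi-sequence tracking informative: the
consensus (unweighted mean) of the per-rearrangement counts is an unbiased
estimate of *c* with variance *c/k* for *k* tracked sequences.

Total nucleated cells are quantified from reference amplicons of regions
present as diploid copies: `reference_templates = 2 * round(mass / 6.53)`
templates for a DNA mass in pg (6.53 pg per human diploid cell), so 20 ug
corresponds to 3,062,787 cell equivalents. When reference counts are
absent the mass conversion is used directly. MRD frequency is the ratio of
consensus malignant cells to total nucleated cells, exactly 0 when no
template is seen.

Assay noise beyond Poisson sampling is modelled as multiplicative lognormal
noise on template counts (`extra_cv`, default 0 — the contrived-sample
studies are Poisson-only unless noise is requested) with counts re-rounded
to integers afterwards, and as per-nucleotide substitution errors in reads
at `per_base_error_rate`.

## Synthetic repertoires and study designs

`gen_healthy_repertoire` draws clone frequencies from a rank power law with
default exponent 2. The exponent matters for the separation criterion: with
exponent 1 the background contains many clones within a factor of 10 of any
candidate (the log-frequency density is flat), which no realistic polyclonal
marrow shows; exponent 2 concentrates mass in a few modest clones and a
long tail, matching the steep clone-size distributions of healthy
repertoires. Sequences are i.i.d. uniform ACGT strings of 45 nt (a typical
IGH CDR3 scale); no V(D)J gene-segment model is attempted.

`gen_validation_grid` emulates the factorial precision study: expected-cell
abundances {2.14, 6.13, 21.44, 61.26, 214.46, 612.56} crossed with DNA
inputs {500 ng, 2 ug, 20 ug}, with factors operator set (3 levels),
instrument set (2), reagent lot (4), day (21) and run-within-day (10).
Factor effects are multiplicative lognormal with a configurable CV, drawn
once per level and shared across strata — a random-effects model on the log
scale. Levels are assigned by balanced permutation (tiling each factor's
levels to the replicate count and permuting independently) rather than
cyclically: cyclic assignment confounds factors whose level counts share a
divisor (e.g. operator's 3 levels and day's 21). Grid measurements stay
real-valued after the multiplicative effects; only template counts of
contrived samples are discretised.

Blank panels contain no malignant templates; with a configurable
`collision_rate` per tracked sequence a coincidentally matching healthy
clone is planted at 1 + Poisson(1) templates, modelling the
intermediate-uniqueness collisions that motivate the limit of blank.

All randomness derives from per-(sample, sequence) substreams of the master
seed (`numpy.random.SeedSequence`), so generating a subset of a study never
shifts the draws of other samples, and fixed seeds reproduce template
counts bit for bit.

## Clonotype identification

A candidate is trackable when it passes all five criteria: at least 3% of
receptor sequences at its locus; at least 0.2% of all nucleated cells; no
more than 5 other less-abundant same-locus sequences within a factor of 10
in frequency (ties in abundance count toward rejection); at least 40
templates; and sufficient uniqueness. Cell fractions use the
reference-amplicon denominator, not read totals.

The uniqueness score is the add-one-smoothed negative log incidence rate,
`-log10((incidence + 1) / (total_repertoires + 1))`: 0 for a ubiquitous
sequence, ~6 for one never seen in a million repertoires. The form is a
design choice — monotone in incidence and bounded is all downstream logic
requires. The allowed-mutation budget N rises with the score in
configurable tiers (default: 0 below score 1, then floor(length/45),
floor(2·length/45), floor(length/15), capped at 3), so non-unique sequences
must match exactly while complex ones absorb somatic variation.

## Tracking and sequence accuracy

Matching is Hamming-only at equal length (no indels): an observed sequence
is assigned to the nearest tracked sequence within its budget N, ties going
to the lowest-index tracked sequence. Detection requires at least one
matched template.

Overall percent agreement accumulates, over records with mismatches within
budget, positive agreement `(length - mismatches) * abundance` and negative
agreement `mismatches * abundance` in exact integer arithmetic;
OPA = 100·PA/(PA+NA). The disagreement rate NA/(PA+NA) is restated as a
Phred score `-10 log10(rate)` (the standard convention — a 3.5e-5 rate maps
to 44.6); a zero rate reports a configurable cap (default 60). The OPA
confidence bounds are Clopper–Pearson on the per-nucleotide proportion.

## Validation statistics

**LoD.** Detection (boolean) is regressed on log10 expected cells with a
probit link (GLM); LoD solves the fitted probability = 0.95. Log dose is
the standard choice for limit-of-detection work and behaves well over the
1–23 cell range; a linear-dose mode is kept. The CI is a percentile
bootstrap over samples (2,000 replicates by default). Complete separation
returns a flagged fit instead of an estimate. For a single tracked
rearrangement the analytic benchmark is 1 − e^(−λ) = 0.95, i.e.
λ = 2.996 cells; the probit approximation to that curve lands within ~3%.

**LoQ.** Relative total error per level is RMSE/expected (equivalently
sqrt(bias² + variance)/expected; 1/sqrt(λ) for an unbiased Poisson
estimator). Sadler's three-parameter profile `y = (b1 + b2 x)^J` is fitted
to the per-level RTE by least squares with multi-start over a J grid
(±0.5…±2), initialising (b1, b2) by linearising `y^(1/J0)`; LoQ is the
crossing of the fitted profile with 0.70, solved by grid scan plus brentq.
Fitting RTE rather than raw variance is the default because the LoQ
criterion is stated on total error; a pure-Poisson profile crosses 70% at
(1/0.7)² = 2.04 cells.

**LoB.** The nonparametric percentile at interpolated rank 0.5 + 0.95·n
(CLSI-style), per DNA-input level and overall. With no collisions every
blank measurement is zero and the LoB is exactly zero.

**Precision.** Variance components per abundance level, pooled across DNA
inputs. Two estimators are provided: REML on log(count + 0.5) with all
factors as variance components (statsmodels MixedLM), back-transformed via
cv² = exp(σ²) − 1; and raw-scale ANOVA method-of-moments, where each
factor's component is max(0, (MSB − MSW)/n0) from its one-way decomposition
and the residual is the total variance minus the factor components — so in
moments mode the components sum to the total variance by construction.
Each component is reported as %CV = 100·sd/mean; repeatability is the
residual %CV, reproducibility the %CV of the summed components, lot-to-lot
the reagent-lot %CV. The two modes answer slightly different questions: at
λ = 2.14 the raw-scale residual %CV is the Poisson floor 100/√2.14 = 68.4,
while the log-scale back-transform of the same data gives ≈76 because
log(X + 0.5) of a low-mean Poisson is skew; the raw scale is the one on
which low-input precision claims should be read. Negative estimates are
truncated to zero; a factor with fewer than two levels in a stratum raises
a confounding error naming it.

**Linearity.** The polynomial method on log10-transformed frequencies
(dilution series span orders of magnitude, and multiplicative errors are
homoscedastic on the log scale): fit orders 1–3; if no nonlinear
coefficient is significant at P < 0.05 the range is linear. Otherwise the
best (AIC) higher-order model is compared with the linear fit at each
level on the back-transformed scale; if every deviation is within ±5% the
range is acceptably linear, else the extreme level on the worse-deviating
end is dropped and the procedure repeats, down to a minimum of four
levels. One consequence of assessing on the log scale: a pure power-law
distortion (e.g. observed ∝ expected²) looks straight on log-log axes and
is reported through its slope (2.0 instead of 1.0) rather than through the
curvature test, so the slope is part of the verdict a reader should check.

**Bias.** Relative bias (observed − expected)/expected is summarised per
stratum (disease × input-cell level) as the mean of per-sample mean
relative errors. The nested bootstrap resamples samples with replacement
within a stratum, then replicates within each selected sample, preserving
the hierarchical correlation; the CI is the 2.5/97.5 percentile over
10,000 replicates (clipped to contain the point estimate). Strata with a
single sample are flagged degenerate.

## Problem sizes and determinism

Simulation sizes are chosen so every check closes its Monte-Carlo error
comfortably: 50,000 samples for the probit LoD study (panel {1, 2, 3, 4,
6, 9} cells), 5,000–10,000 replicates for Poisson mean/CV checks, 900-
replicate grids for the low-input residual CV, 10 independent grids for
factor-CV recovery, and 10,000 bootstrap replicates for bias. All tests
and scripts are deterministic under their fixed seeds.

## What the generator does not emulate

No V(D)J recombination model, somatic-hypermutation phylogenies, chimeric
PCR artifacts, amplification bias, or real database-scale uniqueness
statistics; translocation loci are ordinary tracked sequences. Passing
tests therefore demonstrate the correctness of the estimators and the
tracking logic under the stated sampling model, not the performance of any
assay on clinical material — clinical headline values (e.g. an LoD of
1.903 cells estimated on patient dilutions) depend on data this package
does not model.
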