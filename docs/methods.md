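# Methods

## The model

A risk chart is a function from categorized risk factors to one of six
ordinal risk bands.  Formally, let the stratifiers (sex, age group, WHR
high/normal, family history, diabetes, smoking — any subset) induce a
partition of the population into blocks, and let each block b carry a matrix
G_b ∈ {1..L}^{R×C} over BP rows (R = 4) and cholesterol columns (C = 5, or
C = 1 in the cholesterol-free 1D form), with L = 6 bands
(≤1 %, 2 %, 3–4 %, 5–9 %, 10–14 %, ≥15 %).  A person's score is the gene at
their (block, BP, cholesterol) cell.  Validity is the monotone constraint

    G_b[r, c] ≤ G_b[r', c']   whenever r ≤ r' and c ≤ c',

with index 0 the lowest category of each axis.  The constraint is non-strict:
published charts plainly repeat levels across adjacent cells.  (Rendering
shows the highest BP row first; that flip is presentation only.)

Training maximizes the chart-wide AUROC.  Because scores take only L values,
AUROC reduces to per-level positive/negative histograms, and substituting a
candidate matrix into one block changes only that block's contribution; the
fitness evaluator exploits this to score a candidate in O(R·C + L²) after a
single O(n) pass, independent of cohort size.  This incremental histogram
cache is exact, not an approximation (verified against direct lookup scoring
in the tests).

## Genetic search

Per block: population P = 20 valid chromosomes, up to 50 generations,
stopping after 10 generations without improvement.  Each generation draws
P/2 parent pairs by roulette (probability ∝ fitness; an optional
`weight_offset` subtracts the 0.5 chance baseline, off by default), forms
each pair's full one-point splice pool (both prefix/suffix orders over the
row-major linearization, ≤ 2(R·C−1) candidates, invalid ones dropped,
duplicates removed), roulette-draws two children per pair, and mutates each
child: one uniform gene ±1 with equal probability, clamped to [1, L], then
minimally repaired.  Repair after an increase raises exactly the cells
transitively forced below a monotone predecessor (a prefix-max sweep over
the affected quadrant), and symmetrically lowers after a decrease; on
exhaustively enumerated small instances this equals the unique L1-minimal
valid matrix keeping the changed cell at its new value.  Replacement keeps
the best individual (elitism) and fills the rest by seeded sampling without
replacement from parents ∪ children, so the best-ever fitness trace is
non-decreasing by construction.

Chart-level training initializes each cell from its empirical 10-year event
proportion mapped to the nearest band midpoint (0.5, 2, 3.5, 7, 12, 17.5 %
— a reporting convention, not an estimate; the chart itself is ordinal),
fills empty cells with the rounded block-mean level, and restores validity
by weighted isotonic regression (rows, then columns, weights = cell counts
floored at 1) followed by a cumulative-max sweep — the sweep is needed
because rounding after the two isotonic passes can leave single-step 2D
violations.  Blocks are then visited in descending data-size order (ties
broken lexicographically; empty blocks keep their initialized matrix, since
deployment needs a complete chart), each replaced by its GA solution, for at
most 2 rounds or until the round-over-round AUROC gain drops below 0.001.
The incumbent is always seeded into the block's population, so no update can
lower the training AUROC.  A final modifier raises each covered cell by one
level if its observed positive fraction strictly exceeds 0.5 and lowers it
by one otherwise (ties lowered), clamped and skipped when the change would
break validity; it runs once, after the rounds, on training data only.

Population size, generation count and stall limit are not dictated by the
method and were fixed once at desk-scale values; they are exposed in
`GAParams`.  All randomness flows through one seeded `numpy` generator, and
a fit is bit-reproducible from (cohort, spec, params, seed).

## Cross-validation

Stratified 10-fold: each outcome class is shuffled with the seed and dealt
cyclically, so fold sizes and per-class counts each differ by at most one.
Every fold re-runs the entire pipeline (initialization, GA rounds, modifier)
on the other nine folds and is scored by AUROC on the held-out fold; the
mean over folds is reported.  Training AUROC is optimistically biased
relative to CV — measured on permuted-label cohorts (n = 2,000, 1D chart)
the final training AUROC averages ≈ 0.60 against a true 0.5, while the CV
mean is correctly centered at 0.5.  This bias is intrinsic to any
AUROC-maximizing fit and is why the CV number, not the training number, is
the honest performance estimate.

## The synthetic cohort

No suitable person-level cohort is public, so tests and benchmarks run on a
simulator that emulates the statistical shape of a prospective middle-aged
cohort: default n = 5,432 with a target ten-year event rate of
705/5432 ≈ 13 %.  Each chart cell receives a true event probability

    p(cell) = expit(α + Σ_f β_f · code_f),

with per-category-step log-odds β chosen once at epidemiologically plausible
ten-year magnitudes (age 0.55 per decade group, BP 0.35 and cholesterol 0.22
per category, male 0.45, high WHR 0.30, family history 0.35, diabetes 0.55,
current smoking 0.45) and α solved by root-finding so the expected event
rate over the cell distribution hits the target.  β ≥ 0 is enforced for BP,
cholesterol and age, so the planted surface is monotone by construction.
Category marginals are fixed, field-plausible values (52 % women; age groups
38/28/20/10/4 %; BP 45/30/15/10 %; cholesterol 25/35/25/10/5 %; WHR-high
55 %; family history 15 %; diabetes 10 %; smoking 20 %).  Features are
sampled independently by default; an `age_bp_dependence` knob exponentially
tilts the age×BP joint because real cohorts correlate them.  Outcomes are
independent Bernoulli draws from the person's cell probability.  A
raw-values mode emits continuous measurements (age, systolic BP,
cholesterol, WHR, fasting glucose) floored within each category's interval
so the binning and flag-derivation paths are exercised end to end.

What the simulator does *not* emulate: censoring and competing risks,
missing data, measurement error, secular trends, or any feature correlation
beyond the optional age–BP tilt.  Passing recovery tests therefore show the
optimizer can find a planted monotone signal at realistic prevalences and
effect sizes — not that the method attains any particular accuracy on real
cohort data.

The planted probabilities give two oracles: `bayes_auroc` scores people by
their true cell probability (the ceiling for any scorer constant within
cells), and `recovery_report` computes the Spearman rank correlation between
planted probabilities and learned levels over cells with ≥ 30 covered
records (fewer records make a cell's level essentially unidentified).  Note
that even the exact level-discretized truth does not reach Spearman 1.0:
mapping distinct probabilities onto six levels creates ties, so ≈ 0.93–0.95
is the practical ceiling at these settings.

## Numerical and design choices

- Bins are left-closed/right-open ([120, 140), …); values below the first
  edge take category 1, values at or above the last edge the top category.
  Printed chart ranges overlap at their endpoints otherwise.
- Age groups default to 35–44, 45–54, 55–64, 65–74, ≥75 (five groups from
  the configurable floor of 35); the edges are overridable in the spec.
- WHR is dichotomized at ≥ 0.80 (women) / ≥ 0.95 (men); diabetes is fasting
  glucose ≥ 126 mg/dL, or 2-h glucose ≥ 200 mg/dL, or treatment.
- Missing cholesterol under a 2D spec is an error; lab-free scoring uses the
  1D spec.  No imputation anywhere.
- Crossover linearization is row-major (BP-major); the order is recorded in
  the chart JSON (`gene_order`).
- Candidate fitness is evaluated in the context of the *current* working
  chart (global AUROC), not block-locally, and the ratio modifier runs once
  globally after the GA rounds; both choices are recorded here because the
  alternatives (isolated block fitness; per-step modification) are also
  defensible readings of the procedure.
- Mutation at a boundary level clamps to a no-op rather than wrapping.
- Zero-weight roulette pools fall back to uniform sampling.
- A zero-event cohort is rejected at initialization (AUROC is undefined on a
  single class, so nothing downstream could run).
- Survival-regression-based initialization is supported by loading an
  external chart JSON as the incumbent (`strategy="external"`); fitting such
  a model is out of scope for this package.

## Problem sizes used in tests and the acceptance script

Chart geometry and the repair/AUROC oracle checks are exact and exhaustive
(all 4×1 and 2×2 instances at ≤ 3 levels; 1,000 random AUROC instances at
n ≤ 200).  Operator closure runs 10,000 seeded crossover+mutation cycles.
Training-trace monotonicity uses 20 seeds at n = 20,000; planted-surface
recovery uses n = 50,000 (10 seeds in the tests, 5 in the script); the
training-vs-CV comparison runs at n = 5,432; null calibration uses permuted
labels at n = 2,000 (30 training / 8 CV replicates in the tests).  The 1D
4-feature chart is used for the heavy experiments; a full 1D fit takes
about 1–2 s, a 2D fit about 20 s.

## Known limitations

- The GA treats blocks independently given the shared objective; no
  between-block smoothing is imposed, so sparsely covered blocks are learned
  mostly from their initialization.
- The six-band scale is fixed; finer risk resolution requires redefining the
  bands, not a parameter.
- Training AUROC is optimistically biased (see above); single-number model
  comparisons should use the cross-validated mean.
- The ratio-based modifier uses a hard 50 % threshold, which at a 13 % event
  rate lowers most covered cells by one level; its net effect on AUROC is
  small because near-uniform shifts preserve ranking.
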