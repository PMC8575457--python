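# Methods

## Response quantification

A trial's response is `2 × (N_stim − N_base)` spikes/s: `N_stim` is the
spike count in a 500 ms window starting at odor *delivery* (valve opening
plus a 200 ms air-path delay, both configurable), `N_base` the count in an
equal window anchored 2 s before delivery. Windows are half-open
`[start, end)` so a spike on a shared boundary is counted exactly once. The
factor 2 converts a half-second count difference to a rate; responses can be
negative (odor-evoked suppression) and, for integer counts, are even
integers. All olfactory sensory neurons in a sensillum are summed — no spike
sorting — and both windows must lie inside the recorded span or the trial is
rejected.

Solvent correction subtracts the same sensillum's response to the bare
solvent (water for the acids, paraffin oil for the diagnostics); a missing
odor response stays missing. Two per-sensillum (row-wise) transforms follow:

* **max-normalization** divides by the row's maximum over non-missing
  values, so exactly one odor scores 1 (ties all map to 1; rows with no
  positive value are excluded with a logged warning, never silently kept);
* **z-scoring** centers and scales each row by its mean and *sample*
  (N−1) standard deviation over non-missing values; constant rows are an
  error. The z-score axis is per sensillum across odors — this is what makes
  per-sensillum cluster and PCA structure comparable across animals with
  different absolute firing rates; the per-odor-across-sensilla alternative
  would answer a different question and is not implemented.

Missing cells (`NaN` in the table dialect) mean "recording unavailable" and
are excluded from every row statistic — they are never treated as zero.

## Tuning space

PCA is fitted on the covariance of the z-scored rows (no re-standardization
— the rows are already on a common scale) using complete cases only: any row
with a missing odor value is dropped before the fit. Complete-case deletion
is the reproducible default; a probabilistic PCA for missing data is out of
scope. Components are ordered by explained variance; PC1's sign is fixed so
the C4 loading is ≥ 0, making "larger PC1 = more C4-tuned" a convention
rather than an accident of the solver. A sensillum's scalar phenotype is the
projection of its (complete, z-scored) profile onto PC1. Cluster membership
(C2-max vs C4-max) is decided by directly comparing the z-scored C2 and C4
responses; an exact tie is reported as unclassified rather than broken
arbitrarily — the observed clusters are well separated, so a fitted
clustering algorithm would add machinery without changing a single label.

## Ancestral phenotype states

Discrete tuning states on a rooted tree are reconstructed by unweighted
small parsimony. The bottom-up pass uses Hartigan's multifurcation-safe
rule: an internal node's optimal set contains the states carried by the
maximal number *k* of its children's sets, contributing
(number of children − k) changes; on bifurcating trees this is exactly
Fitch's union/intersection count. The top-down pass reports one optimal
labeling: the root takes the lexicographically smallest member of its set,
and each child keeps its parent's state whenever that state is in its own
set. The change count is invariant under re-rooting (equal change costs);
the labeling is root-dependent, which is why both the count and the
labeling (with the tip-set of each changed branch) are reported. Branch
lengths are parsed but ignored; likelihood-based ancestral *sequence*
reconstruction is a different problem and out of scope.

The built-in fixture is the standard ten-species drosophilid topology
`((((((Dmel,(Dsim,Dsec)),(Dyak,Dere)),Dana),Dpse),Dwil),(Dmoj,Dvir))` with
C2 states for {Dmel, Dsim, Dyak, Dere, Dana, Dpse} and C4 for
{Dsec, Dwil, Dmoj, Dvir}.

## Statistical core

Every two-group comparison runs Shapiro–Wilk on each sample at α = 0.05; if
both pass, Welch's unequal-variance t-test, otherwise a Wilcoxon rank-sum
(Mann–Whitney U). Welch rather than Student because group sizes routinely
differ across genotypes. The rank-sum null is exact for tie-free samples up
to 25 per group and a normal approximation with continuity correction
beyond. Tests are two-sided; directionality (needed for path
classification) is taken from the sample means, separately from the
p-value. Bonferroni correction is `p → min(1, m·p)` with the family size
*m* passed explicitly; `run_landscape` defaults *m* to every comparison it
performs in one invocation (all step tests plus all epistasis tests) — the
most conservative interpretable family — and exposes it as a flag.

## Landscape and epistasis

For *n* substitutions the 2ⁿ genotypes and *n*! single-addition paths are
enumerated exactly (guards at n > 20 and n > 8 respectively). A hypercube
edge is **solid** iff its Bonferroni-corrected p is below α *and* the mean
phenotype increases (toward the derived, C4-tuned state); a significant
decrease stays dashed.

The epistasis test for mutation groups A and B (single+single, or
single+double for the triple-mutant context) takes per-sensillum effects
`a_i = A_i − mean(wt)` and `b_j = B_j − mean(wt)`, draws 1000 index pairs
uniformly with replacement (seeded generator), and forms
`expected_k = mean(wt) + a_{i_k} + b_{j_k}` — the response distribution if
the two effects combined additively. Recentering on `mean(wt)` puts
expected and observed on the same scale; it does not change the rank-sum
p-value. The expected distribution is compared with the observed combined
genotype's values by a two-sided Wilcoxon rank-sum; epistatic iff the
corrected p < 0.05, with negative sign when the observed mean falls short
of the additive expectation.

### Known properties of the bootstrap additivity test

Two behaviors of this procedure matter for interpretation, and both are
verified by simulation in the test suite:

* **It is anti-conservative.** The 1000 bootstrap sums enter the rank-sum
  test as if they were 1000 independent observations, but their center is
  estimated from only ~10 effect values per group plus the initial mean.
  That center error (standard deviation ≈ √3·σ/√n, ≈ 2.7 spikes/s at
  σ = 5, n = 10) is invisible to the rank-sum null, so on perfectly
  additive data the raw test flags "epistasis" in roughly a quarter of
  panels at α = 0.05 rather than 5%. The run-level Bonferroni correction
  absorbs much of this in practice, but single uncorrected calls should be
  read accordingly.
* **The phenotype scale matters.** Per-row z-scoring is nonlinear, so
  effects additive in spikes/s are *not* additive in z-PC1 units; on
  additive synthetic panels the default `pc1` readout produces systematic,
  transform-induced departures from additivity that the test duly flags.
  `run_landscape` therefore exposes three phenotype modes — `pc1`
  (z-scored PCA projection, the standard readout for real recordings),
  `pc1_raw` (PCA of raw corrected responses; linear), and `odor:<name>`
  (single-odor response; linear) — and the package's additivity
  calibration and parameter-recovery checks use the linear modes. Flags on
  the `pc1` scale mean "non-additive on the normalized tuning-shape
  scale", which is a weaker claim than mechanistic interaction.

## Synthetic data

The spike generator is an inhomogeneous Poisson process: baseline rate
everywhere except the 500 ms pulse window, where the evoked rate applies;
per-segment Poisson counts with uniform times. Defaults (baseline 20 Hz,
evoked 60 Hz, 10 s span, onset at 5 s) give the window estimator an
expected value of 2 × (30 − 10) = 40 spikes/s.

The panel generator draws, for every genotype, `n_sensilla` rows of
`baseline(o) + Σ effects + Σ interactions + N(0, σ²)` per odor, with
independent missingness at a configurable rate. Noise is Gaussian rather
than Poisson because panel entries model solvent-corrected *differences* of
counts, which are approximately normal; count-level realism lives in the
spike generator. Defaults — ten sensilla per genotype, σ = 5 spikes/s, no
missing cells — reflect typical single-sensillum recording group sizes and
trial-to-trial variability at these firing rates. The stock
three-substitution configuration (`ir75a_like_config`) starts from a
C2-sensor curve (C2 ≈ 90 spikes/s) and gives each substitution a C2-down /
C4-up shift of 15–30 spikes/s so the triple mutant is a C4 sensor, the
magnitude scale of real tuning switches.

What the generator does *not* emulate: day/animal batch effects, correlated
noise across odors within a sensillum, dose–response structure (a single
1% v/v concentration is assumed), or receptor biophysics. Passing tests
therefore demonstrate correctness of the estimators and decision procedures
under idealized independence, not robustness to those real-data features.

One global seed fans out via `SeedSequence.spawn` to per-component child
seeds (kept below 2³¹), so any stage can be reproduced in isolation.

## Problem sizes and numerics

The test suite and the acceptance script run the stochastic checks at 200
additive panels (calibration), 60 interaction panels (power), 500 spike
trains (estimator bias), and 500 replicates (gated-test level) — sizes at
which the binomial/SEM tolerances asserted are meaningful while the whole
suite stays fast. PCA orthonormality and eigen-equivalence are asserted at
1e-10/1e-8; z-score identities at 1e-12. Degenerate inputs (constant rows,
all-non-positive rows, <2 complete rows, empty samples, oversized mutation
sets) raise typed errors rather than propagating NaNs.
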