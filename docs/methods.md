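# Methods

## The estimator

A larva starved at age x (hr AL3E) pupariates after

    y = β0 + β1·x + β2·max(0, x − τ) + ε,        ε ~ N(0, σ²)

hours.  The model is a *continuous* hinge: the two linear segments join at
the breakpoint τ, which is read as the age at critical weight.  Continuity
is what makes "the inflection point where the relationship changes" a
well-defined single age; a disjoint two-line variant (`continuous=False`)
is provided for sensitivity analysis, reporting the candidate boundary with
the smallest summed RSS.  Neither slope is constrained: post-checkpoint
larvae can pupariate *earlier* when starved, so β1 + β2 may be negative.

Estimation is exact profile least squares.  For fixed τ the design
[1, x, (x−τ)+] is linear, so (β0, β1, β2) have a closed-form OLS solution
and RSS(τ) can be profiled over candidates.  Candidates are placed every
`grid_step` = 0.5 hr between the second-smallest and second-largest
distinct observed ages; a candidate is admissible only when at least two
distinct ages lie on each side (this guarantees a full-rank design).
Observed ages sit on a 2-hr collection schedule, so sub-grid resolution is
needed: around every local minimum of the coarse RSS profile the interval
between its neighbouring candidates (extended to the admissible-region
edge for boundary minima) is scanned densely at `refine_tol` = 0.01 hr.
A dense scan is used rather than golden-section search because RSS(τ) has
kinks at the data ages and is not guaranteed unimodal inside a bracket;
scanning all bracketing intervals of all local minima makes the estimate
agree with an exhaustive dense-grid minimizer (checked on random cohorts in
the acceptance tests) at the same cost.  Ties in RSS are broken to the
smallest τ; a profile that is flat to numerical precision (e.g. a constant
response) additionally raises a `DegenerateFitWarning`.

The per-candidate normal matrices depend only on the ages, which the
resampling schemes below hold fixed, so they are factored once per cohort;
a bootstrap or permutation refit costs a single matrix-vector sweep
(~0.5 ms for 300 larvae).

## Growth conversion

Wet mass is linear in age during the feeding period, so an OLS line of
mass (mg) on age (hr) converts breakpoint ages to masses.  Conversion is
per genotype: a `GrowthFit` carries its group label and refuses to convert
another group's ages unless `allow_cross_group=True`.  Negative predicted
masses (extrapolation outside the feeding period) are returned with an
`ExtrapolationWarning`.

## Resampling

**Bootstrap.**  Ages at starvation are set by the experimenter, so the
default case bootstrap is stratified: larvae are resampled with replacement
*within* each age class, preserving the design's age coverage and keeping
τ identifiable in every replicate (an unstratified mode exists behind
`stratified=False`).  Confidence intervals are equal-tailed percentile
intervals of the bootstrap τ̂ distribution; the mass interval maps every
bootstrap τ̂ through the growth line.  By default the growth line is held
fixed and only the starvation data are resampled — the minimal reading of
"repeat the analysis on bootstrap datasets" applied to the starvation
cohorts; `resample_growth=True` additionally case-resamples the growth
table per replicate, propagating growth-curve uncertainty into the mass
interval.  Replicates whose refit fails are excluded and counted
(`n_failed_boot`); more than 20 % failures aborts with
`UnstableEstimateError`.  Percentile intervals are not guaranteed to
contain the plug-in point estimate; a rare non-containment warns rather
than errors, so long simulation studies are not aborted by one replicate.

**Permutation test.**  The observed statistic is the difference in
breakpoint age (or in converted mass, each group through its own fixed
growth line) between two groups.  Under the null, group labels are
re-assigned uniformly at random among the pooled larvae *within matched
age classes*, preserving each group's per-class sample sizes — both groups
share the same 2-hr starvation design, and stratifying preserves it under
the null.  Two-sided extremeness uses the absolute difference, and the
p-value follows the add-one rule (n_as_extreme + 1)/(n_perm + 1), so it is
never zero.  Age classes present in only one group cannot exchange members
and stay put.

## Time-course conventions

**ΔΔCt.**  Per replicate, ΔCt = Ct_target − Ct_reference (the reference
gene is the internal control run on the same sample); the fold change is
2^−(ΔCt − mean ΔCt of the calibrator cell), with amplification efficiency
fixed at perfect doubling (no efficiency calibration is modelled).
Subtracting the calibrator's arithmetic-mean ΔCt in log2 space fixes the
calibrator's *geometric* mean fold change at exactly 1 (its arithmetic
mean is ≥ 1 by Jensen's inequality); this is the precise sense of
"calibrator = 1" used throughout.  The quantity is invariant to any shift
applied to both Ct channels.

**Windowed letter display.**  Cells (group × time) with ≥ 2 replicates are
compared pairwise by Welch's t test — within a group only when their times
differ by at most the window (default 2 hr), across groups only at equal
times, mirroring how time-course figures annotate "the mean at the time
± 2 hr".  Pairs outside the window are not compared and impose no
constraint on the letters.  Letters are assigned by insert-and-absorb:
start with all cells in one letter column, split every column containing
both members of a significantly different pair, absorb columns that become
subsets.  This guarantees the display invariant — compared-and-different
cells never share a letter, compared-and-indistinguishable cells always
do — which `LetterAssignment.verify()` asserts on every output.  No
multiplicity correction is applied by default (`holm=True` applies Holm's
step-down to the tested pairs).  Zero-variance pairs are decided by their
means.  With two replicates per cell the Welch test has ~1 degree of
freedom and little power; the machinery is agnostic to the replicate
count.

## Synthetic cohorts

`SyntheticConfig` parameterizes the generative model the analysis assumes:
piecewise-linear mean starvation response with Gaussian noise truncated at
zero (a lognormal mode probes skew sensitivity), a linear growth line,
qPCR Ct pairs with a stable reference gene and a target offset by
−log2(fold(t)), and a unimodal Gaussian-shaped hormone pulse sampled in
2-hr classes.  Defaults: hinge at 9 hr AL3E, intercept 50 hr, pre-slope
−1.8 hr/hr, flat plateau (≈ 33.8 hr, the anatomy of wild-type-like
cohorts), noise SD 2 hr, ages 0–24 hr in 2-hr classes, 25 larvae per
class; growth 0.25 mg + 0.07 mg/hr with 0.05 mg noise, putting ~0.86 mg at
the default hinge.  These are illustrative values with realistic structure,
not calibrated to any particular dataset.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: death before pupariation (records support it;
the generator never produces it), non-Gaussian or heteroscedastic response
noise beyond the lognormal flag, plate/batch structure within age classes,
curvature of the growth trajectory near the end of feeding, and
amplification-efficiency variation in qPCR.

## Verification experiments (sizes as run by the test suite)

* exact recovery on noise-free cohorts at three hinge/slope settings;
* agreement of τ̂ with an exhaustive 0.01-hr dense-grid RSS minimizer
  (independent lstsq path) on 100 random 50-larva cohorts;
* 95 % CI coverage over 200 cohorts of 300 larvae (noise SD 2 hr), 300
  bootstrap replicates each — observed coverage ~0.93, within [0.90, 0.99];
* type-I error of the permutation test over 500 null pairs, 199
  permutations each — rejection rate ~0.04, within [0.025, 0.075];
* power ≥ 0.80 against a 4-hr separation in true hinges over 200 pairs;
* the ΔΔCt identities to machine precision;
* letter/decision-matrix consistency on 1000 random matrices against an
  independent brute-force checker.

These sizes keep the full suite in the minutes range on one CPU; the
coverage, calibration and power bands are properties of the procedure, not
of a particular seed.

## Known limitations

* The breakpoint has a non-standard limiting distribution; percentile
  intervals can undercover slightly in small cohorts (observed ~0.93 at
  n = 300).  BCa or studentized intervals are out of scope.
* One breakpoint only; cohorts with two checkpoints need a different model.
* The permutation test assumes exchangeability within age classes under
  the null; strong group differences in response *variance* violate it.
* Pairwise letters are reported without multiplicity correction by
  default, matching the figure convention the display reproduces; use
  `holm=True` when error-rate control across many cells matters.
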