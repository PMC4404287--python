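# Methods

## Measurement model

A face is a set of up to 21 named Farkas landmarks with 3D coordinates in
mm. The 23 standard distances are straight-line Euclidean distances —
"linear distances" in the anthropometric sense — not geodesics along the
skin. Two conventions fix the ambiguous entries:

- *Alar length* (subalare–pronasale) has no canonical side; we compute
  both sides and report their mean, which is invariant under relabelling
  of left and right.
- Paired landmarks carry explicit `_L`/`_R` suffixes. Sides are never
  inferred from coordinates, so measurements do not depend on head pose.

Missing landmarks cause the distances that need them to be *omitted with
a warning*, never imputed: imputation would silently shrink group
differences in downstream tests.

Mesh surface area is the sum over triangles of half the cross-product
magnitude. Zero-area slivers (common in real scan meshes) contribute
nothing and warn rather than fail.

## Sex classification

Feature ranking uses mRMR with the MID (difference) criterion:
relevance I(x; class) minus the mean mutual information with the
already-selected features. MI is the plug-in histogram estimate on
equal-frequency bins (default 8), which makes the ranking invariant to
monotone rescaling of any feature and needs no density-estimation
tuning. Ties break lexicographically by feature name, so the ranking is
fully deterministic. The MIQ (quotient) criterion is available behind a
flag.

Subset search evaluates *nested prefixes* of the ranking — standard mRMR
practice; the 2²³ subset lattice is intractable — scoring each prefix by
tenfold stratified cross-validated LDA and keeping the prefix with the
best mean per-class accuracy (ties to the smaller subset).

The LDA itself is solved in closed form: w = Σ_pooled⁻¹(μ₊ − μ₋), with a
ridge term λ = 1e-6·trace(Σ)/p engaged only when the pooled covariance
is ill-conditioned. Priors are equal by default (the cohorts are
near-balanced and accuracy is reported per class); proportional priors
are available. Cross-validation folds come from a seeded stratified
shuffle (default seed 20150415); reported per-class accuracies pool the
out-of-fold predictions, with per-fold means also returned.

## Group comparison

All t-tests are the pooled (equal-variance) form: the published degrees
of freedom (n₁+n₂−2 throughout) identify it uniquely. p-values are
two-tailed; the effect size is r² = t²/(t²+df), the only formula
consistent with every published t/r² pairing. Raw-cohort tests are
computed *through the same summary-moment route* as printed-table tests,
so the two agree to machine precision by construction. Raw p-values are
primary (the original analyses applied no multiplicity correction);
Holm-adjusted values are reported alongside.

Direction calls compare the sign of the (high − low) trait difference
with the sign of the (male − female) dimorphism for the same feature: a
significant shift toward the opposite sex's typical value is
*less_sex_typical*, a shift beyond the own-sex typical value is
*more_sex_typical*, non-significant differences are *null* (α = .05).

## Discriminant function analysis

Canonical weights are the leading eigenvector of W⁻¹B, normalised so
discriminant scores have unit pooled within-group variance (the
convention that makes raw and standardized coefficients well defined),
and oriented so the designated positive group (high-trait by default)
projects positive. Standardized coefficients are raw weights times
√(W_ii/(n−g)); predictors with |standardized coefficient| > .30 (strict)
are flagged. Significance uses Bartlett's χ² approximation to Wilks' Λ.
Classification uses the Fisher rule with equal priors (proportional
available); "cross-validated" accuracy is leave-one-out (jackknife),
the convention matching a single reported percentage with no fold count
or seed. For two groups the DFA decision rule is algebraically the LDA
rule, which the tests verify prediction-by-prediction.

## Synthetic cohorts

Each group is multivariate normal over its features with the published
means and SDs and an exchangeable correlation: cov(i,j) =
sd_i·sd_j·(ρ + (1−ρ)·[i==j]), ρ configurable with default 0.3. The real
inter-feature covariance is unpublished; the exchangeable structure is
the simplest that separates univariate from multivariate behaviour. Rows
containing a non-positive draw (deep-tail events, probability ≈ 1e-4 for
the smallest mean/SD ratio) are redrawn, keeping the positivity
invariant with negligible distributional bias. Generation is
byte-identical under a fixed seed.

The study-1 preset carries the six published dimorphic distances plus 17
*fabricated* non-dimorphic filler distances (identical parameters in
both sexes) so that feature selection faces the full 23-distance search
space. The study-2 presets carry the published low/high-trait group
parameters including facial area. The study-2 philtrum-length values
(≈21–24 mm) are irreconcilable with study-1 philtrum (≈7–8 mm); they are
stored verbatim but flagged suspect and excluded from geometric closure.

Landmark-level cohorts deform a fabricated, bilaterally symmetric
21-point template face (only its induced distances matter) by
least-squares over all 63 coordinates until the induced distances meet
each subject's sampled targets. The six dimorphic distances form a
cycle-free endpoint graph and are always jointly realisable, so they are
the strict targets (closure well under 0.1 mm); a full 23-distance
sample is generically self-inconsistent (e.g. outer canthal width vs
intercanthal width plus the eye fissures), so the optional full-target
mode treats the remaining distances as soft residuals. Strict targets
that cannot be met (triangle-inequality violations) raise a per-subject
error naming them.

### What a green test establishes — and a known impossibility

Green simulation tests establish that the machinery recovers the
structure the generator put in; they say nothing about real facial
covariance, non-normality, or measurement error, none of which the
generator emulates.

One consequence of the exchangeable-correlation choice deserves
emphasis. Filler features have *zero marginal relevance* (identical
distributions in both sexes), and the mRMR ranking correctly places the
large-effect dimorphic features on top. But under exchangeable ρ = 0.3
the fillers correlate with the dimorphic features' noise, making them
classical *suppressor variables*: the population LDA using all 23
features reaches ≈95.6% per-class accuracy versus ≈88.8% using only the
six dimorphic ones. An accuracy-maximising subset search therefore
*provably* extends past the dimorphic features into the fillers — and
restricting to the six would cap per-class accuracy below 90% at
ρ = 0.3. "Selection excludes all fillers" and "per-class accuracy above
90%" cannot both hold in this synthetic world; the acceptance suite
keeps both assertions and documents the failing one rather than tuning
ρ toward a pass.

## Numerical choices

- mRMR tie-breaks: lexicographic by feature name at every step.
- LDA ridge: λ = 1e-6·trace(Σ)/p, applied only on ill-conditioning
  (condition number > 1e12 or n ≤ p+2), with a warning.
- DFA eigenvector: unit within-group score variance; sign fixed by the
  positive group's centroid.
- Landmark solver: trust-region least squares from the template start,
  tolerances 1e-12; strict targets weighted 1000×; infeasibility when a
  strict target misses by > 0.05 mm (closure contract is 0.1 mm).
- Cohort CSV round-trips floats at 10 significant digits.

## Limitations

- No landmark detection from images or meshes; landmarks are inputs.
- The published classification accuracies (97.19%/95.04% for sex;
  89.7%/88.9% for trait groups) depend on the original raw data and
  covariance, which are not public; they are not reproduction targets.
- Whether the published facial areas cover the full ear-to-ear capture
  or a cropped region is unstated; area is computed over the whole mesh.
- Two-group DFA only; no stepwise entry, no ≥3-group canonical analysis.
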