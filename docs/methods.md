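# Methods

## Data model

A cohort is a pair of aligned tables: a `ConnectomeStack` holding each
subject's Fisher-z rsFC values in edge-major form (subjects × N(N−1)/2,
lexicographic (i,j) pairs, i<j, 0-based; diagonals never stored) and a
`SubjectTable` with age in years, binary sex, five imaging confounds (mean
framewise displacement in mm and four scanner-position coordinates),
optional white-matter measures (mean FA, log-transformed WMH volume) and an
optional nine-assessment cognitive battery. Correlations at |r| ≥ 1 are
clipped to 1−1e−7 before the z-transform so downstream regression never
sees infinities. Quality control keeps subjects whose missing-edge fraction
is ≤ 0.1 and whose per-subject edge standard deviation lies in (0.01, 2.0)
— placeholder bounds, configurable, since acceptable-variation conventions
differ between cohorts — and remaining missing edges are imputed with the
across-subject edge mean, which is a fixed point of the imputation.

## Edge-wise regression

All edges share one design matrix `[1, age_c, (age_c²), sex, confounds]`
with age mean-centered (centering leaves the age slope, its t and p
untouched while conditioning the design; the quadratic term is the square
of centered age). The stack is fit with a single pseudoinverse; per-edge
residual variances give t and two-sided p for the age coefficient. Edges
with zero residual variance are reported as t=0, p=1 with a warning rather
than an error, since a degenerate edge should not abort a 30,000-edge fit.
A quadratic age term is retained only when it is significant at α=0.05
*and* its partial r² reaches 1% — evaluated globally by default (median p
and median partial r² across edges, one decision for the whole connectome)
because the retention rule is stated once for the model, not per edge; a
per-edge mode exists for sensitivity analysis.

The inference matrix `W = {−log10 p_ij}` is masked by the sign of the age
coefficient (default: keep only age-related *decreases*); the signed t and
sign matrices are always retained. Underflowing p-values cap w at 50.

## Subnetwork extraction

The extraction objective is `T(S) = Σ_{i<j∈S} (w_ij − λ)`. The additive
per-edge penalty λ is an interpretable significance floor: an edge
contributes only beyond `−log10` of the edge-level threshold, so sparse or
weakly significant sets score ≤ 0 and are never reported. Default
λ = −log10(0.05) ≈ 1.301.

Search is greedy with local refinement: seed from a maximal remaining edge
(the top 5 seed edges are each tried and the best accepted candidate kept),
grow by the node with the largest positive score gain, then alternate
single-node removals, additions and swaps until no move improves (ties
always break toward the lowest node id, making every run deterministic).
Accepted sets need score > 0 and at least `min_size` = 5 nodes — below
that, candidates are dominated by the permutation null. Accepted nodes are
peeled off (rows/columns zeroed) so successive subnetworks are disjoint.
On random 10–14-node instances the heuristic attains the exhaustive
optimum in ≥ 80% of cases and ≥ 95% of the optimal score always; the
enumerator (`brute_force_best_subgraph`, guarded at N ≤ 15) provides the
oracle.

## Permutation inference

Significance is network-level only. Each permutation shuffles the age
column (and its square, jointly) across subjects while sex, confounds and
connectomes stay attached to their subjects — a Draper–Stoneman-style
scheme that tests the age effect conditional on the observed covariate
structure; Freedman–Lane residual permutation is available as an option.
The permuted pipeline (same direction mask, λ, min_size) yields
`T_k = max` subnetwork score, 0 when nothing is extracted. Observed
subnetworks are ranked against this single max-null with the add-one
estimator `p = (1 + #{T_k ≥ T_obs})/(M + 1)`; with the default M = 1000
the attainable floor is ~0.001.

With the default acceptance gate the procedure is *strictly conservative*
on null data: in 200 simulated null cohorts (n=200, N=60) extraction never
produced a candidate, so the family-wise false-positive rate is ≈ 0, well
below the nominal 0.05. Exact calibration of the permutation machinery is
therefore verified with the gate at its weakest (min_size=2), where every
cohort yields a candidate, the max statistic is continuous, and the
empirical family-wise rate sits on the nominal level (test suite:
200 cohorts, M=99, 99% binomial band around 0.05).

## Mediation, cognition

The paths age → mediator → mean subnetwork rsFC are fit as two OLS
regressions — `mediator ~ age + sex` giving `a`, `outcome ~ age + mediator
+ sex` giving `b` and `c′` — which is exactly the just-identified linear
SEM, so no iterative SEM optimizer is needed. `total = a·b + c′` equals
the total-regression age coefficient identically (linear decomposition),
and `prop_mediated = a·b/total` is invariant to linear rescaling of
mediator or outcome. Uncertainty comes from a subject-resampling bootstrap
(percentile CIs; 95% coverage verified within the binomial band over 200
replicates at n=1000); a Sobel delta-method interval is reported alongside.
Proportions are also exposed on the percent scale. When |total| ≈ 0 the
proportion is flagged unstable rather than suppressed.

The general cognitive score is PC1 of the standardized battery, oriented so
higher = better and scaled to unit variance, with its explained-variance
fraction reported; PCA was chosen over a fitted factor model because a
one-factor battery makes the two equivalent up to scaling, and PC1 is
deterministic. Missing entries are imputed by single-draw predictive mean
matching (linear predictor on the other assessments, k=5 donors, seeded);
multiple imputation is out of scope. The rsFC–cognition association is
`score ~ mean_rsfc + age` by OLS.

## Synthetic cohorts

The generator draws ages uniformly on 44–82 years (the covariate design
matters only through leverage, so the uniform range is preferred over any
cohort's empirical histogram; configurable), Bernoulli(0.5) sex, standard
normal confounds, and Gaussian edge noise (sd 0.3 by default, a typical
edge-level residual scale for Fisher-z rsFC) around a constant 0.25
baseline. Planted node subsets add `beta_age·age_c` (default −0.003 z/yr)
to every intra-subset edge; `beta_age` acts on *centered* age so that an
OLS slope on age in years recovers it in its stated per-year units.
Mediators are standardized latents `a·age_z + noise`, reported on
plausible FA / log-WMH scales; setting `outcome_scale > 0` couples
`c′·age_z + b·mediator` into the first planted subnetwork's edges, making
the implied proportion mediated `a·b/(a·b + c′ + a₂·b₂)` hold in
expectation (scale-free, so `outcome_scale` cancels). By default the
coupling is off so a planted subnetwork's age slope equals `beta_age`
exactly. The cognitive battery loads a single latent factor correlated
(ρ=0.3 by default) with the planted subnetwork's mean connectivity;
equal loadings of 1.4 against unit noise put PC1's expected explained
variance at 70%. Edge missingness is completely at random.

What the generator does *not* emulate: spatial autocorrelation between
parcels, heavy-tailed or heteroscedastic edge noise, realistic age
distributions, correlated missingness, or raw BOLD time series. Passing
tests therefore certify the statistical machinery under the assumed model,
not robustness to real-data violations of it.

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale: the headline
permutation run uses n=300 subjects, N=90 regions and M=999 permutations;
calibration suites use 200 cohorts at n=200/N=60 with M=99; recovery uses
50 seeds at n=500; mediation coverage uses 200 replicates at n=1000 with
499 bootstrap draws. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the pipeline fans one master seed out to the
stages via `SeedSequence`, and reruns with the same config are
bit-identical. Rank deficiency in the design raises an error naming the
collinear columns; brute-force enumeration refuses graphs above 15 nodes;
permutation counts, λ, min_size, QC bounds and bootstrap sizes are all
plain config values.

## Known limitations

The additive-shrinkage objective and greedy search are this package's own
formalization of "dense, high-weight, minimally sized" subnetwork
extraction; other published extraction tools optimize related but not
identical criteria, so node-set boundaries may differ near the
significance floor. Edge-level multiplicity is deliberately uncorrected
(inference is network-level). The mediation model is linear and
cross-sectional; proportions mediated are unstable when the total effect
is near zero and are flagged, not hidden. With small M the add-one p-value
floor `1/(M+1)` bounds attainable significance.
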