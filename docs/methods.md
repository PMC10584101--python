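# Methods

This note documents the models, conventions and design decisions
behind `rnfldecay`, in the spirit of a statistical package's model
documentation: what is computed, under which assumptions, and what the
synthetic validation does and does not demonstrate.

## Coordinate convention

All modules share one angular grid: `n_points` (default 256) equally
spaced points on the peripapillary calculation circle, indexed 1..N in
counterclockwise TSNIT order, with point 1 at the temporal origin
(0°). Point j sits at θ_j = (j−1)·360/N degrees; at N = 256 the
spacing is 1.40625°, reported as 1.41°. Profiles are assumed already
recorded in TSNIT index order for both eyes by the device, so no
laterality mirroring is performed. All public interfaces use degrees;
trigonometry is done in radians internally.

## Profiles and stratification

A profile is one eye's N thickness values (μm) plus age, disc area and
disease status. Profiles containing any value below 30 μm — the
structural measurement floor of circumpapillary SD-OCT — are retained
but flagged `excluded`, so exclusion counts remain reportable.
Stratification uses 3 age bands (40–49, 50–59, ≥ 60 years; cohort
inclusion requires age ≥ 40) × 3 disc-size classes (< 1.6, 1.6–2.6,
> 2.6 mm²). Boundary values 1.6/2.6 mm² fall in Average and ages
50/60 in the older band (ranges read as inclusive).

## Normative catalog and Angular Decay

Each (group, angular point) entry stores the raw thickness sample of
the group's normal eyes; evaluation is the counting eCDF (ties count
with multiplicity, right-continuous). Quantile inversion is type 1
(left-continuous inverse, lower order statistic at ties) so that
quantile∘eCDF is the identity on sample points; with an interpolating
convention the percentile contours could differ by one order
statistic. No smoothing is applied across angles or across strata —
the reference is strictly empirical, which is also why small strata
degrade quantile resolution (a warning is logged below 20 eyes, but no
minimum is enforced).

Angular Decay is the pointwise complement of the normative quantile.
Glaucomatous eyes are ranked against the normal-only catalog of their
own stratum. Normal eyes may be ranked against a catalog that includes
themselves (no leave-one-out correction); for a normal eye this makes
decay exactly uniform on the grid {0, 1/m, …, (m−1)/m} of its group
size m — the probability-integral-transform property the test suite
checks by Kolmogorov–Smirnov.

## Petals and directional summaries

Exceedance is strict (decay > τ); points equal to τ lie outside
petals. The default τ = 0.75 focuses on the last quartile of normative
decay and is exposed everywhere as a parameter. Run-finding treats the
sequence as circular: the temporal origin is never a petal boundary,
so a defect straddling 0° is one petal. Widest-petal ties are broken
by larger summed decay, then by smaller starting index — deterministic
and decay-respecting. μ* weights are the raw decay values of the
member points (not decay − τ), at the grid angles of those points. If
the weighted resultant length falls below 10⁻¹² of the total weight
(possible only for near-uniform full-circle petals), μ* is undefined
and reported NA with a warning. λ* and Λ are petal-width fractions of
the circle; 0 ≤ λ* ≤ Λ ≤ 1 whenever a petal exists, and Λ = 0 exactly
when ν = 0.

## von Mises mixtures

The mixture Σ α_k vM(μ_k, κ_k) is fitted by EM on the μ* angles
(eyes with μ* = NA are excluded and counted). The E-step uses
log-densities computed with exponentially scaled Bessel functions
(stable up to the κ cap); the M-step sets α to mean responsibility,
μ to the responsibility-weighted circular mean, and κ by inverting the
Bessel ratio A(κ) = I₁(κ)/I₀(κ) at the weighted mean resultant length
— Best–Fisher three-regime start refined by 5 Newton steps, capped at
κ = 500 to bound the likelihood for degenerate (repeated-angle) data.
Defaults: 20 random restarts from Dirichlet responsibility draws,
relative tolerance 10⁻⁸, 500 iterations max; non-convergence flags the
fit rather than raising, but any within-run decrease of the
log-likelihood beyond roundoff raises immediately (EM ascent is a
structural invariant, asserted on every iteration). Components are
reported sorted by mean angle so fits are comparable across seeds.

Model order is chosen by minimizing BIC = −2ℓ + (3K − 1) ln n over
K = 1..5 (K means, K concentrations, K−1 free proportions). Clinical
reports of such fits print BIC on package-specific scales that are not
identifiable from the criterion above, so only the argmin over K —
not the BIC magnitude — is treated as comparable across
implementations. The paired-eye analysis uses the
Jammalamadaka–SenGupta circular correlation; it is undefined (raises)
when either series has zero circular variance. The circular
unimodality test sometimes cited alongside such analyses is
deliberately not implemented: no specific test statistic is pinned
down, and guessing one would be worse than omitting it.

## Classification trees

The published comparison used conditional-inference trees; this
package deliberately implements CART-style Gini splitting with
maximal-selection permutation p-values instead — the same report
surface (per-split p-value, per-node Gini and class counts,
specificity with normal as the negative class), a different split
statistic. Consequences: reported specificities are comparable in kind
but not numerically to conditional-inference results. At each node the
best (feature, threshold) pair maximizes the Gini decrease (thresholds
at midpoints between adjacent distinct values); its p-value is the
fraction of label permutations (default 1000) whose *best achievable*
decrease over all features and thresholds matches or beats the
observed one — valid under threshold selection. Splits are accepted at
p < 0.05, to depth 3, with at least 7 samples per node (small trees,
matching the readable clinical-report style).

`class_weight="balanced"` weights samples inversely to class frequency
in split search and leaf voting. This matters because at realistic
prevalence (e.g. 100 glaucomatous among 600 eyes) an unweighted
majority vote labels every leaf normal, which makes specificity
trivially 1 and the model useless; balanced weighting is the standard
CART remedy and is used in the model comparisons. Reported Gini and
class counts stay on raw counts.

Cluster-refined classification partitions eyes before fitting: eyes
with defined μ* go to the von Mises component (fitted on glaucomatous
μ*) with maximal responsibility; eyes with no petal (μ* = NA) form
their own stratum, which typically receives a majority-normal stump.
One tree is fitted per stratum on the local-loss index λ* (NA λ*
encoded as 0 — no petal means no measured local loss), and the
confusion counts are pooled over all eyes.

## Synthetic cohort generator

The generator emulates the statistical structure the framework
assumes, with defaults chosen once to be clinically plausible:

* **Mean curve**: baseline 60 μm plus two von Mises-shaped humps of
  55/62 μm at 80°/280° with shape 2.2 — the TSNIT double hump with
  superior/inferior peaks ≈ 115–122 μm, temporal/nasal troughs
  ≈ 62–72 μm and normal mean thickness ≈ 95 μm.
* **Group effects**: additive offsets of 0/−2.5/−5 μm across age bands
  (mild diffuse age-related thinning) and −2/0/+2 μm across disc-size
  classes.
* **Noise**: per-eye offset (SD 8 μm) plus smooth angular noise — unit
  white noise convolved with a wrap-consistent moving average (window
  from the correlation length, default 5 points, kernel scaled to
  preserve variance) times 6 μm. Values are floored at 30 μm.
* **Metadata**: ages uniform over 40–75; disc areas log-normal around
  2.1 mm² (σ_log 0.22), clipped to 0.8–4.8 mm².
* **Defects**: glaucomatous eyes multiply a healthy profile by
  1 − depth·wedge(θ), the wedge a von Mises bump whose width parameter
  is its full width at half maximum (tapered edges, not a hard
  sector). Default clusters sit at 100° and 290° with width 40° and
  depth 0.5. Each eye's realized defect direction is drawn around its
  cluster center with concentration `direction_kappa` = 12
  (≈ 15–17° between-eye scatter) — without this scatter, synthetic μ*
  modes are point masses far tighter than the concentrated
  (κ ≈ 11–15) clusters real cohorts show, and mixture fitting
  degenerates.

Everything is reproducible from a single seed; the data/metadata/
ground-truth CSVs the CLI writes are byte-identical across reruns.

What the generator does **not** model: biophysical axon-bundle
trajectories, device speckle or segmentation error, inter-eye
correlation within subjects, diffuse (non-focal) glaucomatous
thinning, or age/disc effects on profile *shape* (effects are additive
offsets only). Passing tests therefore demonstrate that the pipeline
recovers planted directional structure under the stated noise model —
not that it would achieve the same accuracy on clinical scans.

## Problem sizes and numerical choices

The validation suite uses cohorts of 500 normal + 100 glaucomatous
eyes (the two-defect-cluster reference conditions), 300-angle mixture
simulations over 20 seeds for the two-component regime, 10³ random
sequences for the petal-tracer oracle comparison and 10⁴ for the loss
index bounds — sizes at which the stochastic checks are stable across
seeds while the whole suite runs in a few minutes. Quantile
probabilities are validated to (0, 1]; τ to (0, 1) strictly; mixture
weights to sum to 1 within 10⁻¹⁰; vm densities integrate to 1 within
10⁻⁸ over the circle for κ from 0 to 50.

## Known limitations

* The normative reference is purely empirical; strata with few eyes
  give coarse quantiles and hence coarse decay values.
* μ* summarizes only the widest petal; eyes with two comparable
  defects are represented by one of them (the wider, or the tie-break
  winner).
* BIC magnitudes are implementation-specific; only the selected K is
  portable.
* In-sample specificity/sensitivity are reported (matching the
  clinical-report style of small audited trees); no cross-validation
  machinery is included.
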