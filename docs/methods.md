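# Methods

This note records the statistical model the package implements, the
defaults and numerical choices, what the simulator does and does not
emulate, and the design decisions taken where the method leaves room.

## Sampling model

A camera watches a circular sector of angle θ out to a truncation
distance w. Time is discretized into snapshot moments t seconds apart
(default t = 3 s); treating each snapshot as an instantaneous point
count removes the bias that animal movement induces in distance
distributions. Effort at camera k is e_k = (θ/2π)(T_k/t) snapshot ×
circle-fraction units, with T_k the deployment span minus one hour at
each end (habituation after set-up, disturbance before retrieval;
deployments shorter than two hours contribute zero effort).

Observed radial distances are assigned to half-open 1-m bins
[c_{j−1}, c_j); distances below the left truncation l or at/above w
are discarded. Left truncation (e.g. 1 m for species that pass under
the camera's view) replaces the disc area πw² by the annulus
π(w² − l²) everywhere.

## Detection function

g(r) = key(r) · (1 + Σ_j a_j s_j(r/w)), clamped at zero and rescaled
so max g over [l, w] is 1. Keys: uniform (no parameters), half-normal
exp(−r²/2σ²), hazard-rate 1 − exp(−(r/σ)^−b) with b > 1. Series
terms use truncation-scaled distance r_s = r/w: cos(jπ r_s), r_s^{2j},
or probabilists' Hermite He_{2j}(r_s). Monotonicity is not enforced —
only non-negativity and the max-rescaling.

The likelihood is multinomial over pooled bin counts with cell
probabilities π_j ∝ ∫_bin r g(r) dr (the r-weighting is point-transect
geometry). Rescaling cancels in π_j, so the optimizer never needs the
max; the detection probability P̂ = ∫ g·2r dr / (w²−l²) does use it.
Bin integrals use a fixed 24-point Gauss–Legendre rule per bin
(exactness far below the 1e−8 verified against adaptive quadrature);
P̂ itself uses adaptive quadrature.

Fitting works in unconstrained coordinates (log σ, log(b−1), raw
coefficients) with L-BFGS-B; σ starts at the mean retained distance,
b at 2.5, coefficients at 0, with 5 jittered restarts before a fit is
declared non-convergent. Non-convergence is a flag, not an exception:
grids proceed and selection excludes flagged models. The parameter
covariance is the inverse observed information (central finite
differences) in the internal coordinates; Wald intervals for σ and b
are computed on the log scale and transformed back, and the delta
method for P̂ differentiates through the same coordinates. Data with
fewer occupied bins than free parameters (or a single occupied bin)
are flagged degenerate without optimization.

## Model selection

Two steps. Step 1, within each key family: ĉ = χ²/df of the family's
most-parameterized converged model; every family member's QAIC =
−2ℓ/ĉ + 2K uses that shared ĉ; lowest QAIC wins the family. K counts
free detection-function parameters only (ĉ excluded). Step 2, across
family winners: smallest ĉ, where each winner's ĉ is its *own* χ²/df —
this is the comparable, per-model quantity the selection table prints.
Ties break by fewer parameters, then lower QAIC.

For the QAIC division ĉ is floored at 1 (configurable): quasi-
likelihood practice does not reward underdispersion. The raw
(unfloored) ĉ is what step 2 compares and what is reported — observed
ĉ below 1 is meaningful evidence of no overdispersion and selecting on
it matches the printed workflow.

The χ² GOF merges bins with expected count below 2 into their inner
neighbour (toward r = 0; the first bin merges outward) before
computing the statistic, df = bins − 1 − K; df ≤ 0 marks the model
untestable rather than erroring.

## Activity level

Clock times of independent events (retained-anchor 30-minute filter
per camera × species; the filter is never applied to distance data)
map linearly to the circle. The von Mises kernel density is evaluated
in exponentially scaled form (no overflow at high concentration), its
peak located on a 512-point grid with bounded local refinement, and
A = 1/(2π max f̂) ∈ (0, 1]. A is rotation-invariant, so anchoring of
clock time (solar vs civil) does not affect it.

Bandwidth: the circular plug-in rule κ* = (3n κ̂² I₂(2κ̂) /
(4√π I₁(κ̂)²))^{2/5} on the von Mises MLE concentration κ̂ (A1-inverse
approximation, capped at 500 for degenerate samples). Near-uniform
samples drive κ* toward 0 and Â toward 1, as they should.

The CI is a percentile bootstrap over event times (default B = 1000,
seeded), with κ* held at its point-estimate value across resamples —
re-selecting the bandwidth per resample roughly quadruples cost for a
negligible change at the sample sizes involved. The interval is
expanded, if ever necessary, to include the point estimate. Whether
the reference workflow's intervals were bootstrap or delta-method is
not documented; bootstrap is used and labelled as such. Activity is
pooled over all cameras per species (one A per species); per-stratum
activity is possible by subsetting but is not the default.

## Density and uncertainty

D̂ = Σn_k / (π(w²−l²) Σe_k P̂) × (1/Â) × s̄, computed per m² and
converted with a single named constant (1e6 m²/km²). Three CV
components combine in quadrature: (i) encounter rate — the
effort-weighted between-camera estimator var(n/E) = K/(E²(K−1)) ·
Σ e_k²(n_k/e_k − n/E)²; (ii) detection — delta method through P̂;
(iii) activity — bootstrap SD over Â. The 95% interval is lognormal,
D̂·exp(±z√ln(1+cv²)) with z = 1.96 (no small-sample t multiplier; the
choice is labelled here because reference workflows vary).

Stratified estimates share the pooled detection function and pooled A
(robustness by pooling); only counts and effort are stratified. A
stratum with zero detections reports D = 0 with a flagged one-sided
interval. A single camera leaves the encounter-rate CV undefined
(flagged) rather than silently zero.

## Simulator

The generator emulates the survey design the package targets: 56
cameras (9 urban / 24 suburban / 23 exurban), θ = 42° (a typical
camera field of view; real surveys must supply their own θ since it is
camera-model-specific), 30-day deployments, t = 3 s, w_max = 10 m,
hazard-rate truth (σ = 2 m, b = 3), density 5 /km² (optionally per
stratum), and a nocturnal von Mises activity schedule whose
concentration is solved from a target activity level A (A = 0.5 ↔
κ ≈ 0.877; closed form A = I₀(κ)e^{−κ}).

Independent mode draws each camera's retained count from the exact
marginal law Poisson(D·A·e_k·πw²·P), distances iid ∝ r·g(r)
(rejection sampling), and clock times iid from the activity schedule
snapped to the snapshot lattice — the per-snapshot thinning model
marginalized analytically, which is why 100-rep validation studies run
in seconds. Correlated-presence mode instead draws cluster entries at
rate λ/μ with geometric cluster sizes (mean μ = 5 snapshots), one
shared distance and consecutive timestamps per cluster: expected
totals are unchanged but bin counts become overdispersed (median ĉ
well above 1 in validation, versus ≈1 for independent mode). A gamma
heterogeneity injector (unit mean, chosen CV) scales per-camera
densities to reproduce large encounter-rate CVs.

What the simulator does **not** emulate: animal movement and home
ranges (distances are redrawn independently, so there is no
within-individual spatial correlation beyond the cluster mode),
imperfect distance measurement and binning error, missed availability
at distance 0 (g(0) = 1 is assumed true), seasonal activity drift, and
camera failure mid-deployment. Passing validation therefore
demonstrates the estimator and its intervals are correct *under the
model's assumptions*; it cannot detect field-data violations such as
responsive movement toward cameras.

## Validation sizes

The test suite and `scripts/acceptance.py` use: 500 replicate fits at
n = 500 for maximum-likelihood recovery and Wald coverage; 100
replicate full surveys for bias, interval coverage and stratified
ordering; 50 paired replicates for the overdispersion contrast; 10,000
draws for the activity closed form. These sizes give Monte-Carlo error
comfortably below the property tolerances (e.g. SE of a 95% coverage
estimate at 100 reps ≈ 2.2 points) while keeping a full validation run
under a minute.

## Known limitations

- Continuous (unbinned) likelihoods are not implemented; bins are the
  native data model.
- No covariates in the detection function, no size-biased group
  correction (group sizes near 1 are assumed), no spatially explicit
  density surface.
- The encounter-rate variance treats cameras as independent points; it
  does not model spatial autocorrelation between nearby cameras.
- QAIC's ĉ is estimated from the same data used for ranking; with few
  occupied bins ĉ is noisy and step 2 can be unstable (the audit trail
  in `SelectionResult.entries` is retained so this is inspectable).
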