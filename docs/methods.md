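# Methods

## The biphasic model family

Both model kinds are split ("bi-") Gaussians: with Δ = x − e (`gaussian`)
or Δ = ln x − ln e (`loggaussian`),

    y(x) = c + (d − c) · exp(−½ (Δ/w)²),   w = b for Δ ≤ 0, w = b·f for Δ > 0.

Parameters and units:

| parameter | meaning | constraint | units |
|---|---|---|---|
| b | left-branch (induction) width | > 0 | dose (gaussian) / log-dose (loggaussian) |
| c | baseline response in both tails | ≥ 0 | response (τ, e.g. BIF) |
| d | peak response E_max | > c | response |
| e | peak location, the MPC | > 0 (loggaussian) | dose |
| f | right/left width ratio (asymmetry) | > 0 | — |

The curve attains exactly d at x = e, tends to c as x → 0⁺ and x → ∞
(log-Gaussian; the dose-0 value is defined as the limit c), and is
symmetric about e in its dose metric iff f = 1. The reading "c = baseline,
d = peak amplitude reference" is fixed by the internal consistency of the
effective-dose arithmetic: the half-peak effect level is (c + d)/2, not
d/2, and only this reading reproduces a consistent (D, E) vector triple
for a fitted curve whose baseline is positive.

## Fractional effects and the two-dimensional effective dose

The fractional effect p ∈ [−100, 100] indexes position on the curve:
p = 0 at the peak, p < 0 on the ascending (induction) branch, p > 0 on the
descending (inhibition) branch, |p| = 100 at the baseline. The effect
component interpolates linearly between peak and baseline,

    E_(p) = c + (1 − |p|/100)(d − c),

and is even in p — the two branches share effect levels. The dose component
inverts the model on the selected branch in closed form: with
s = sqrt(−2 ln(1 − |p|/100)),

    D_(p) = e ∓ b·s / e ± b·f·s            (gaussian, left/right)
    D_(p) = e·exp(∓b·s) / e·exp(±b·f·s)    (loggaussian).

p = ±100 is excluded from dose inversion (the dose is 0 or unbounded);
reporting grids default to [−99, 99]. A Gaussian left branch can formally
cross dose 0 for strong effects; such doses are clipped to 0 with a
warning, and the synthetic-model generators used in the test suite keep
e > 3.1·b so the whole reported range stays positive.

## Fitting

`fit_biphasic` minimizes squared residuals over (b, c, amp, e, f) with
amp = d − c, under bounds b, amp, f > 0, c ≥ 0 (and e > 0 for the
log-Gaussian), using `scipy.optimize.least_squares` (trust-region
reflective). Initial values are moment-based: e₀ at the dose with maximal
mean response, d₀/c₀ from the max/min mean response, b₀ from the half-peak
crossing on the left (span/4 fallback), f₀ = 1; optional multistart jitters
(b₀, f₀) by factors {½, 2}. Non-convergence and degenerate near-flat fits
(amplitude below 10⁻⁶ of the response scale) are returned flagged, never
silently.

The Box-Cox transform-both-sides option applies the same power transform
h(y; λ) to observations and predictions and picks λ on a grid
({−1, −½, 0, 0.33, ½, 1} by default) by maximum profile likelihood,
−n/2·ln(RSS_λ/n) + (λ−1)·Σ ln y. Transformed and untransformed fits are
never compared by raw RSS (the scales are incommensurable): model-kind
selection (`select_model`) always compares candidates on the untransformed
scale and breaks ties toward the log-Gaussian, the usual convention for
concentration data.

With λ = 1 the TBS fit reproduces the plain fit up to optimizer tolerance
(a tested invariant). For data with multiplicative lognormal error the
variance-stabilizing transform is the log (λ = 0); the simulation studies
below fit on that scale. This also removes a pathology of raw-scale least
squares on single-replicate peak data: with few points and proportional
noise, a near-interpolating "spike" (b → 0, f huge) can undercut the
residuals of the genuine peak, whereas on the log scale the low-dose
points carry equal weight and the spike is never optimal.

## Additive mixtures

For a constant-ratio ray with dose fractions j_i (Σ j_i = 1), Loewe
additivity Σ D_i/D_(p),i = 1 rearranges to the predictive form

    D_add(p) = (Σ_i j_i / D_(p),i)⁻¹,

the j-weighted harmonic mean of component effective doses, and the same
structure is projected onto the effect dimension,

    E_add(p) = (Σ_i j_i / E_(p),i)⁻¹.

The effect-dimension weights are an open design point — composition gives
no unique way to apportion *effect* among components — and this package
reuses the dose fractions: it is the only choice computable from the
mixture composition alone, it preserves the structural parallel between
the two dimensions, and it keeps the sham identity exact. (A
`effect_weights` hook is reserved for alternatives.)

Sweeping p yields the additive curve as a parametric (dose, effect) path;
the dose coordinate is strictly increasing in p, so the path is
single-valued in dose. Predicted curves are emitted as (p, dose, effect)
tables, not closed-form functions of dose; consumers interpolate.

Structural guarantees (all tested, several property-based): sham mixtures
of any model, any n, any fractions reproduce the component curve exactly;
outputs are invariant under component permutation; predictions are
equivariant under rescaling of the dose or response units; additive values
always lie within the component range.

## Combination indices

With a biphasic model fitted to the mixture's own data on its total-dose
axis,

    CI_D(p) = D_mix(p) / D_add(p),
    CI_E(p) = E_add(p) / E_mix(p),
    CI_w(p) = CI_D(p) · CI_E(p).

CI_D < 1 means the mixture needs less total dose than additively expected
(synergism in dose). CI_E is oriented so that CI_E < 1 means the mixture
*attains a higher* empirical effect than expected — the orientation that
makes "synergism" consistently mean "more biosensor signal than predicted"
in both dimensions, and that makes counteracting departures cancel in
CI_w (e.g. CI_D = ½, CI_E = 2 → CI_w = 1). The literal ratio
E_mix/E_add is available via `orientation="literal"`. Monotonicity
(tested): raising the mixture peak lowers CI_E; shifting its MPC down
lowers CI_D.

Two departure criteria are implemented:

* **Pharmacological**: a two-sided one-sample t-test of H₀: CI = 1 on
  ln CI across independent replicate values (CI is a positive ratio; the
  null is multiplicative, so the log scale is the natural one), df = n − 1.
  Zero-variance samples at the null return p = 1; off the null, p = 0 with
  a warning.
* **Risk management** on CI_w: < 0.5 synergism, > 2 antagonism, otherwise
  additive (boundaries inclusive to additive).

Replicate-level protocol: single-compound curves are fitted once on all
replicates pooled (the stable reference), the mixture is fitted once per
independent replicate experiment, giving one (CI_D, CI_E) pair per
replicate and p; the pooled mixture fit provides the point estimate.
`polygonogram_summary` tabulates CI_w and its category for all pairs at
representative levels p ∈ {−50, 0, +50}; missing levels are listed as
absent, never imputed.

## Synthetic data

The generator emulates a biosensor mixture experiment: factor-2 serial
dilution series of 7–9 levels, 3–4 independent replicates, constant-ratio
mixture rays anchored at the components' D_(−50) ("1:1" = each component
at equal multiples of its own half-peak induction dose; unequal weights
give 75:25-type rays), and mean-corrected multiplicative lognormal noise
(positive responses with spread roughly proportional to signal; an
additive-Gaussian option exists for robustness checks). D_(−50) is
interpreted as the ascending-branch dose giving the half-peak fractional
effect (p = −50).

Mixture ground truth with imposed (CI_D, CI_E) is the additive curve with
doses multiplied by CI_D and effects divided by CI_E. Because this family
has no closed form in dose, the true curve is tabulated and responses at
requested doses are obtained by monotone linear interpolation. The
tabulation is parameterized by the *branch variable* t rather than p: the
effect fraction is q = exp(−t²/2) and each component dose is
e_i·exp(w_i t) (log-Gaussian) or e_i + w_i t (Gaussian). The p scale
saturates at ±100 in double precision, so no p grid can represent the
curve at strong serial dilutions — truncating there leaves a floor of
(1 − |p|_max/100) of the amplitude, which for an 80-fold induction range
is a ~40% error at baseline and visibly biases fits of the simulated
data. On the t scale the grid [−12, 12] (step 0.01) reaches within ~1e−31
of baseline; doses beyond even that range are clamped with a warning.
Sham, noise-free output matches the component curve to ~1e−5 (linear
interpolation error).

What the generator does *not* emulate: dose-dependent replicate
correlation, plate/edge effects, detection floors, metal speciation
chemistry, or p-dependent interaction profiles (imposed CI values are
constant in p). Passing recovery tests therefore demonstrates correctness
of the estimation machinery under the stated noise model, not robustness
to every feature of laboratory data.

## Simulation studies (test suite conditions)

All studies run inside the ordinary test suite with fixed seeds, sized to
finish in about two minutes in total.

* **Parameter recovery** — log-Gaussian (b=0.4, c=1, d=80, e=2.5, f=0.7),
  8 factor-2 dilutions from 10 (4× the MPC, so the design straddles the
  peak), 3 replicates, 10% CV; 200 simulations. Median relative errors:
  all parameters ≲ 11% (f, the hardest, ~11%; the MPC ~4%).
* **CI recovery** — two distinct log-Gaussian components, constant-ratio
  fractions, imposed (CI_D, CI_E) ∈ {(0.5, 1), (1, 2)}, 10% CV,
  4 mixture replicates, 200 simulations, everything re-fitted from the
  noisy data (singles pooled, mixture pooled, TBS λ = 0). Median estimates
  land within a few percent of the imposed values at p ∈ {−50, 0, +50}.
* **Type-I error** — sham binary mixtures at exact additivity, 10% CV,
  4 single-replicate mixture fits per run, 500 runs; t-test at p = 0.
  The sham design keeps the null exact (a non-sham additive curve is not
  exactly representable by the 5-parameter family, so re-fitting it would
  inject a deterministic model-mismatch bias), and the known component
  model serves as the additive reference so that only replicate-to-
  replicate variation — the quantity the test is about — enters the
  statistic; a fitted reference would be shared across replicates and
  correlate them. Measured rejection ≈ 4–5% in both dimensions, within
  the binomial band around the nominal 5%.

## Numerical choices and edge cases

* Dose 0 observations are retained in fitting; the log-Gaussian evaluates
  them as the limit c.
* Fewer than 5 distinct dose levels is a hard error; a dose range whose
  maximal mean response sits at an edge triggers a "does not straddle the
  peak" warning.
* Degenerate (flat) data yield a flagged non-converged result, not an
  exception; model selection aggregates all-candidate failures into one
  error listing each cause.
* Tie-break in model selection: equal untransformed RSS prefers the
  log-Gaussian.
* CI computations reject non-positive effective doses/effects
  (invalid-state) rather than emitting signed indices.
* All pipeline CSV outputs are deterministic given config + seed, with
  fixed column orders; plots are rendered from quantities that are always
  written as CSV first.

## Known limitations

* The effect-dimension weighting by dose fractions is a modelling choice;
  alternative apportionments would change CI_E for strongly asymmetric
  mixtures (sham results are unaffected).
* Imposed-CI simulations treat CI as constant in p; p-dependent
  interaction patterns can be represented by the analysis (the CI profile
  is computed pointwise) but not yet by the generator.
* Only the two split-Gaussian kinds are provided; monotonic families
  (log-logistic etc.) and independence-based null models (Bliss) are out
  of scope, as is a time dimension in the effective-dose vector.
* The per-replicate mixture fit needs ≥ 5 distinct dose levels per
  replicate; sparser designs fall back to the pooled fit without
  replicate-level inference.
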