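# Methods

## Sand-darkness index

A beach's colour is the per-channel histogram mode of an 85 × 85 RGB
pixel block at the centre of the beach (the zone with the highest nest
density and least vegetation/water contamination).  Ties in a channel's
histogram break toward the smaller (darker) value, which makes the
mode deterministic.  Standardization uses the lightest and darkest
zones of the same image as endpoints: with `D_light` and `D_dark` the
Euclidean RGB distances from the beach colour to those endpoints,

    d = D_light / (D_light + D_dark).

Only the two anchor conditions (`d = 0` at the light endpoint, `d = 1`
at the dark one) are fixed by the problem; among formulas satisfying
them we chose this ratio because it is symmetric in the two distances,
bounded by construction, and strictly monotone along the light→dark
segment in RGB space.  Because both endpoints come from the same image,
the index is invariant to image-wide illumination changes (time of day,
cloud cover), but it is *not* a calibrated albedo: it cannot be
compared across sensors beyond that per-image standardization.

Geometry uses the haversine great-circle distance on a sphere of radius
6371.0 km (mean Earth radius).  A beach's single location for distance
matrices is the arithmetic midpoint of its two endpoints — the same
place the colour was sampled.  At a regional (Central American) scale
the degree-space midpoint is accurate to well under a kilometre; no
antimeridian handling is attempted.

## Nesting-activity model

Counts from regional monitoring databases are extremely sparse (in the
motivating survey, 169 of 1620 beach–year cells).  The model separates
time from space: expected counts `E_ij = T_i p_j` with time-constant
beach shares `p_j`.  That constancy is an assumption forced by the
sparseness, not a biological claim; it is what lets unmonitored years
borrow strength from monitored ones.

The observation model is Gaussian with SD `S_ij = a N_ij + b`,
`a, b > 0` — a variance proxy that grows with the count, using the
*observed* count exactly as specified (a cell observed as 0 has SD
`b`).  Missing cells contribute nothing to the likelihood.  The
synthetic generator, by contrast, scales noise by the latent mean
(`a E_ij + b`), since `N` does not exist before it is drawn; the
mean/observation mismatch is deliberate and probes the estimator's
robustness to its own misspecification.

Numerics: shares are optimized through the additive-logistic
(multinomial-logit) transform (K − 1 unconstrained parameters, interior
of the simplex only — zero shares are approached but never hit);
`T`, `T_0`, `a`, `b` through logs.  The exponential family indexes
years from 0 at the first year, so `T_0` is the total in that year.
L-BFGS-B runs from a method-of-moments start plus (default) 5 seeded
perturbations; the best optimum is kept and the start itself is a
candidate, so the reported value never exceeds the value at
initialization.  `select_models` fits constant → exponential →
year-specific, re-expressing each optimum as a start for the next
family; since the families are nested, this enforces
`−lnL(YS) ≤ −lnL(exp) ≤ −lnL(const)` up to optimizer monotonicity.

AIC is `2k + 2(−lnL)` with `k` = temporal parameters + (K − 1) + 2:
the error parameters `a` and `b` are counted because they are fitted.
Akaike weights are `exp(−Δ/2)` normalized.  When observations number
fewer than parameters the fit proceeds but the results object and its
summary carry an identifiability warning.

Shares below 1e-12 are treated as numerically zero on the log10 scale:
they are excluded from the activity regression and listed in the
result, rather than being patched with pseudo-counts.

## Thermal reaction norms

Sex ratio: `sr(t) = 1/(1 + exp((P − t)/S))`, the symmetric logistic in
which `P` is the pivotal temperature and the transitional range of
temperatures has the closed form `TRT(l) = 2|S| ln((1 − l)/l)`,
verified in the tests against bisection inversion to 1e-9 °C.  (At
`l = 0.05`, `TRT = 2S·ln 19`.)

Hatching success: the double logistic given in the README.  The factor
4 in each exponent makes `S_low`/`S_high` the slope of its limb at the
midpoint.  The falling limb uses the negative-slope parameter
`S_high`; the curve is unimodal whenever the limbs are separated
(`ΔP > 2(S_low + |S_high|)`) and bounded by `MaxHS`.

Fitting is binomial maximum likelihood — females out of *sexed*
hatchlings for the sex ratio, hatched out of *incubated eggs* for
hatching success; records with a zero denominator are ignored.  Model
probabilities are clamped to `[1e-12, 1 − 1e-12]` inside the
log-likelihood so extreme temperatures with observed successes cannot
produce −∞.  Optimization is Nelder–Mead followed by an L-BFGS-B
polish inside the prior box, from a data-driven start (midpoint
crossing of the observed proportions) plus 5 seeded random restarts.

Posteriors use box-uniform priors — the published supports for the
hatching norm; `P ~ U[25, 35]`, `S ~ U[0.01, 5]` for the sex-ratio norm
(unstated in the source analysis; the adopted box spans all reported
turtle pivotal temperatures).  The sampler is component-wise
random-walk Metropolis–Hastings: Gaussian proposals, rejection of
proposals outside the support (exact under a uniform prior), defaults
of 10 000 burn-in and 40 000 retained sweeps, proposal scales started
at a tenth of each prior width and tuned every 200 burn-in sweeps
toward a 0.2–0.5 acceptance rate, then frozen so the retained chain is
non-adaptive.  Chains are bit-reproducible given a seed.  Credible
intervals are equal-tailed quantiles; TRT intervals are computed by
applying the closed form to every retained draw.  Calibration is
checked against the analytic Beta posterior of a binomial toy and the
uniform law of a flat target.

## Spatial statistics

The Mantel statistic is the Pearson correlation of the
strictly-lower-triangle entries of the two matrices; the null permutes
rows and columns of one matrix simultaneously, and the p-value uses the
add-one estimator `(1 + hits)/(1 + n_perm)` (never zero, unbiased
against resampling ties).  The default is one-tailed (greater), since
the scientific hypothesis — nearby beaches are more similar — is
directional.  Full enumeration of all `n!` permutations (n ≤ 8) serves
as the oracle in tests, alongside a cross-check against scikit-bio's
implementation.  A type-I-error experiment (independent darkness, 400
replicates) verifies the 5% level.

The darkness-vs-volcano comparison and the activity regression are
ordinary least squares via statsmodels, compared by AIC with the same
Akaike-weight machinery as the temporal models.  The activity
regression supports both `log10 p_j ~ darkness` and the per-km variant
`log10(p_j / length) ~ darkness`, since nest density per km is the
more comparable quantity across beaches of very different lengths.

## Synthetic scenarios

`ScenarioConfig` defaults emulate the motivating survey's scale: 291
beaches along a ~3000 km coastline, nest counts for 1997–2014 with
observation probability 169/1620 ≈ 0.104, darkness as a Gaussian
random field with a 100 km correlation length (squashed through the
normal CDF) plus an exponentially decaying darkening within ~50 km of
volcanos, shares log-linear in darkness with slope −2, error scale
a = 0.1, b = 2, and reaction-norm truths at the published point
estimates for East Pacific olive ridleys (P = 30.24 °C, S = 0.6521 °C
— the value implied by a 3.84 °C TRT5% — MaxHS = 0.8, P_low = 24.83 °C,
ΔP = 8.74 °C, S_low = 1 °C, S_high = −1 °C; MaxHS and the limb slopes
are not published and were chosen once as values typical of olive
ridley clutches).  Incubation experiments default to 20 constant
temperatures spanning 22–36 °C with 50 eggs each.

Tests and the acceptance suite run reduced problem sizes chosen as
recovery scenarios (e.g. 5 beaches × 10 years at 70 % observation;
17 temperatures × 20 eggs), which keep the full suite under two
minutes while still exercising every stage end to end.

What the generator does *not* emulate: arribada over-dispersion
(mass-nesting counts are far noisier than Gaussian), inter-annual
drift in beach shares, observer effort correlated with nesting volume,
image-to-image sensor differences, and philopatry feedback across
generations.  Passing recovery tests therefore show the estimators are
correct under the model's own assumptions, not that the assumptions
hold for any particular real rookery.

## Known limitations

- The year-specific family at realistic sparseness has more parameters
  than observations per year in some years; the identifiability
  warning is the only guard, matching the method's intended use as an
  index rather than an inferential model for `T_i`.
- The Gaussian count likelihood admits positive density at negative
  counts; with the fitted `a`, `b` this mass is negligible, but the
  model is not a true counting process.
- Metropolis–Hastings here is single-chain; no cross-chain convergence
  statistic (R-hat) is computed.  The adaptive phase is frozen before
  retention, but short chains on multimodal posteriors remain the
  user's responsibility.
- The per-image colour standardization corrects illumination, not
  sensor spectral response; darkness values are comparable within a
  survey, weaker across surveys.
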