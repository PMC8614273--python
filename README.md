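# nestnorm

Statistical tools for the spatial ecology of sea-turtle nesting beaches:
why do some beaches in a region host thousands of olive ridley
(*Lepidochelys olivacea*) nests a year while nearby beaches host almost
none?  Two temperature-mediated mechanisms compete as explanations.
Dark volcanic sand absorbs more solar radiation, incubates nests warmer,
and — because marine turtles have temperature-dependent sex
determination with females produced at warm temperatures — should
feminize clutches; combined with natal philopatry, dark beaches should
accumulate nesting females.  But the same heat kills embryos, so dark
beaches may instead simply produce fewer hatchlings.  `nestnorm`
implements the quantitative pipeline needed to confront these
hypotheses with data: sand-darkness scoring, a sparse spatio-temporal
nesting-activity model, spatial permutation tests, and thermal reaction
norms for sex ratio and hatching success.

## What it computes

**Sand darkness** (`nestnorm.beach_color`).  Each beach is scored from
the per-channel modal RGB colour of a pixel block at its centre,
standardized against the lightest and darkest zones of the same image:
`d = D_light / (D_light + D_dark)` with `D` Euclidean distances in RGB
space, so `d = 0` at the white endpoint and `d = 1` at the black
endpoint (an inverse albedo proxy).

**Nesting activity** (`nestnorm.nesting`).  Observed nest counts
`N_ij` (year *i*, beach *j*) are modelled through expected counts
`E_ij = T_i · p_j`, where the yearly regional totals `T_i` follow one of
three families — constant `T`, exponential `T_0·e^{r·i}`, or
year-specific `T_1..T_Y` — and `p_j` are time-constant beach shares on
the simplex (K − 1 free parameters).  Observations enter a Gaussian
likelihood with SD `S_ij = a·N_ij + b` (a, b > 0); families are
compared by AIC and Akaike weights, and unobserved cells are imputed
with `E_ij` (observed counts are always preferred).

**Thermal reaction norms** (`nestnorm.norms`).  The female proportion
at constant incubation temperature *t* is the logistic
`sr(t) = 1/(1 + e^{(P−t)/S})` with pivotal temperature `P` (`sr(P) = ½`)
and transitional range of temperatures
`TRT(l) = 2|S|·ln((1−l)/l)` centred on `P`.  Hatching success is a
scaled product of rising and falling logistics,
`HS(t) = MaxHS · [1 + e^{4(P_low−t)/S_low}]⁻¹ · [1 + e^{4(P_low+ΔP−t)/S_high}]⁻¹`,
null at both thermal extremes.  Both norms are fitted by binomial
maximum likelihood; credible intervals come from a component-wise
random-walk Metropolis–Hastings sampler under box-uniform priors
(`P_low ~ U[20,40]`, `S_low ~ U[0,5]`, `MaxHS ~ U[0,1]`,
`ΔP ~ U[0,10]`, `S_high ~ U[−5,0]`).

**Spatial statistics** (`nestnorm.spatial`).  A Mantel permutation test
(9999 permutations by default, add-one p-value) of geographic distance
against pairwise darkness difference; an AIC comparison of
`darkness ~ distance to nearest Holocene volcano` against an
intercept-only model; and OLS of `log10 p_j` on darkness (optionally
per km of beach).

**Synthetic data** (`nestnorm.simulate`).  A seeded scenario generator
producing beaches with spatially autocorrelated darkness, sparse nest
counts from the `T_i · p_j` process, and binomial incubation outcomes
from the two reaction norms — the test bed for parameter-recovery
validation of every stage.

## Worked example

```python
import nestnorm as nn
from nestnorm.simulate import ScenarioConfig, gen_beaches, gen_nest_counts, gen_incubation

cfg = ScenarioConfig(seed=1, n_beaches=6, years=tuple(range(2005, 2013)), obs_prob=0.7)
beaches, volcanos = gen_beaches(cfg)
table = nn.NestCountTable.from_dataframe(gen_nest_counts(cfg, beaches))

selection, best = nn.select_models(table, seed=1)
print(selection.round(3).to_string(index=False))
```

```
        model     aic  delta_aic  akaike_weight
     constant 468.060     55.280            0.0
  exponential 452.431     39.651            0.0
year_specific 412.780      0.000            1.0
```

The year-specific family wins decisively (Akaike weight 1.0): the
simulated totals vary strongly between years, and the AIC penalty for
its extra parameters is more than repaid.  `best.summary()` lists the
fitted yearly totals `T_i` and beach shares `p_j`; `best.index()`
returns the filled beach × year matrix (observed counts kept, missing
cells imputed with `T_i·p_j`) and the `log10 p_j` index used in the
darkness regression.

```python
data = nn.IncubationDataset(gen_incubation(cfg))
res = nn.SexRatioModel(data).fit(seed=1)
t = res.trt()
print(f"P = {res.params[0]:.2f}, TRT5% {t.lower:.2f}-{t.upper:.2f} °C (width {t.width:.2f})")

chain = res.sample_posterior(nn.MCMCConfig(n_iter=20_000, burn_in=5_000, seed=1))
lo, hi = nn.credible_interval(chain, "P")
print(f"pivotal temperature 95% CI: {lo:.2f}-{hi:.2f} °C")
```

```
P = 30.30, TRT5% 28.42-32.17 °C (width 3.75)
pivotal temperature 95% CI: 30.07-30.51 °C
```

The fit recovers the scenario's generating pivotal temperature
(30.24 °C) within 0.06 °C from 20 eggs per temperature, and the
credible interval comfortably covers it.

A command-line interface mirrors the library:

```sh
nestnorm simulate --seed 1 --out-dir data/
nestnorm index  --nests data/nests.csv --seed 42 --out fit.json
nestnorm mantel --beaches data/beaches.csv --n-perm 9999 --seed 7
nestnorm norms  --data data/incubation.csv --which sex_ratio --mcmc 40000 --seed 1 --out norm.json
nestnorm regress --beaches data/beaches.csv --index fit.json --volcanos data/volcanos.csv
```

Every JSON artifact embeds a manifest (input hashes, settings, seed,
package version) sufficient to reproduce it exactly.

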