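# Methods

This note documents the models implemented in `entch4`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions.

## The measurement problem

Enteric CH4 from dairy cows is measured accurately in respiration
chambers or ventilated head boxes, but those are too costly for
routine herd-scale recording. The sniffer method instead samples air
at the feed bin of an automatic milking system (AMS) while the cow is
milked and uses breath CO2 as a tracer: the CH4/CO2 volume ratio of
the background-corrected breath, multiplied by the cow's (predicted or
measured) daily CO2 output, estimates daily CH4. Alternatively, the
ratio enters multiple-regression equations alongside easily recorded
covariates (live weight, energy-corrected milk, dry matter intake).

## Formulas

- **ECM** (Tyrrell & Reid energy standardization):
  `ECM = milk × (376·fat% + 209·protein% + 948)/3138` (kg/day).
- **Days in pregnancy** when breeding records are absent: cows are
  assumed pregnant from 126 days in milk (a 406-day median calving
  interval minus 280-day gestation), so `DIP = clamp(DIM − 126, 0,
  280)`. The 280-day cap is this package's choice: DIP cannot exceed
  gestation length, and without it the linear rule extrapolates
  without bound for long lactations. Its effect is negligible
  (1.6·10⁻³ per day inside a ~1.4·10³ quantity).
- **HPU** (CIGR heat-production model):
  `HPU = (5.6 LW^0.75 + 22 ECM + 1.6e-3 DIP)/1000` (×10³ W), with a
  fixed CO2 equivalent of 180 L/h per HPU; daily CH4 by the tracer
  route is `ratio × 180 × HPU × 24`.
- **MCF**: `(CH4 [L/day] × E_CH4 [kJ/L] / 1000) / GEI [MJ/day] × 100`
  (J/100 J). The methane gross energy density `E_CH4` defaults to the
  Brouwer combustion constant 39.54 kJ/L and is an explicit parameter;
  this value makes the bundled worked example internally consistent
  (618 L/day at 474 MJ/day → 5.15 J/100 J).
- **Bundled equations** (`data/published_equations.yaml`): stored at
  printed precision, never re-derived at import. Note an internal
  inconsistency of the published set that users should know about: the
  LW+ECM+ratio equation evaluated at the published covariate means
  gives ≈ 524 L/day, while the published panel mean emission is 471
  L/day (the DMI-only equation at mean DMI does return 471); the
  fitting panel's internal ECM mean evidently differed from the
  printed summary. The package reproduces each number from its own
  printed inputs and does not attempt to reconcile them.

## Sniffer trace processing

Concentrations are ppm internally; percent inputs are converted on
read (1% = 10,000 ppm).

1. **Background**: mean CH4 and CO2 over a 5-min cow-free window.
   Both "before" and "after" milking are legitimate; the default rule
   is pre-visit if available, else post-visit, averaging the two when
   both exist. Windows under 60 s are rejected.
2. **Head-position filter**: second *i* is retained iff
   `CO2[i] − bg ≥ 500 ppm`. The threshold separates breath plume from
   barn air; it is configurable. Corrected CH4 is clipped at 0
   (analyzer noise can dip below background).
3. **Visit ratio**: ratio of the corrected means over retained
   seconds ("averaged at each visit, then the ratio"), not the mean of
   per-second ratios; the latter is available behind a flag for
   sensitivity analysis (it up-weights low-CO2 seconds where the ratio
   is noisiest). A visit needs ≥ 60 retained seconds (one minute of
   near-bin breathing) to be valid — the minimum stabilizes the ratio
   and is this package's choice.
4. **Eructation rate**: belches appear as brief CH4 bursts, hence
   peaks in the per-second CH4/CO2 series. The detector (scipy
   `find_peaks`) requires prominence ≥ max(0.25 × median of the
   positive ratio series, 3 × robust noise SD) and ≥ 10 s spacing;
   both are configurable. The noise SD comes from the median absolute
   successive difference (insensitive to the spikes themselves). The
   relative prominence floor scales with the cow's baseline ratio; the
   absolute floor suppresses noise peaks on flat stretches; 10 s
   reflects the physiological refractory spacing of eructation. On
   realistic synthetic traces these defaults recover a true 1.1/min
   within the 0.9–1.4/min physiological band. The per-second ratio is
   computed on retained (filtered) seconds only, with gaps bridged,
   and the per-visit rate is normalized by retained time — normalizing
   by wall-clock visit time would under-count by exactly the head-away
   fraction.
5. **Time after eating**: hours from the end of the last 10-min
   activity bin labelled "eating" (ending at or before the visit) to
   visit start. Ties in dominant-activity bins break in favour of
   eating, which conservatively shortens the covariate. Visits with no
   prior eating are flagged missing rather than given a value.
6. **Adjustment to 0 h**: the measured ratio declines approximately
   linearly with time after eating over the 0–8 h range. Given the
   fitted mixed model, `ratio₀ = ratio − (β_time + β_time×diet)·t`.
   This is exactly the inverse of the generator's decay, which the
   tests exploit.

## Head-box flux

Per-second emission (L/s of pure gas) is `flow/60 × excess_ppm ×
10⁻⁶` with flow in L/min at 0 °C, 1 atm (no temperature/pressure
normalization layer: the instrument is assumed to report standardized
flow). Totals over the 15-min measurement extrapolate to daily
emission by 1440/15 = 96. Traces deviating from 900 s are pro-rated,
with a warning beyond ±60 s. Recovery-test factors (measured/injected
CO2) are computed but **not** applied by default — correction is
opt-in (`recovery_factor`), since recovery rates near 100% are
routinely reported without being used as corrections. Where a cow has
several 15-min measurements per period, the pipeline averages them per
cow-period and records n.

## Statistical layer

- **Equation development**: OLS via statsmodels. Adjusted R² =
  1 − (1 − R²)(n − 1)/(n − p − 1); RMSE = √(SSE/(n − p − 1)) — the
  regression root mean square error, matching standard GLM software
  output (√(SSE/n) is a plausible rival convention and is not used).
  VIFs come from auxiliary regressions of each covariate on the
  others; orthogonal covariates give exactly 1. Rank-deficient designs
  raise a collinearity error rather than silently pseudo-inverting.
- **Time-after-eating model**: linear mixed model by REML
  (statsmodels MixedLM), fixed effects time + time×diet + diet with
  the high-fibre diet as reference level, random intercepts for Latin
  square (grouping factor) and cow within square (variance
  component). Fits whose variance components collapse below 10⁻⁴ ×
  residual variance are returned with a `boundary` flag rather than
  raised — with only two squares the square variance is weakly
  identified, which is a property of the design, not the fitter.
  Covariance-structure selection is implemented as an AIC choice
  between the full model and the model without the cow intercept
  (a cow random intercept induces compound symmetry within cow;
  these are the two structures expressible without modelling
  per-visit serial correlation). `random_effects=False` fits the same
  fixed design by OLS — the zero-variance-component limit used as an
  oracle in the tests.
- **Through-origin regression**: slope = Σxy/Σx² in closed form;
  RMSE with n − 1 df; uncentered adjusted R². Used for all
  predicted-vs-observed agreement summaries (slope 1 = proportionally
  unbiased).
- **Residual-vs-DIM diagnostic**: OLS of (observed − predicted) on
  days in milk with a pointwise 95% prediction band; points outside
  the band are flagged. A positive slope with early-lactation points
  below the band is the signature of fixed-HPU overestimation in
  early lactation (body-fat mobilization lowers the true CO2-per-HPU).

## Synthetic data: what it does and does not emulate

Generator defaults are the documented study conditions: panel n = 121
with DMI 16.7 ± 3.68, ECM 27.4 ± 6.78, ratio 0.088 ± 0.0119 and
correlations r(LW,DMI) = 0.51, r(LW,ECM) = 0.32, r(DMI,ECM) = 0.80;
emission noise SD 40.8 L/day (the published residual scale of the
LW+ECM+ratio equation); visit-level ratio model with intercept 0.102,
slope −0.0034/h, diet offsets LF −0.026 / MF −0.016, interaction
slopes 0.00015/h, cow SD 0.005, residual SD 0.005; eructation rate
1.1/min; head-box flow ~520 L/min. Values the sources leave
unspecified were fixed once at field-realistic levels: LW ~
Normal(650, 50) kg truncated to [400, 900] (the feeding-trial cows
were 647 ± 36.7 kg); ratio-covariate correlations 0; breath CO2
excess 3,470 ppm (the fitted corrected-CO2 intercept of 0.347%);
head-away fraction 0.15; analyzer noise 50 ppm CO2 / 2 ppm CH4;
square SD 0.002; AMS visits 420 s; eructation spikes as a renewal
process with 10-s dead time plus exponential tail (mean chosen so the
long-run rate is exact) and lognormal amplitudes (median 1× the
baseline ratio, σ = 0.3), shaped as 5-s triangular pulses re-centred
so the latent ratio stays the expected ratio-of-means.

Deliberate simplifications — and therefore limits on what passing
tests show about real data:

- The ratio's time decay is linear with no diurnal (Fourier-type)
  structure; real diurnal patterns are nonlinear.
- Breath CO2 excess is constant within a visit except for head-away
  gaps; real plumes fluctuate with breathing and head position.
- Eructation spikes are re-centred so they carry no net CH4 mass
  relative to the latent ratio; in reality belches carry a large CH4
  share, and the AMS-vs-head-box diffusion attenuation (the residual
  ~8% deficit after 0-h adjustment) is **not** modelled — the
  generator's AMS and head-box latent ratios agree by construction.
- No rumen fermentation kinetics, meal-size effects, or energy
  balance; cow effects are exchangeable Gaussian intercepts.
- Activity logs are deterministic bouts after scheduled feedings, not
  behaviour.

Every generator is bit-reproducible under a fixed seed (default
20210930); all stochastic routines take a seed or Generator.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
panel refits use n = 10,000 (20 replicates for the averaged recovery
check), mixed-model recovery uses 2 squares × 3 cows × 3 diets × 60
visits (1,080 rows), trace-level checks use 40–60 simulated visits of
420 s, and mass-balance checks 100 head-box replicates. These sizes
put Monte-Carlo error well inside the documented tolerances while the
whole suite completes in seconds. Tolerances on recovery tests are
2 Monte-Carlo SEs (coefficients) or 1–3% (means over replicates);
oracle-equivalence checks are at 10⁻⁸ relative. Degenerate inputs
(empty traces, all-zero x, single diet level, rank-deficient designs)
are exercised explicitly; ties and boundaries follow the rules stated
above (≥ 500 ppm keeps the second; a bout ending exactly at visit
start gives 0 h; eating wins dominant-activity ties).
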