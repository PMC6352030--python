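# Methods

## Problem and quantities

Osmotic dehydration (OD) removes water from plant tissue immersed in a
hypertonic solution while some of the osmotic agent diffuses in.  Given
a sample's initial state `(m0, s0)` (mass in g, dry-matter mass
fraction) and its state `(m, s)` after `tau` minutes of immersion, the
package computes five descriptors on a dry-matter basis:

- water content `WC = (1 - s)/s` (g water per g dry matter);
- solid gain `SG = (s*m - s0*m0)/(s0*m0)` (g solids taken up per g
  initial dry matter);
- water loss `WL = [(1-s0)*m0 - (1-s)*m]/(s0*m0)`;
- true water loss `WL_T = WL/(1 + SG)` — water removed per gram of the
  dry matter *actually present*, so concurrent solute uptake no longer
  inflates the apparent dehydration;
- the ratio `CR = WL_T/WL = 1/(1 + SG)`, which is near 1 when
  dehydration proceeds with little impregnation and falls towards 0 as
  uptake dominates.

`WL` and `SG` can be negative (swelling, leaching); they are retained
and logged, never clipped.  `CR` is 0/0 at `tau = 0` and is reported as
missing there; when the ratio is modelled, the exact anchor `CR(0) = 1`
is supplied to the fit instead.

The rendering of WC deserves a note: the dry-basis form `(1 - s)/s` is
used because it reproduces the characteristic fresh-apple value of
5.69 g H2O/g d.m. at `s = 0.1495` and is the standard dry-basis
definition.  An alternative per-initial-dry-matter bookkeeping,
`(1 - s)*m/(s0*m0)`, is available via `water_content_per_initial_dm`
and the `wc_per_initial_dm` switch of `kinetics_table`.

Descriptors are computed per replicate and then averaged over
replicates per (solute, time); model fitting consumes the averaged
series by default (per-replicate series remain available).

## Kinetic models

Three empirical families describe a response `Y(tau)`:

- **Peleg** `Y = Y0 ± tau/(k1 + k2*tau)`: `1/k1` is the initial rate,
  `Y0 ± 1/k2` the equilibrium value.  The sign is an explicit
  `direction` (+1 rising, −1 falling).  `Y0` is *fixed* by default (to
  the measured initial value for WC, 0 for WL/SG/WL_T, 1 for CR);
  freeing it is an option.
- **Kelvin–Voigt** `Y = A(1 − e^(−tau/B))`: single-exponential
  saturation to `A` with time constant `B` (min).  The rate form
  `A(1 − e^(−K*tau))` with `K = 1/B` is the same curve and agrees to
  machine precision.  We use the standard time-constant convention:
  63.2% of the equilibrium is attained at `tau = B` (36.8% remains) —
  a "37%" phrasing occasionally seen in the literature refers to this
  remaining fraction.
- **Burgers** `Y = A(1 − e^(−tau/B)) + C*tau`: Kelvin–Voigt plus a
  constant-rate term.  `C >= 0` by default (physically a sustained
  uptake/loss phase; an unconstrained mode exists for diagnostics).
  With `C = 0` it reduces exactly to Kelvin–Voigt, which the tests
  exploit as a nesting check.

Time is minutes throughout.  Table conventions that label the Peleg
constants with hour-based units are treated as display metadata; all
fitted magnitudes here are per-minute.

## Fitting

`scipy.optimize.least_squares` (trust-region reflective, bounds
`k1, k2, B >= 1e-9`, `C >= 0`, `x_scale='jac'`, ftol/xtol/gtol 1e-12)
minimizes the residual sum of squares.  Seeds are closed-form:

- Peleg: the model linearizes exactly as `tau/|Y − Y0| = k1 + k2*tau`;
  ordinary regression gives the seed (exact on noise-free data).
- Kelvin–Voigt: plateau seeded at `1.05 * max|Y|`; the time constant
  from the earliest informative point,
  `B = −tau_1/ln(1 − Y_1/A_seed)`.  Using only the first point is
  deliberate: with the plateau deliberately inflated by 5%, later
  points sit in a regime where the log transform reflects the inflation
  rather than the decay, and a whole-grid log-linear slope can misjudge
  `B` by tens of percent even on exact data, while the first point
  stays within ~10%.
- Burgers: the Kelvin–Voigt seed plus `C` from the trailing two-point
  slope in excess of the seeded saturation curve, floored at 0.

If the first start does not reach an essentially zero cost, up to three
restarts are taken from multiplicatively jittered seeds drawn with a
fixed-seed RNG, keeping the best cost — so fitting is deterministic for
identical inputs and options, and invariant to row order (series are
sorted internally).  Non-convergence raises a `FitError` carrying the
optimizer diagnostics; in batch reports failed fits become flagged rows
(`fit_ok=False`) rather than exceptions.

### Fit statistics

For `N` points, `n` free parameters, residuals `e_i = pred_i − obs_i`:

- `R^2 = 1 − SS_res/SS_tot` (the standard definition; a historical
  ratio form `sum(pred − mean_pred)^2 / sum(obs − mean_pred)^2` is kept
  as the `r2_ratio_form` diagnostic);
- reduced chi-squared `chi2 = SS_res/(N − n)`;
- `RMSE = sqrt(SS_res/N)` — hence the identity
  `chi2*(N − n) = N*RMSE^2`, asserted on every fit;
- `CRV = 100 * sqrt(chi2) / mean(obs)` in percent; **CRV < 20%** marks
  the fit usable for prediction, larger values descriptive only.

`N` counts the fitted points of the averaged series *including* the
`tau = 0` anchor for responses with a known initial value; on the
standard 0–180 min grid with 30-min steps, `N = 7`.

## Treatment statistics

Factorial inference follows the classical recipe at `alpha = 0.05`:

- **ANOVA**: main effects only by default (solute, time), type II sums
  of squares via statsmodels OLS.  F and p are recomputed from the SS
  table so degenerate designs behave predictably: a residual mean
  square at floating-point zero yields `F = inf, p = 0` for factors
  with signal and `NaN` when nothing varies; zero error degrees of
  freedom raise.  An interaction term is available with replication.
- **Tukey HSD**: every pairwise contrast of a factor shares the
  half-width `q_{alpha,k,df} * sqrt(MS_E/ñ)`, `ñ` the harmonic mean of
  the two group sizes (Tukey–Kramer for mild imbalance); a contrast is
  significant iff `|difference| > limit`.  Studentized-range quantiles
  come from `scipy.stats.studentized_range` and are validated against
  published q-tables (k ≤ 6, df ≤ 30) to 0.01.  Letters use the
  insert-and-absorb compact letter display, ordered so `a` is the
  lowest-mean group; levels sharing a letter do not differ
  significantly, a property asserted against the contrast table.
- **Pearson correlation** (e.g. water activity vs water content):
  `scipy.stats.pearsonr`, requiring n ≥ 3 and nonzero variance.

## Synthetic studies

`generate_study` emulates a five-solute immersion experiment: apple-like
samples in 30% erythritol/xylitol/maltitol/DHA and 50% sucrose, grid
0–180 min at 30-min steps, two technological replicates, nominal sample
mass 20 g and initial dry fraction `s0 = 0.1495` (WC0 = 5.69 g/g d.m.).
True WL/SG trajectories come from per-solute model presets chosen so
the study reproduces the canonical qualitative ordering (sucrose the
highest WL and SG with a pronounced constant-rate phase; maltitol the
lowest WL).  The mass-balance relations are inverted exactly —

    m = s0*m0*(1+SG) + (1−s0)*m0 − WL*s0*m0,  s = s0*m0*(1+SG)/m

— so a round trip through `solid_gain`/`water_loss` is the identity to
1e-12, and infeasible trajectories (implied `s` outside (0, 1] or
`m <= 0`) raise before any noise is drawn.

Noise is additive Gaussian, independently on mass (sd 0.05 g, a typical
balance) and dry fraction (sd 0.002, typical oven-drying repeatability);
per-replicate initial masses are drawn with sd 0.7 g around 20 g,
keeping essentially all samples within the nominal ±2 g.  Draws that
leave the valid region are resampled (up to 100 tries) before clipping,
to avoid bias near the boundaries.  `tau = 0` rows restate the initial
state exactly — the initial weighing *is* the time-zero measurement —
so the generated WC at time zero equals `(1 − s0)/s0` for every solute.
A fixed seed reproduces the study byte-for-byte.

What the generator does **not** emulate: real tissue variability
between replicates beyond the initial-mass draw, structural changes
(cell breakdown altering diffusivity mid-run), correlated errors
between mass and dry-matter determinations, or water-activity dynamics
(only an optional linear-in-WC proxy with noise is provided, for
exercising the correlation machinery).  Passing recovery tests
therefore demonstrate that the estimation pipeline is correct and well
calibrated under the stated error model, not that any particular real
tissue obeys these models.

## Verification strategy and problem sizes

- Noise-free closure: series generated from published fitted parameters
  on the 7-point grid are re-fitted and must return each parameter to
  0.1% relative (`scripts/acceptance.py` recomputes these end to end).
- Zero-noise end-to-end: `generate_study` → `kinetics_table` →
  `fit_model` reproduces every generating parameter to 1e-4 relative.
- Noisy recovery: 200 simulated studies under the default noise model;
  the median relative error of the Peleg constants stays below 10%.
- Null calibration: 1000 simulated balanced 5×6×2 Gaussian-null studies;
  the solute main effect rejects at 5% ± 2%.
- Property tests (hypothesis, derandomized): mass-balance identities,
  `CR*(1+SG) = 1`, model-form equivalences, letter/contrast
  consistency, reader/writer round trips.

These sizes keep the full suite under a minute on one CPU while leaving
the Monte-Carlo margins comfortably wide.

## Known limitations

- Only additive Gaussian measurement error is modelled; real dry-matter
  determinations can have multiplicative or correlated errors.
- No uncertainty intervals on fitted parameters and no AIC/BIC model
  selection; families are compared by CRV, then RMSE.
- The Burgers `C >= 0` default reflects the uptake/loss physics of OD;
  genuinely decreasing constant-rate phases need the unconstrained mode.
- Tukey letters assume the homoscedastic ANOVA error; no Welch-type
  correction is offered.
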