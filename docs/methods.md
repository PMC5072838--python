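# Methods

## Competition model and selection coefficients

One selection cycle is batch growth followed by capillary chemotaxis
selection. Growth of a mutant/wildtype pair is modelled by Lotka-Volterra
competition with shared saturation,

    dm/dt = r_m m (1 − (m + w)/k),   dw/dt = r_w w (1 − (m + w)/k),

with abundances as fractions of the carrying capacity k (default 1) and
rates in h⁻¹. Growth selection over the 11.5-h phase is the change in the
natural-log abundance ratio, s_g = ln(m_T/w_T) − ln(m_0/w_0), obtained by
numerical integration (adaptive explicit Runge-Kutta, rtol 1e-8, atol 1e-12;
tolerances configurable). Capillary selection maps a chemotactic-ability
difference c to a log-enrichment s_c, and per-hour relative fitness over the
cycle is w = (s_g + s_c)/T.

Two bookkeeping conventions are supported and must not be mixed:

| convention  | s_c       | T      | use                                   |
|-------------|-----------|--------|---------------------------------------|
| `main_text` | 0.5·c     | 12 h   | phenotype bookkeeping, capillary assay |
| `gradient`  | c         | 11.5 h | landscape and selective gradients      |

Under `gradient` the chemotaxis axis of the landscape *is* the per-cycle
selection, so the chemotaxis gradient of the surface is exactly 1/T =
1/11.5 ≈ 0.087. The two conventions differ only by a fixed rescaling of the
chemotaxis axis and of the fitness unit; every function takes the convention
explicitly.

## Baseline calibration

The ancestral growth rate and initial frequencies of the landscape baseline
are not measured quantities; they are set from the experimental design. The
serial transfer dilutes 2048-fold, so a cycle starts at about 1/2000 of
carrying capacity; a competition assay mixes the two strains 1:1, giving
m₀ = w₀ = 1/4000. The ancestral rate defaults to r_w = 1.0 h⁻¹, under which
the mixed culture reaches 98% of carrying capacity at 11.5 h — "late
exponential" saturation consistent with the cycle design. A helper
(`calibrate_ancestral_rate`) inverts the logistic closed form for any other
target saturation; calibrating to 99% from an inoculum of 1/2000 gives
r ≈ 1.06 h⁻¹.

With this baseline the mean selective gradients over the standard grid
(c ∈ [−1, 8] step 0.2, r ∈ [−0.2, 0.3] step 0.025) are 0.608 on the growth
axis and 0.0870 on the chemotaxis axis. The growth gradient is sensitive to
the assumed inoculum: starting each competitor at 1/2000 instead (total
1/1000) lowers it to 0.555, because the culture saturates sooner and fast
growers enjoy their advantage for less time.

## Selective gradients

The surface is additively separable — s_g depends only on the growth
difference and s_c only on the chemotaxis difference — so its mixed second
differences vanish and a 46×21 grid costs only 21 integrations. Each
gradient is the mean of all forward differences between adjacent nodes along
its axis divided by the step; on a plane this is the exact slope, and on the
smooth competition surface it summarises overall selection strength per
trait. The curvature along the growth axis (forward differences decline as
r grows) reflects sigmoid growth: the faster a mutant already is, the
smaller the benefit of growing faster still, because the culture saturates
earlier.

## Pareto front and constrained optimum

The trade-off front is an ordinary least-squares regression of chemotaxis
difference on growth-rate difference over the isolates judged to sit on the
boundary (phase-2 isolates in the synthetic panels). The constrained
optimum maximises cycle fitness along the fitted line by a 201-point coarse
scan refined with a bounded one-dimensional search; ties within 1e-9 of the
maximum resolve to the lowest growth difference. Because s_g' exceeds
9.6·(1/T-scaled) nowhere in the searched range, fitness along a
c = 2.7 − 9.6·r front rises toward lower growth rates and the optimum sits
at the low-r end of the searched interval — trade-off-bound populations
accumulate chemotaxis at a growth cost.

## r/k sensitivity surface

The end-of-growth outcome f(r, k) is the Δ log-ratio of a mutant with rate r
and capacity parameter k (its saturation term is 1 − (m+w)/k) against a
fixed baseline competitor with k = 1, from initial abundances of 1/2000
each. Derivatives are forward differences at step 0.01. The per-strain
meaning of k in a shared culture is a modelling choice (documented here
because the quantity has no unique definition): k scales only the mutant's
own saturation response. Under this form df/dr is positive and declines
with r (diminishing returns), while |df/dk| grows with r — a faster mutant
reaches the capacity-limited regime sooner, so its capacity parameter
matters more, not less.

## Estimators

- Growth rate: OLS slope of ln(counts) on time; exact on noiseless
  exponentials; SE from residual variance (zero for an exact two-point fit).
- Logistic fit: nonlinear least squares of N(t) = K·N₀·e^{rt}/(K+N₀(e^{rt}−1))
  (Levenberg-Marquardt via trust-region with positivity bounds). Flagged
  ill-conditioned when no observation reaches half the fitted K or the K
  standard error exceeds the estimate — all-pre-inflection designs cannot
  identify the capacity.
- Chemotaxis: ln(post_m/post_a) − ln(pre_m/pre_a); dilution-invariant and
  antisymmetric under label swap. Zero counts raise an error; a pseudo-count
  is available but strictly opt-in, so regularisation is never silent.
- Motility: a cell is motile above a speed threshold, default 5 µm/s —
  the experimental definition of "motile" is not standardised, so the
  threshold is a reported parameter, chosen to separate Brownian jiggle
  (~1 µm/s) from flagellar swimming (~10–25 µm/s) in the synthetic mixture.
  The decomposition satisfies mean = f·motile_mean + (1−f)·nonmotile_mean
  identically.
- Speed-vs-chemotaxis: OLS with or without intercept; through-origin R² uses
  the uncentred total sum of squares (conventions differ; the uncentred form
  keeps R² in [0, 1] for the no-intercept model).

## Evolution simulator

Genotypes carry a motility-investment allocation u ∈ [0, 1] expressed during
growth (u_growth) and at selection time (u_select), a base rate r_base, a
plasticity flag, and a cost-free chemotaxis component c_free. Realised
traits are r_eff = r_base(1 − γ·u_growth) and c_eff = c_free + c_max·u_select.
Non-plastic genotypes hold one u for the whole cycle, which confines them to
a line of slope −c_max/(γ·r_base) in difference space; the defaults
(γ = 0.25, c_max = 2.4, r_base = 1.0) give the empirical front slope −9.6,
and the c_free cap of 2.7 gives its intercept. c_free models early
chemotaxis gains with no measurable growth cost — without such a component a
pure trade-off model cannot produce a front with a nonzero intercept or a
first phase in which chemotaxis rises while growth stays flat.

One cycle is: (i) multi-lineage Lotka-Volterra growth with shared
saturation; (ii) capillary reweighting of lineage i by exp(s_c(c_eff,i)),
exactly consistent with the selection-coefficient definition, so a
deterministic two-lineage cycle reproduces s_g + s_c to integrator
tolerance; (iii) a 2048-fold dilution with multinomial resampling at a
census of 1e5 virtual cells (census = None gives the deterministic
infinite-census limit used in oracle tests); (iv) mutation.

The mutation kernel is an effective parameterisation, not a measured
quantity: Poisson(1) events per cycle, each picking a parent lineage by
frequency and applying either a Gaussian step on c_free (SD 0.9, clipped to
the cap) or on an allocation trait (SD 0.5, reflected into [0, 1]); 10% of
events unlock plasticity, after which u_growth and u_select mutate
independently. The step scales are deliberately coarse: selection along the
front is weak (the front nearly parallels the fitness isoclines), so
phase-2 progress within 150 cycles requires large-effect mutations — which
is also what the experiment's sequencing found (few mutations of large
effect). The simulator runs in the `gradient` convention, under which
chemotaxis gains outcompete their growth cost along a −9.6 front; under the
half-strength `main_text` weighting the same front would favour growth and
the trajectory would run the other way.

Phase detection is by explicit statistics on the weekly summary, not by
eye: phase 1 = a pre-plasticity week with mean c-gain ≥ 0.5 and
|mean r-diff| ≤ 0.12; phase 2 = a week within (0.1, 1.0) of the constrained
optimum in (r, c); phase 3 = a week after plasticity reaches a majority
with the mean phenotype ≥ 0.5 above the front line. Phase timing is
configuration-dependent; only the existence and order of the phases is
asserted.

## Synthetic data

Noise families are chosen to match each assay's sampling process: Poisson
for flow-cytometry-like counts, multinomial for capillary enrichment,
Gaussian mixtures for per-cell speeds, and i.i.d. Gaussian measurement error
for isolate phenotypes. Every generator has a zero-noise mode on which its
estimator is exact, and all draws flow through one seeded generator, so runs
are bit-reproducible.

Panel defaults: 11 weeks × 6 isolates, front c = 2.7 − 9.6r, phase
boundaries after weeks 2 and 7, chemotaxis noise SD 0.3 (the scale of the
reported error bars) and growth-rate noise SD 0.005 — growth rates come
from count regressions and are roughly an order of magnitude tighter than
capillary assays. The asymmetry matters statistically: noise on the
regression's predictor attenuates the fitted front slope (errors in
variables), so a generator with heavy r-noise would bias the slope recovery
that the panel is designed to exercise.

Speed archetypes are piecewise-linear schedules over {0, 2, 4, 6, 8, 10,
11.5} h: the ancestor peaks mid-cycle and slows near capacity; mid-evolution
clones swim faster than the ancestor nearly throughout; late plastic clones
suppress motility during rapid growth and boost the motile fraction as
capacity approaches. These reproduce the qualitative patterns of the
measured speed curves, not their absolute values (the real per-cell data are
not deposited).

What passing tests on synthetic data do and do not show: they demonstrate
that the estimators are unbiased and well-calibrated under the assumed noise
families and that the pipeline is internally consistent; they cannot
validate the noise families themselves against real flow-cytometry or
video-tracking data.

## Problem sizes and numerical choices

The default test suite and analysis scripts use the full 46×21 landscape
grid, 150-cycle simulations, and Monte Carlo sizes of 100–500 replicates
per recovery check; everything runs in well under a minute apiece. The
independent integration oracle is a fixed-grid RK4 at 400k steps. All logs
are natural; time is in hours, speeds in µm/s; grid endpoints are
inclusive. Degenerate inputs (zero counts, empty speed samples, single-node
grid axes, constant predictors, extinct populations) raise typed errors
rather than propagating NaNs, and the simulator reports extinction and
halts gracefully rather than dividing by zero at an empty bottleneck.

## Known limitations

- The capillary stage is a fitness weight, not a spatial chemotaxis model;
  no PDE or run-and-tumble physics.
- The competition ODEs are deterministic; demographic stochasticity enters
  only at the bottleneck.
- The per-strain capacity parameter in the r/k surface has no unique
  definition in a shared culture; results for k ≠ 1 depend on the declared
  form.
- Mutational supply in the simulator is an effective model; simulated phase
  timing should not be compared quantitatively to experimental weeks.
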