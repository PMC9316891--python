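# Methods

This note documents the models and numerical procedures implemented in
`forcequant`, the choices made where the design was genuinely open, and what
the synthetic test bed can and cannot show about real tower data.

## Quantizer design

**PMF estimation.** A variable's distribution is estimated by bin counting:
bins `[x0 + iδ, x0 + (i+1)δ)` anchored at the data minimum by default, with
mass `p_i = c_i / n` and density `f̂ = c_i / (n δ)`. The default width is the
normal reference rule `δ = 3.5 σ n^(−1/3)`, which is optimal in the
mean-integrated-squared-error sense for Gaussian data and serviceable for the
mildly non-Gaussian forcing distributions handled here. Widths are kept
unrounded internally; a 1-decimal presentation rounding is applied only when
building default histograms, so a wind-speed record with σ = 1.70 m/s and
n = 9600 gets δ = 0.3 m/s.

**Lloyd–Max iteration.** The N-level quantizer is fitted on the discrete PMF
(bin centers weighted by mass): given interior thresholds, each cell's
representation point becomes the conditional mean of its mass; thresholds are
then reset to midpoints of adjacent points. Both half-steps weakly decrease
the expected squared error, so the stored distortion trace is non-increasing
and the iteration converges to a local minimum. Iteration stops when the
largest threshold movement falls below `tol × (Xmax − Xmin)` (default
`tol = 1e-6`, `max_iter = 500`; a capped run carries `converged=False`).
A sample-based mode treats each observation as a support point of weight 1/n.

**Cell convention.** Cells are half-open `(T_{j−1}, T_j]` with the first cell
closed at the global minimum; a value exactly on a threshold joins the lower
cell, and out-of-range values clamp to the end cells. This matters only for
data that land exactly on a threshold.

**Initialization and local minima.** The deterministic default descends from
both the equiprobable (quantile) thresholds and the equal-width thresholds and
keeps the better fit; descending from the equal-width start also guarantees
the converged distortion never exceeds the fixed-binning baseline on the same
PMF. Optional seeded random restarts (`restarts=k`) add k further starts,
alternating plain range-uniform threshold draws with draws mapped through the
PMF's quantile function; the latter explore basins where mass actually lives.
Scalar quantizers on coarse PMFs (~20 support points) do exhibit multiple
fixed points at N ≥ 4, and the experiment-level fitting functions therefore
default to `restarts=64` — still milliseconds of work — which in testing
recovers the exhaustive-search optimum on every PMF small enough to enumerate.

**Empty cells.** If a cell loses all mass mid-iteration, its representation
point is parked at the cell midpoint and iteration continues; a quantizer
that converges in that state is flagged `degenerate` rather than failing.

## Information metrics

Entropy is Shannon entropy in bits with the `0 log 0 = 0` convention;
`Hmax = log₂ N_d` uses the declared category count. Joint entropy is computed
by direct counting of category tuples over timesteps — no smoothing or bias
correction — which keeps the complexity ratio exactly reproducible and
consistent with the bin-counting PMF estimate. The known downward bias of
plugin entropy estimates is immaterial here because numerator and denominator
of Cm are estimated the same way on the same ~10⁴ timesteps.

**The Cm denominator.** The "full-resolution" discretization of continuous
forcing is a genuine modelling choice: instrument precision, storage
precision, and histogram binning all give different absolute joint entropies.
The package bins each variable with its normal-reference-rule width by
default and exposes the discretization as an argument
(`full_resolution_histograms`, or any per-variable histogram/width), so the
sensitivity of Cm to this choice can be examined directly. Cm is reported in
[0, 1]; variables a scenario leaves unquantized enter the numerator at full
resolution.

## Scenario suite

Cases 1–7 quantize the subsets {Ta}, {U}, {VPD}, {Ta,U}, {Ta,VPD}, {U,VPD},
{Ta,U,VPD}; each quantized variable sweeps N ∈ {2,3,4,5}, giving 4^f
scenarios per case and 124 in all. The radiation case quantizes Rg alone.
Because shortwave is essentially zero at night, Rg quantizers are fitted on,
and applied to, daytime steps only (Rg > 5 W/m² by default — real records
are near but not exactly zero at night); nighttime Rg passes through
unchanged. Quantizers are fitted once on the full-period record and reused
across scenarios; per-window refitting is deliberately not the default, so
every scenario of a case shares one set of representation points.

## Surrogate flux model

The built-in model is a stateless big-leaf surrogate, *not* a multilayer
canopy model; it exists so that quantization effects propagate through a
smooth, physically plausible forcing→flux map with exactly known structure.
Per 15-min step, with forcing Rg, Ta, VPD, U:

- net radiation `Rn = a·Rg` (a = 0.8 lumps albedo and net longwave), ground
  heat `G = g·Rn` (g = 0.1), available energy `A = Rn − G`;
- gross uptake `Amax · Rg/(Rg+K) · exp(−((Ta−Topt)/Tb)²)` with
  Amax = 30 µmol/m²/s, K = 300 W/m², Topt = 25 °C, Tb = 12 °C, scaled by
  LAI/4 when an LAI series is present; ecosystem respiration
  `r0 · Q10^((Ta−25)/10)` with r0 = 2 µmol/m²/s, Q10 = 2; Fc = respiration −
  uptake (daytime uptake negative);
- surface conductance `gs = m·max(An,0)/(1+VPD/1.5) + b` (Ball–Berry-style,
  m = 0.009 mol m⁻² s⁻¹ per µmol m⁻² s⁻¹, b = 0.01 mol/m²/s), aerodynamic
  conductance `ga = 0.08·U + 0.01` mol/m²/s;
- latent heat is VPD-driven demand through the series conductance,
  `LE = min(A, 440 · gs·ga/(gs+ga) · VPD)` floored at zero, and sensible heat
  closes the balance, `SH = A − LE`, so `LE + SH + G = Rn` holds to machine
  precision at every step.

Parameter magnitudes are chosen to give midsummer midday fluxes of realistic
order (LE of order 10²  W/m², Fc of order −20 µmol/m²/s). Because the
surrogate is stateless, no spin-up question arises between scenarios. Any
model honouring the `ForcingSet → {Fc, LE, SH}` contract can replace it,
including an external executable driven through the CSV round-trip I/O.
Footprint mixing `X = fm·Xm + (1−fm)·Xs` composes two runs per-timestep with
convex weights; fm defaults to a constant 0.5 when no footprint series is
available.

## Sensitivity statistics

`SM_t` is the across-days RMSE between full-model and quantized-model output
at each time-of-day step (the square root is applied — the statistic is in
flux units). Days with a missing value at a step are dropped pairwise there
and the effective day count recorded. Windowed variants restrict to inclusive
DOY ranges, defaulting to the five 20-day blocks 150–170, 171–190, 191–210,
211–230, 231–250; time-of-day aggregation averages SM_t over half-open clock
blocks `[start, end)` that must land on the 15-min grid. The comparison table
carries one row per scenario with its Cm and block-averaged SM_t per flux;
the full model anchors it at (Cm, SM_t) = (1, 0).

## Synthetic forcing generator

The generator emulates the statistical structure of a mid-latitude
agricultural growing season (default 100 days from DOY 150, 96 steps/day):

- **Rg**: per-day half-sinusoid over a 14.4-h daylight window peaking at
  850 W/m², multiplied by a persistent cloud-transmissivity factor (a
  logistic transform of an AR(1) driver, spanning clear sky to heavy
  overcast), and exactly zero at night.
- **Ta**: 22 °C mean, a mid-season seasonal arch (±3 °C), a 5 °C diurnal
  half-amplitude peaking at 15:00, plus AR(1) noise (stationary σ 1.5 °C).
- **VPD**: `es(Ta)·(1−RH)` with the Magnus saturation curve and RH a bounded
  AR(1) process (mean 0.70, σ 0.12) — so VPD is upper-bounded by es and
  inherits Ta's diurnal cycle, as in real records.
- **U**: a Gaussian AR(1) process mapped through a Weibull(shape 1.8,
  scale 2.5 m/s) margin, giving the right-skewed, long-tailed, temporally
  correlated wind distribution on which optimal and equal-width quantizers
  differ most.
- **PPT**: independent wet steps with probability 0.01 and exponential depth,
  zero otherwise.

One master seed spawns one substream per variable in fixed order, so the same
spec is bit-reproducible and adding a variable never perturbs the others.

**What passing tests show — and don't.** The generator reproduces the
qualitative features the analysis relies on (skewed wind, near-symmetric
temperature, nighttime-zero radiation with realistic cloud mass at low
daytime values, Ta-coupled VPD), and on it the suite verifies the method's
structural claims: scenario combinatorics, quantizer optimality, entropy
dominance of rate-distortion quantization over fixed binning, complexity
anchors and monotonicity, and exact surrogate energy closure. It does not
reproduce site-specific flux magnitudes, gap structure, synoptic weather, or
soil-moisture memory, so numerical SM_t values here characterize the
surrogate on synthetic forcing, not any field site. One caveat worth naming:
for a nearly symmetric variable at N = 2 the optimal quantizer and fixed
binning become equivalent, and the entropy ordering between them can tie to
within ~10⁻⁵ bits either way at some seeds.

## Degenerate inputs and numerical conventions

Constant series are rejected where a bin width must be derived (zero σ) and
yield zero entropy where categories are given. All-missing series, empty
masks, misaligned grids, non-uniform timestamps, and partial final days are
hard errors (the last unless truncation is requested). Missing values are
NaN throughout — never silently zero — and are excluded pairwise from PMFs,
entropies, and SM_t. CSV round-trips preserve float bits (shortest-repr
write, round-trip parse) and missing flags.
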