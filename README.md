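# forcequant

Rate–distortion quantization of model forcing time series, and an
information-theoretic sensitivity analysis built on it, for canopy-flux
(ecohydrological) models.

## The problem

Land-surface and canopy models are driven by high-resolution meteorological
forcing — shortwave radiation *Rg* (W/m²), air temperature *Ta* (°C), vapor
pressure deficit *VPD* (kPa), wind speed *U* (m/s) — whose precision is set
by instruments, not by what the model actually uses. Deliberately *quantizing*
a forcing variable to a handful of representative values, and watching how far
the model's fluxes move, reveals which inputs the model exploits at full
precision and which could be radically simplified. This package provides the
whole workflow for modelers who want to ask that question of their own model:

1. **Quantization** (`forcequant.quantize`). A variable's probability mass
   function is estimated by bin counting with the normal-reference-rule width
   3.5 σ n^(−1/3). The Lloyd–Max algorithm then designs an *N*-level scalar
   quantizer by alternating two optimality conditions until the thresholds
   converge: each representation point x̂ⱼ is the conditional mean of the mass
   in its cell αⱼ = (Tⱼ₋₁, Tⱼ], and each threshold is the midpoint of adjacent
   points, Tⱼ = (x̂ⱼ + x̂ⱼ₊₁)/2. The expected squared-error distortion
   d(X, X̂) = E(X − X̂)² decreases at every iteration. Equal-width "fixed
   binning" with bin-center representation points is the baseline.
2. **Information metrics** (`forcequant.information`). Shannon entropy
   H(X_d) = −Σ P(xₙ) log₂ P(xₙ) of discretized series, joint entropy by direct
   counting, and the forcing complexity of a quantized scenario,
   Cm = H(T̂a, Û, V̂PD) / H(Ta, U, VPD) ∈ [0, 1].
3. **Scenarios and model runs** (`forcequant.scenarios`). Seven cases quantize
   subsets of {Ta, U, VPD} to N ∈ {2,3,4,5} levels (4^f scenarios for f
   quantized variables — 124 in total), plus a radiation case that quantizes
   *Rg* for daytime steps only. Any model callable on a forcing set can be
   plugged in; a big-leaf surrogate with exact energy closure is built in,
   as is footprint mixing X = f_m·X_maize + (1 − f_m)·X_soy.
4. **Sensitivity** (`forcequant.sensitivity`). For each time-of-day step t,
   SM_t = √( Σ_d (F(d,t) − Q(d,t))² / D ) is the RMSE across days between
   full-forcing and quantized-forcing model output — a sensitivity, not an
   error. Windowed (20-day) variants, 3-hour time-of-day aggregation, and a
   per-scenario Cm-vs-SM_t comparison table summarize the experiment.
5. **Synthetic forcing** (`forcequant.synthetic`). A seeded generator emulates
   a 100-day growing season at 15-min resolution (diurnal shortwave that is
   exactly zero at night, afternoon-peaking temperature, Magnus-coupled VPD,
   right-skewed autocorrelated wind, sparse precipitation), so the entire
   pipeline is testable without any data download.

## Worked example

```python
import forcequant as fq

fset = fq.generate_forcing(fq.SynthesisSpec(n_days=100, seed=1))
ta = fset["Ta"].values
pmf = fq.estimate_pmf(ta, fq.normal_reference_width(ta.std(), ta.size))
print(fq.lloyd_fit(pmf, 2).summary())
```

```
lloyd quantizer, N=2, distortion=4.22693
thresholds: [13.8232 23.8561 33.5278]
points:     [20.4339 27.2784]
iterations=2 converged=True
```

The two-level quantizer replaces every temperature below 23.86 °C by
20.43 °C and every one above it by 27.28 °C; the threshold sits exactly at
the midpoint of the two representation points, and the mean squared error of
the simplification is 4.23 °C². Running the full experiment ranks scenarios
by how much forcing complexity they remove versus how far they move the
model:

```python
scen = (fq.enumerate_scenarios(cases=(1, 2, 3, 4, 5, 6, 7))
        + fq.enumerate_scenarios(cases=("Rg",)))
result = fq.run_experiment(fset, scen, seed=1)          # 129 model runs
table = fq.complexity_sensitivity_table(result, fset)
print(table.sort_values("cm")[["scenario", "cm", "SMt_LE_12:00-15:00"]].head(3))
```

```
         scenario       cm  SMt_LE_12:00-15:00
case7_Ta2_U2_VPD2 0.232516            6.504323
case7_Ta2_U2_VPD3 0.273490            6.082188
case7_Ta2_U3_VPD2 0.275058            5.867569
```

Quantizing all three meteorological variables to two levels keeps only 23% of
the forcing's joint information content and shifts midday latent heat by
6.5 W/m² RMSE; the full model anchors the table at Cm = 1, SM_t = 0.

A `forcequant` console script exposes the same pipeline from the shell
(`synth`, `quantize`, `entropy`, `run`, `sensitivity` subcommands); see
`forcequant --help`.

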