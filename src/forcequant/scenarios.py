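"""Quantization scenario enumeration, scenario forcing construction, the
built-in surrogate canopy-flux model, footprint mixing, and the experiment
runner.

The seven meteorological cases quantize subsets of {Ta, U, VPD}; a separate
radiation case quantizes Rg for daytime steps only (nighttime shortwave is
essentially zero, so quantizing it is meaningless).  With f quantized
variables and levels N in {2,3,4,5}, each case expands to 4**f scenarios:
Cases 1-7 give 4 + 4 + 4 + 16 + 16 + 16 + 64 = 124 scenarios, and the Rg
case 4 more.

The flux model behind the experiment is pluggable: anything callable as
``model(forcing_set) -> {"Fc": FluxSeries, "LE": ..., "SH": ...}`` works.
The built-in surrogate is a deliberately small big-leaf energy-balance and
light-response model, not a multilayer canopy model; its value
is that its response to forcing is smooth, monotone where it should be, and
closes the energy balance exactly, so quantization effects propagate
cleanly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .forcing import FluxSeries, ForcingSet
from .quantize import Quantizer, apply_quantizer, estimate_pmf, lloyd_fit, fixed_binning_fit, normal_reference_width
from .synthetic import daylight_mask, magnus_es

__all__ = [
    "CASE_VARIABLES",
    "Scenario",
    "SurrogateParams",
    "ScenarioRun",
    "ExperimentResult",
    "enumerate_scenarios",
    "fit_quantizers",
    "build_scenario_forcing",
    "surrogate_model",
    "footprint_mix",
    "run_experiment",
]

#: which forcing variables each case quantizes
CASE_VARIABLES: dict[str | int, tuple[str, ...]] = {
    1: ("Ta",),
    2: ("U",),
    3: ("VPD",),
    4: ("Ta", "U"),
    5: ("Ta", "VPD"),
    6: ("U", "VPD"),
    7: ("Ta", "U", "VPD"),
    "Rg": ("Rg",),
}

DEFAULT_LEVELS = (2, 3, 4, 5)
FLUX_NAMES = ("Fc", "LE", "SH")


@dataclass(frozen=True)
class Scenario:
    """One assignment of quantization levels to a subset of forcing variables."""

    case: str | int
    levels: tuple[tuple[str, int], ...]  # ((variable, N), ...) in case order
    method: str = "lloyd"

    @property
    def level_map(self) -> dict[str, int]:
        return dict(self.levels)

    @property
    def scenario_id(self) -> str:
        tag = "_".join(f"{v}{n}" for v, n in self.levels)
        return f"case{self.case}_{tag}" if tag else "full"

    def __str__(self) -> str:
        return self.scenario_id


def enumerate_scenarios(
    cases: Sequence[str | int] = (1, 2, 3, 4, 5, 6, 7),
    levels: Sequence[int] = DEFAULT_LEVELS,
    method: str = "lloyd",
) -> list[Scenario]:
    """Cross-product of level assignments per case, in stable order.

    Each case with f quantized variables expands to ``len(levels)**f``
    scenarios; the default seven meteorological cases over N in {2,3,4,5}
    give 124.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    out: list[Scenario] = []
    for case in cases:
        if case not in CASE_VARIABLES:
            raise ValueError(f"unknown case {case!r}")
        variables = CASE_VARIABLES[case]
        for combo in itertools.product(levels, repeat=len(variables)):
            out.append(Scenario(case, tuple(zip(variables, combo)), method))
    return out


def fit_quantizers(
    fset: ForcingSet,
    variables: Sequence[str],
    levels: Sequence[int] = DEFAULT_LEVELS,
    method: str = "lloyd",
    rg_threshold: float = 5.0,
    bin_widths: Mapping[str, float] | None = None,
    seed: int | None = 0,
    restarts: int = 64,
    tol: float = 1e-6,
) -> dict[tuple[str, int], Quantizer]:
    """Fit one quantizer per (variable, level) on the full-period forcing.

    Quantizers are fitted once on the whole record and reused across
    scenarios.  Rg is fitted on daytime values only (threshold in W/m2);
    histogram bin widths default to the normal reference rule per variable.
    """
    out: dict[tuple[str, int], Quantizer] = {}
    for name in variables:
        series = fset[name]
        mask = daylight_mask(series, rg_threshold) if name == "Rg" else None
        values = series.values if mask is None else series.values[mask]
        values = values[~np.isnan(values)]
        if bin_widths and name in bin_widths:
            width = bin_widths[name]
        else:
            width = normal_reference_width(values.std(ddof=0), values.size)
        pmf = estimate_pmf(values, width)
        for n in levels:
            if method == "lloyd":
                out[(name, n)] = lloyd_fit(pmf, n, seed=seed, restarts=restarts, tol=tol)
            elif method == "fixed":
                out[(name, n)] = fixed_binning_fit(values.min(), values.max(), n)
            else:
                raise ValueError(f"unknown method {method!r}")
    return out


def build_scenario_forcing(
    base: ForcingSet,
    scenario: Scenario,
    quantizers: Mapping[tuple[str, int], Quantizer],
    rg_threshold: float = 5.0,
) -> ForcingSet:
    """Replace the scenario's variables by their quantized series.

    All other variables pass through bit-identical; Rg keeps its original
    nighttime values (daytime-only quantization).
    """
    out = base
    for name, n in scenario.levels:
        key = (name, n)
        if key not in quantizers:
            raise KeyError(f"no fitted quantizer for {name} at N={n}")
        series = base[name]
        mask = daylight_mask(series, rg_threshold) if name == "Rg" else None
        qs = apply_quantizer(series, quantizers[key], mask=mask)
        out = out.replace_series(name, qs.values)
    return out


# ---------------------------------------------------------------------------
# surrogate canopy-flux model

@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the built-in big-leaf surrogate flux model.

    Units: conductances mol m-2 s-1, fluxes W m-2 (heat) and umol m-2 s-1
    (carbon), radiation W m-2, temperature degC, VPD kPa, wind m s-1.
    """

    net_rad_fraction: float = 0.8   # a: Rn = a * Rg (albedo + longwave lumped)
    ground_fraction: float = 0.1    # g: G = g * Rn
    amax: float = 30.0              # light-saturated gross uptake [umol/m2/s]
    k_light: float = 300.0          # half-saturation of the light response [W/m2]
    t_opt: float = 25.0             # photosynthesis temperature optimum [degC]
    t_breadth: float = 12.0         # Gaussian breadth of the temp response [degC]
    bb_slope: float = 0.009         # Ball-Berry-style slope [mol m-2 s-1 per umol m-2 s-1]
    bb_intercept: float = 0.01      # residual surface conductance [mol/m2/s]
    vpd_half: float = 1.5           # VPD at which stomata halve [kPa]
    ga_coeff: float = 0.08          # aerodynamic conductance per unit wind [mol m-2 s-1 per m/s]
    ga_min: float = 0.01            # still-air aerodynamic conductance [mol/m2/s]
    le_coeff: float = 440.0         # latent-heat scaling [W m-2 per (mol m-2 s-1 kPa)]
    resp_base: float = 2.0          # ecosystem respiration at 25 degC [umol/m2/s]
    q10: float = 2.0                # respiration temperature sensitivity
    lai_ref: float = 4.0            # LAI at which amax applies

    def validate(self) -> None:
        if not 0 < self.net_rad_fraction <= 1:
            raise ValueError("net_rad_fraction must lie in (0, 1]")
        if not 0 <= self.ground_fraction < 1:
            raise ValueError("ground_fraction must lie in [0, 1)")
        for name in ("amax", "k_light", "t_breadth", "bb_slope", "bb_intercept",
                     "vpd_half", "ga_coeff", "le_coeff", "q10", "lai_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resp_base < 0 or self.ga_min < 0:
            raise ValueError("resp_base and ga_min must be non-negative")


def surrogate_model(
    fset: ForcingSet,
    params: SurrogateParams | None = None,
) -> dict[str, FluxSeries]:
    """Big-leaf surrogate fluxes {Fc, LE, SH} from {Rg, Ta, VPD, U} forcing.

    Per timestep: net radiation Rn = a*Rg, ground flux G = g*Rn, available
    energy A = Rn - G.  Gross uptake follows a hyperbolic light response
    scaled by a Gaussian temperature response (and LAI when present);
    ecosystem respiration is Q10 in Ta; Fc = respiration - gross uptake
    (daytime uptake negative).  Surface conductance is Ball-Berry-like in net
    uptake with a hyperbolic VPD closure; aerodynamic conductance is linear
    in wind.  Latent heat is the VPD-driven demand through the series
    conductance, capped by available energy and floored at zero; sensible
    heat closes the balance, SH = A - LE, so LE + SH + G = Rn exactly.
    """
    params = params or SurrogateParams()
    params.validate()
    for name in ("Rg", "Ta", "VPD", "U"):
        if name not in fset:
            raise ValueError(f"surrogate model requires forcing variable {name!r}")
    rg = fset["Rg"].values
    ta = fset["Ta"].values
    vpd = np.maximum(fset["VPD"].values, 0.0)
    u = np.maximum(fset["U"].values, 0.0)
    lai_scale = 1.0
    if "LAI" in fset:
        lai_scale = np.clip(fset["LAI"].values / params.lai_ref, 0.0, 1.5)

    rn = params.net_rad_fraction * rg
    ground = params.ground_fraction * rn
    avail = rn - ground

    light = rg / (rg + params.k_light)
    f_temp = np.exp(-(((ta - params.t_opt) / params.t_breadth) ** 2))
    gross = params.amax * lai_scale * light * f_temp
    resp = params.resp_base * params.q10 ** ((ta - 25.0) / 10.0)
    fc = resp - gross                      # uptake negative by convention
    an_net = np.maximum(gross - resp, 0.0)

    f_vpd = 1.0 / (1.0 + vpd / params.vpd_half)
    gs = params.bb_slope * an_net * f_vpd + params.bb_intercept
    ga = params.ga_coeff * u + params.ga_min
    g_series = gs * ga / (gs + ga)
    demand = params.le_coeff * g_series * vpd
    le = np.minimum(np.maximum(avail, 0.0), demand)
    sh = avail - le

    ts = fset.timestamps
    return {
        "Fc": FluxSeries("Fc", fc, ts),
        "LE": FluxSeries("LE", le, ts),
        "SH": FluxSeries("SH", sh, ts),
    }


def footprint_mix(fm, maize: FluxSeries, soy: FluxSeries) -> FluxSeries:
    """Footprint-weighted flux: X = fm * X_maize + (1 - fm) * X_soy.

    ``fm`` is the maize contributing fraction (scalar or per-timestep array);
    the soybean fraction is 1 - fm, so the fractions sum to one at every
    timestep by construction.
    """
    if not maize.timestamps.equals(soy.timestamps):
        raise ValueError("flux series are not on the same grid")
    fm = np.asarray(fm, float)
    if np.any(fm < 0) or np.any(fm > 1):
        raise ValueError("footprint fraction must lie in [0, 1]")
    if fm.ndim == 1 and len(fm) != len(maize):
        raise ValueError("footprint fraction series must match the flux grid")
    mixed = fm * maize.values + (1.0 - fm) * soy.values
    return FluxSeries(maize.name, mixed, maize.timestamps, maize.units)


# ---------------------------------------------------------------------------
# experiment runner

@dataclass(frozen=True)
class ScenarioRun:
    scenario: Scenario
    fluxes: dict[str, FluxSeries] | None
    failed: bool = False
    message: str = ""


@dataclass
class ExperimentResult:
    """Full-model fluxes plus one flux triple per scenario."""

    full: dict[str, FluxSeries]
    runs: list[ScenarioRun]
    quantizers: dict[tuple[str, int], Quantizer] = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        """Total recorded model runs including the full model."""
        return len(self.runs) + 1

    def to_frame(self):
        """Tidy long table: scenario id, case, flux, timestep value columns."""
        import pandas as pd

        rows = []
        ts = next(iter(self.full.values())).timestamps
        for name, flux in self.full.items():
            rows.append(pd.DataFrame({
                "scenario": "full", "case": "full", "flux": name,
                "timestamp": ts, "value": flux.values,
            }))
        for run in self.runs:
            if run.failed or run.fluxes is None:
                continue
            for name, flux in run.fluxes.items():
                rows.append(pd.DataFrame({
                    "scenario": run.scenario.scenario_id,
                    "case": f"case{run.scenario.case}",
                    "flux": name, "timestamp": ts, "value": flux.values,
                }))
        return pd.concat(rows, ignore_index=True)


def run_experiment(
    base: ForcingSet,
    scenarios: Sequence[Scenario],
    model: Callable[[ForcingSet], dict[str, FluxSeries]] | None = None,
    quantizers: Mapping[tuple[str, int], Quantizer] | None = None,
    rg_threshold: float = 5.0,
    seed: int | None = 0,
    restarts: int = 64,
) -> ExperimentResult:
    """Run the full model and every quantized scenario.

    Quantizers are fitted once on ``base`` (unless supplied) and reused.  A
    scenario whose model call raises is logged, marked failed, and the run
    continues.  Deterministic for a fixed seed and configuration.
    """
    model = model or surrogate_model
    if quantizers is None:
        needed: dict[str, set[int]] = {}
        for sc in scenarios:
            for v, n in sc.levels:
                needed.setdefault(v, set()).add(n)
        quantizers = {}
        for v, ns in needed.items():
            method = next(sc.method for sc in scenarios if v in sc.level_map)
            quantizers.update(fit_quantizers(
                base, [v], sorted(ns), method=method,
                rg_threshold=rg_threshold, seed=seed, restarts=restarts))
    full = model(base)
    runs: list[ScenarioRun] = []
    for sc in scenarios:
        try:
            forcing = build_scenario_forcing(base, sc, quantizers, rg_threshold)
            fluxes = model(forcing)
            runs.append(ScenarioRun(sc, fluxes))
        except Exception as exc:  # noqa: BLE001 - contract: log and continue
            runs.append(ScenarioRun(sc, None, failed=True, message=str(exc)))
    return ExperimentResult(full, runs, dict(quantizers))
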