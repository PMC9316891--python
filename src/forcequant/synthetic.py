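"""Synthetic growing-season forcing generator.

Emulates a mid-latitude agricultural flux-tower record at 15-min resolution:
a half-sinusoid shortwave cycle that is exactly zero at night, air temperature
with seasonal and diurnal harmonics plus red noise, vapour pressure deficit
derived from temperature through the Magnus saturation curve and a stochastic
relative humidity, a right-skewed autocorrelated wind speed, and mostly-zero
precipitation.  Everything is driven by one seed through per-variable
substreams, so adding a variable never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forcing import ForcingSeries, ForcingSet

__all__ = ["SynthesisSpec", "generate_forcing", "daylight_mask", "magnus_es"]

# fixed substream order; append only, never reorder
_SUBSTREAMS = ("Rg", "Ta", "RH", "U", "PPT")


def magnus_es(ta_c: np.ndarray) -> np.ndarray:
    """Saturation vapour pressure [kPa] from air temperature [degC] (Magnus form)."""
    ta_c = np.asarray(ta_c, float)
    return 0.6108 * np.exp(17.27 * ta_c / (ta_c + 237.3))


@dataclass
class SynthesisSpec:
    """Parameters of one synthetic growing-season realization.

    Defaults emulate a 100-day (DOY 150-250) maize/soybean season: midday
    shortwave peaks near 850 W/m2 over a 14.4-h day, air temperature averages
    22 degC with a ~5 degC diurnal half-amplitude peaking mid-afternoon, VPD
    follows es(Ta)*(1-RH), and wind speed is Weibull-distributed (shape < 2,
    hence right-skewed) with strong 15-min autocorrelation.
    """

    n_days: int = 100
    steps_per_day: int = 96
    seed: int = 0
    start: str = "2018-05-30"  # DOY 150

    rg_peak: float = 850.0          # clear-sky midday shortwave [W/m2]
    rg_day_fraction: float = 0.6    # daylight fraction of the 24-h cycle
    rg_cloud_sigma: float = 1.5     # stationary sd of the cloudiness AR(1) driver
    rg_clear_bias: float = 1.0      # >0 biases toward clear sky; 0 gives 50% mean attenuation

    ta_mean: float = 22.0           # season-mean air temperature [degC]
    ta_diurnal_amp: float = 5.0     # diurnal half-amplitude [degC]
    ta_seasonal_amp: float = 3.0    # mid-season warming half-amplitude [degC]
    ta_peak_hour: float = 15.0      # clock hour of the diurnal maximum
    ta_noise_sigma: float = 1.5     # stationary sd of the AR(1) residual [degC]

    rh_mean: float = 0.70           # mean relative humidity (0-1)
    rh_sigma: float = 0.12          # stationary sd of the RH AR(1) process
    vpd_floor: float = 0.0          # lower bound on VPD [kPa]

    u_shape: float = 1.8            # Weibull shape (right-skewed for k < 2)
    u_scale: float = 2.5            # Weibull scale [m/s]
    u_autocorr: float = 0.9         # lag-1 autocorrelation of the driving process

    ppt_wet_prob: float = 0.01      # probability a 15-min step is wet
    ppt_mean_intensity: float = 0.8 # mean wet-step depth [mm]

    variables: tuple = ("Rg", "Ta", "VPD", "U", "PPT")
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.steps_per_day < 1:
            raise ValueError("steps_per_day must be >= 1")
        for name in ("rg_peak", "ta_diurnal_amp", "ta_seasonal_amp", "ta_noise_sigma",
                     "rh_sigma", "u_shape", "u_scale", "ppt_mean_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.rg_day_fraction <= 1:
            raise ValueError("rg_day_fraction must lie in (0, 1]")
        if not 0 <= self.ppt_wet_prob <= 1:
            raise ValueError("ppt_wet_prob must lie in [0, 1]")
        if not 0 < self.rh_mean < 1:
            raise ValueError("rh_mean must lie in (0, 1)")
        if not 0 <= self.u_autocorr < 1:
            raise ValueError("u_autocorr must lie in [0, 1)")


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """AR(1) path with stationary standard deviation ``sigma``."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def generate_forcing(spec: SynthesisSpec) -> ForcingSet:
    """Generate a seeded synthetic forcing set.

    The same spec (including seed) always yields a bit-identical realization.
    """
    spec.validate()
    n = spec.n_days * spec.steps_per_day
    ss = np.random.SeedSequence(spec.seed)
    rngs = dict(zip(_SUBSTREAMS, (np.random.default_rng(c) for c in ss.spawn(len(_SUBSTREAMS)))))

    step = pd.Timedelta(days=1) / spec.steps_per_day
    timestamps = pd.date_range(spec.start, periods=n, freq=step)
    hours = (np.arange(n) % spec.steps_per_day) * (24.0 / spec.steps_per_day)
    day_index = np.arange(n) // spec.steps_per_day

    # --- shortwave: clipped half-sinusoid, multiplicative cloudiness, hard 0 at night
    half_day = 12.0 * spec.rg_day_fraction
    solar_phase = (hours - 12.0) / half_day  # -1..1 over daylight
    shape = np.where(np.abs(solar_phase) < 1.0, np.cos(0.5 * np.pi * solar_phase), 0.0)
    # cloud transmissivity in (0, 1): persistent AR(1) driver through a logistic,
    # spanning clear sky down to heavy overcast so low daytime Rg has real mass
    cloud_z = _ar1(rngs["Rg"], n, 0.97, spec.rg_cloud_sigma)
    cloud = 1.0 / (1.0 + np.exp(-(spec.rg_clear_bias + cloud_z)))
    rg = spec.rg_peak * shape * cloud
    rg[shape <= 0.0] = 0.0

    # --- air temperature: seasonal arch + afternoon-peaking diurnal + red noise
    season = spec.ta_seasonal_amp * np.sin(np.pi * day_index / max(spec.n_days - 1, 1))
    diurnal = spec.ta_diurnal_amp * np.cos(2.0 * np.pi * (hours - spec.ta_peak_hour) / 24.0)
    ta = spec.ta_mean + season + diurnal + _ar1(rngs["Ta"], n, 0.95, spec.ta_noise_sigma)

    # --- VPD through the Magnus curve; RH is a bounded AR(1) process
    rh = np.clip(spec.rh_mean + _ar1(rngs["RH"], n, 0.97, spec.rh_sigma), 0.05, 0.99)
    vpd = np.maximum(magnus_es(ta) * (1.0 - rh), spec.vpd_floor)

    # --- wind: Gaussian copula onto a Weibull margin keeps skew and memory
    z = _ar1(rngs["U"], n, spec.u_autocorr, 1.0)
    u = stats.weibull_min.ppf(np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12),
                              spec.u_shape, scale=spec.u_scale)

    # --- precipitation: sparse wet steps with exponential depth
    rng_p = rngs["PPT"]
    wet = rng_p.random(n) < spec.ppt_wet_prob
    ppt = np.where(wet, rng_p.exponential(spec.ppt_mean_intensity, size=n), 0.0)

    fields = {"Rg": rg, "Ta": ta, "VPD": vpd, "U": u, "PPT": ppt}
    series = {name: ForcingSeries(name, fields[name], timestamps)
              for name in spec.variables if name in fields}
    meta = {
        "site": "synthetic",
        "seed": spec.seed,
        "n_days": spec.n_days,
        "doy_range": (int(timestamps[0].dayofyear),
                      int(timestamps[-1].dayofyear)),
    }
    return ForcingSet(series, meta)


def daylight_mask(rg: ForcingSeries, threshold: float = 5.0) -> np.ndarray:
    """True where shortwave exceeds ``threshold`` W/m2 (daytime steps).

    Radiation is near zero but not exactly zero at night in real records, so
    the default keeps a small positive threshold.
    """
    if threshold < 0:
        raise ValueError("daylight threshold must be non-negative")
    return rg.values > threshold
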