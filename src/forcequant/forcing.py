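"""Data model and I/O for uniformly sampled forcing and flux time series.

Every downstream computation (quantizer fitting, entropy estimation, diurnal
sensitivity) assumes a strictly uniform time grid, so the containers here
validate it once at construction and the rest of the package can rely on it.
Missing values are carried as NaN and are never silently treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ForcingSeries",
    "FluxSeries",
    "ForcingSet",
    "read_forcing_csv",
    "write_series_csv",
    "diurnal_index",
    "day_of_year_labels",
]

#: conventional units for the variables handled throughout the package
DEFAULT_UNITS = {
    "Rg": "W/m2",
    "Ta": "degC",
    "VPD": "kPa",
    "U": "m/s",
    "PPT": "mm",
    "Pa": "kPa",
    "Ca": "ppm",
    "LAI": "m2/m2",
    "Fc": "umol/m2/s",
    "LE": "W/m2",
    "SH": "W/m2",
}


class GridError(ValueError):
    """Raised when a time series violates the uniform-grid contract."""


def _validate_grid(timestamps: pd.DatetimeIndex) -> pd.Timedelta:
    if len(timestamps) < 2:
        raise GridError("a series needs at least two timestamps")
    deltas = np.diff(timestamps.asi8)
    step = deltas[0]
    if step <= 0:
        raise GridError("timestamps must be strictly increasing")
    bad = np.nonzero(deltas != step)[0]
    if bad.size:
        i = int(bad[0])
        raise GridError(
            f"non-uniform time grid: interval between {timestamps[i]} and "
            f"{timestamps[i + 1]} is {pd.Timedelta(deltas[i], 'ns')}, expected "
            f"{pd.Timedelta(step, 'ns')}"
        )
    return pd.Timedelta(step, "ns")


@dataclass(frozen=True)
class _Series:
    """One uniformly sampled time-series variable."""

    name: str
    values: np.ndarray
    timestamps: pd.DatetimeIndex
    units: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        timestamps = pd.DatetimeIndex(self.timestamps)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(values) != len(timestamps):
            raise ValueError(
                f"{self.name}: {len(values)} values vs {len(timestamps)} timestamps"
            )
        _validate_grid(timestamps)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timestamps", timestamps)
        if not self.units:
            object.__setattr__(self, "units", DEFAULT_UNITS.get(self.name, ""))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def step(self) -> pd.Timedelta:
        return self.timestamps[1] - self.timestamps[0]

    @property
    def steps_per_day(self) -> int:
        """Number of samples per day (96 for 15-min data)."""
        per_day = pd.Timedelta(days=1) / self.step
        if abs(per_day - round(per_day)) > 1e-9:
            raise GridError(
                f"step {self.step} does not divide a day; diurnal analysis undefined"
            )
        return int(round(per_day))

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of explicitly flagged missing values."""
        return np.isnan(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "_Series":
        return replace(self, values=np.asarray(values, float),
                       name=name if name is not None else self.name)


class ForcingSeries(_Series):
    """Meteorological forcing variable (Rg, Ta, VPD, U, PPT, ...)."""


class FluxSeries(_Series):
    """Modelled or observed canopy-atmosphere flux (Fc, LE, SH)."""


@dataclass
class ForcingSet:
    """A bundle of forcing series sharing one time grid."""

    series: dict[str, ForcingSeries]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.series:
            raise ValueError("ForcingSet needs at least one series")
        names = list(self.series)
        ref = self.series[names[0]].timestamps
        for name in names[1:]:
            if not self.series[name].timestamps.equals(ref):
                raise GridError(f"series {name!r} is not on the shared time grid")

    def __getitem__(self, name: str) -> ForcingSeries:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return next(iter(self.series.values())).timestamps

    @property
    def steps_per_day(self) -> int:
        return next(iter(self.series.values())).steps_per_day

    def replace_series(self, name: str, values: np.ndarray) -> "ForcingSet":
        """Return a copy with one variable's values substituted."""
        if name not in self.series:
            raise KeyError(name)
        new = dict(self.series)
        new[name] = new[name].with_values(values)
        return ForcingSet(new, dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: s.values for name, s in self.series.items()},
            index=self.timestamps.rename("timestamp"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "ForcingSet":
        ts = pd.DatetimeIndex(frame.index)
        series = {
            str(c): ForcingSeries(str(c), frame[c].to_numpy(dtype=float), ts)
            for c in frame.columns
        }
        return cls(series, metadata or {})


def read_forcing_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    timestamp_column: str = "timestamp",
    timestamp_format: str | None = None,
) -> ForcingSet:
    """Read a delimited forcing file onto a verified uniform grid.

    Parameters
    ----------
    path : path-like
        CSV file with a header row and a timestamp column.
    column_map : mapping, optional
        ``{variable name: csv column}``; by default every non-timestamp
        column is taken as a variable under its own header.
    timestamp_column : str
        Header of the timestamp column.
    timestamp_format : str, optional
        Explicit ``strftime`` format; ISO-8601 is parsed automatically.

    Unparseable numeric cells become flagged missing values (NaN); an
    irregular time grid or a missing mapped column is a hard error.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if timestamp_column not in frame.columns:
        raise ValueError(f"timestamp column {timestamp_column!r} not found in {path}")
    ts = pd.to_datetime(frame[timestamp_column], format=timestamp_format)
    ts = pd.DatetimeIndex(ts)
    if column_map is None:
        column_map = {c: c for c in frame.columns if c != timestamp_column}
    series: dict[str, ForcingSeries] = {}
    for name, col in column_map.items():
        if col not in frame.columns:
            raise ValueError(f"mapped column {col!r} (variable {name!r}) missing from {path}")
        values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        series[name] = ForcingSeries(name, values, ts)
    return ForcingSet(series, {"source": str(path)})


def write_series_csv(data: ForcingSet | Iterable[_Series], path) -> None:
    """Write series to CSV such that a re-read reproduces values bit-for-bit.

    Floats are written with Python's shortest-roundtrip repr (pandas default),
    so ``read_forcing_csv(write_series_csv(x))`` is lossless for finite values
    and preserves missing flags (written as empty cells).
    """
    if isinstance(data, ForcingSet):
        frame = data.to_frame()
    else:
        data = list(data)
        if not data:
            raise ValueError("nothing to write")
        ref = data[0].timestamps
        for s in data[1:]:
            if not s.timestamps.equals(ref):
                raise GridError("all series written together must share a grid")
        frame = pd.DataFrame({s.name: s.values for s in data},
                             index=ref.rename("timestamp"))
    if frame.empty:
        raise ValueError("nothing to write")
    # shortest round-trip repr keeps values bit-exact through write/read
    frame.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S",
                 float_format=lambda x: repr(float(x)))


def diurnal_index(series: _Series, truncate: bool = False) -> np.ndarray:
    """Arrange a series as a days x time-of-day matrix.

    Element ``(d, t)`` is the value on day ``d`` at time-of-day step ``t``
    (``t = 0`` is the interval beginning 00:00 local time).  Flattening the
    result restores the original series.

    A partial final day is an error unless ``truncate`` is set.
    """
    spd = series.steps_per_day
    n = len(series)
    if n % spd:
        if not truncate:
            raise ValueError(
                f"length {n} is not a multiple of {spd} steps/day; "
                "pass truncate=True to drop the partial final day"
            )
        n -= n % spd
    return series.values[:n].reshape(-1, spd)


def day_of_year_labels(series: _Series) -> np.ndarray:
    """Day-of-year label for each whole day of the series grid."""
    spd = series.steps_per_day
    n_days = len(series) // spd
    return series.timestamps[: n_days * spd : spd].dayofyear.to_numpy()
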