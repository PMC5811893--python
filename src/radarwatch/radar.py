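"""XGPS radar-detector front end: comparator counting and the power index.

The logger converts 9.41 GHz X-band radar bursts into a low-frequency
power-indicator voltage (0-3.3 V). Instead of an ADC, the voltage is compared
every ``sample_period`` seconds against four reference voltages, each half the
previous (1.65, 0.825, 0.412, 0.206 V); a sample strictly above a reference
increments that comparator's counter, so a sample above 1.65 V increments all
four and the counts nest: c3 <= c2 <= c1 <= c0. The per-interval radar-level
power index is

    index = sqrt(8*C3 + 4*C2 + 2*C1 + C0)

a quantized-power integral over the interval. A fix is a *detection* when its
index is positive (equivalently C0 >= 1); contact-level debouncing belongs to
the encounter layer, not here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geo import GeoPoint

__all__ = [
    "DEFAULT_REFERENCE_VOLTAGES",
    "RadarConfig",
    "ComparatorCounts",
    "RadarRecord",
    "BirdTrip",
    "power_index",
    "power_index_arrays",
    "count_comparators",
    "extract_detections",
    "read_trip_csv",
    "write_trip_csv",
]

DEFAULT_REFERENCE_VOLTAGES = (1.65, 0.825, 0.412, 0.206)


@dataclass(frozen=True)
class RadarConfig:
    """Detector front-end configuration.

    ``sample_period`` defaults to 0.1 s (the comparator sampling cadence);
    ``integration_interval`` is the logging interval the counts accumulate
    over (deployments used 60, 120 or 300 s).
    """

    reference_voltages: tuple = DEFAULT_REFERENCE_VOLTAGES
    sample_period: float = 0.1
    max_signal: float = 3.3
    integration_interval: float = 120.0

    def __post_init__(self) -> None:
        v = self.reference_voltages
        if len(v) != 4 or any(a <= b for a, b in zip(v, v[1:])):
            raise ValueError("reference voltages must be 4 strictly decreasing values")
        for a, b in zip(v, v[1:]):
            if abs(a / b - 2.0) > 0.02:
                raise ValueError("each reference voltage must be half the previous (±1%)")
        if self.sample_period <= 0 or self.integration_interval <= 0 or self.max_signal <= 0:
            raise ValueError("sample_period, integration_interval, max_signal must be > 0")

    @property
    def n_samples(self) -> int:
        """Comparator samples per integration interval."""
        return int(round(self.integration_interval / self.sample_period))


class ComparatorCounts(NamedTuple):
    """Pulse counts above the four references (highest threshold first)."""

    c3: int
    c2: int
    c1: int
    c0: int


def power_index(counts) -> float:
    """Radar-level power index sqrt(8*c3 + 4*c2 + 2*c1 + c0).

    Zero iff all counts are zero; strictly monotone in every count.
    """
    c3, c2, c1, c0 = counts
    if min(c3, c2, c1, c0) < 0:
        raise ValueError(f"negative comparator count: {counts}")
    return math.sqrt(8.0 * c3 + 4.0 * c2 + 2.0 * c1 + c0)


def power_index_arrays(c3, c2, c1, c0) -> np.ndarray:
    """Vectorized :func:`power_index`."""
    c3, c2, c1, c0 = (np.asarray(c, dtype=float) for c in (c3, c2, c1, c0))
    if min(c.min(initial=0) for c in (c3, c2, c1, c0)) < 0:
        raise ValueError("negative comparator count")
    return np.sqrt(8.0 * c3 + 4.0 * c2 + 2.0 * c1 + c0)


def count_comparators(voltage_trace, config: RadarConfig = RadarConfig()) -> ComparatorCounts:
    """Count, per threshold, the samples strictly above it.

    Samples above ``max_signal`` saturate the detector: they are clipped and a
    RuntimeWarning reports how many. Ties at a threshold do not count.
    """
    v = np.asarray(voltage_trace, dtype=float)
    if v.size and v.min() < 0:
        raise ValueError("negative voltage sample")
    n_clipped = int(np.count_nonzero(v > config.max_signal))
    if n_clipped:
        warnings.warn(f"{n_clipped} samples above max_signal clipped (detector saturation)",
                      RuntimeWarning, stacklevel=2)
        v = np.minimum(v, config.max_signal)
    counts = tuple(int(np.count_nonzero(v > thr)) for thr in config.reference_voltages)
    return ComparatorCounts(*counts)


@dataclass(frozen=True)
class RadarRecord:
    """One radar detection: a fix whose integration interval saw signal."""

    t: int
    pos: GeoPoint
    counts: ComparatorCounts
    index: float


_COUNT_COLS = ["c3", "c2", "c1", "c0"]
_BASE_COLS = ["t", "lat", "lon"]


@dataclass
class BirdTrip:
    """One foraging trip of one logger-equipped bird.

    ``df`` holds one row per GPS fix: ``t`` (UTC seconds, strictly
    increasing), ``lat``, ``lon``, comparator counts ``c3..c0`` (if the
    firmware stored them) and ``radar_index``. The index is recomputed from
    counts whenever counts are present.
    """

    bird_id: str
    df: pd.DataFrame
    sex: str | None = None
    colony: GeoPoint | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        df = self.df
        for col in _BASE_COLS:
            if col not in df.columns:
                raise ValueError(f"trip frame missing column {col!r}")
        t = df["t"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"trip {self.bird_id}: timestamps not strictly increasing")
        if all(c in df.columns for c in _COUNT_COLS):
            df = df.copy()
            df["radar_index"] = power_index_arrays(*(df[c].to_numpy() for c in _COUNT_COLS))
            self.df = df
        elif "radar_index" not in df.columns:
            raise ValueError("trip frame needs either c3..c0 counts or radar_index")

    @property
    def t0(self) -> int:
        return int(self.df["t"].iloc[0])

    @property
    def t1(self) -> int:
        return int(self.df["t"].iloc[-1])

    @property
    def duration_h(self) -> float:
        return (self.t1 - self.t0) / 3600.0

    @property
    def has_counts(self) -> bool:
        return all(c in self.df.columns for c in _COUNT_COLS)


def extract_detections(trip: BirdTrip) -> pd.DataFrame:
    """All fixes of the trip with a positive power index, time-ordered.

    Returns a frame with ``t, lat, lon, radar_index`` (plus counts when
    stored); positions are those of the coincident GPS fixes. May be empty.
    """
    mask = trip.df["radar_index"].to_numpy() > 0
    cols = _BASE_COLS + (_COUNT_COLS if trip.has_counts else []) + ["radar_index"]
    return trip.df.loc[mask, cols].reset_index(drop=True)


def iter_records(detections: pd.DataFrame):
    """Yield :class:`RadarRecord` views of a detections frame."""
    has_counts = all(c in detections.columns for c in _COUNT_COLS)
    for row in detections.itertuples(index=False):
        counts = (ComparatorCounts(int(row.c3), int(row.c2), int(row.c1), int(row.c0))
                  if has_counts else ComparatorCounts(0, 0, 0, 0))
        yield RadarRecord(int(row.t), GeoPoint(row.lat, row.lon), counts, float(row.radar_index))


# ---------------------------------------------------------------------------
# Logger CSV dialect: bird_id, timestamp, lat, lon, then either c3..c0 or
# radar_index. Timestamps ISO-8601 UTC; header row required.

def _iso_to_epoch(series: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(series, utc=True, format="ISO8601")
    return (ts.astype("int64") // 10**9).to_numpy()


def _epoch_to_iso(t: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.asarray(t, dtype="int64"), unit="s", utc=True).strftime(
        "%Y-%m-%dT%H:%M:%SZ")


def read_trip_csv(path, sex: str | None = None, colony: GeoPoint | None = None,
                  complete: bool = True) -> BirdTrip:
    """Read one trip in the logger CSV dialect (counts or index variant)."""
    raw = pd.read_csv(path)
    required = {"bird_id", "timestamp", "lat", "lon"}
    if not required.issubset(raw.columns):
        raise ValueError(f"{path}: logger CSV needs columns {sorted(required)}")
    bird_ids = raw["bird_id"].unique()
    if len(bird_ids) != 1:
        raise ValueError(f"{path}: expected a single bird_id, found {list(bird_ids)}")
    df = pd.DataFrame({"t": _iso_to_epoch(raw["timestamp"]),
                       "lat": raw["lat"].astype(float),
                       "lon": raw["lon"].astype(float)})
    if set(_COUNT_COLS).issubset(raw.columns):
        for c in _COUNT_COLS:
            df[c] = raw[c].astype(np.int64)
    elif "radar_index" in raw.columns:
        df["radar_index"] = raw["radar_index"].astype(float)
    else:
        raise ValueError(f"{path}: need either c3..c0 columns or radar_index")
    return BirdTrip(bird_id=str(bird_ids[0]), df=df, sex=sex, colony=colony,
                    complete=complete)


def write_trip_csv(trip: BirdTrip, path, dialect: str = "counts") -> None:
    """Write a trip in the logger CSV dialect (``counts`` or ``index``)."""
    if dialect not in ("counts", "index"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = pd.DataFrame({"bird_id": trip.bird_id,
                        "timestamp": _epoch_to_iso(trip.df["t"].to_numpy()),
                        "lat": trip.df["lat"], "lon": trip.df["lon"]})
    if dialect == "counts":
        if not trip.has_counts:
            raise ValueError("trip stores no comparator counts; use dialect='index'")
        for c in _COUNT_COLS:
            out[c] = trip.df[c].astype(np.int64)
    else:
        out["radar_index"] = trip.df["radar_index"]
    out.to_csv(path, index=False)
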