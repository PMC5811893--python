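"""Spatiotemporal matching of radar detections to VMS vessel reports.

VMS (vessel monitoring system) positions arrive hourly; detections are
1-5 min apart. For each detection, every vessel with pings bracketing the
detection time (bracket gap <= 90 min, tolerating one missed ping) is
linearly interpolated to the detection time; the nearest vessel within the
match radius is assigned, otherwise the detection is *undeclared* — the
signature of a vessel emitting radar but reporting no position.

The default 6 km radius covers the detector's ~5.5 km reception ceiling plus
interpolation slack of the hourly pings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import interpolate_track, pairwise_haversine_km
from .radar import _epoch_to_iso, _iso_to_epoch

__all__ = [
    "MatchResult",
    "match_detections",
    "match_detection",
    "distance_intensity_table",
    "attribute_events",
    "read_vms_csv",
    "write_vms_csv",
    "DEFAULT_BIN_EDGES_KM",
]

#: distance-bin breakpoints echoing the reported reception structure
#: (detections mainly 0.2-2 km, up to 5.5 km)
DEFAULT_BIN_EDGES_KM = (0.0, 0.2, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 5.5, 6.0)

MAX_BRACKET_S = 90 * 60


@dataclass(frozen=True)
class MatchResult:
    """Nearest declared vessel at one detection, or NONE (undeclared)."""

    t: int
    vessel_id: str | None
    distance_km: float
    interp_gap_s: float
    radar_index: float = float("nan")


def match_detections(detections: pd.DataFrame, vms: pd.DataFrame,
                     match_radius_km: float = 6.0,
                     max_bracket_s: float = MAX_BRACKET_S) -> pd.DataFrame:
    """Match every detection to its nearest bracketed VMS vessel.

    ``detections`` needs columns ``t, lat, lon`` (``radar_index`` carried
    through when present); ``vms`` needs ``vessel_id, t, lat, lon``. Returns
    one row per detection: ``t, vessel_id, distance_km, interp_gap_s,
    radar_index`` with ``vessel_id`` empty-string for undeclared. Vessels
    without a valid bracket at a detection are skipped, never extrapolated.
    """
    if match_radius_km <= 0:
        raise ValueError("match_radius_km must be > 0")
    n = len(detections)
    t = detections["t"].to_numpy(dtype=np.int64)
    lat = detections["lat"].to_numpy(dtype=float)
    lon = detections["lon"].to_numpy(dtype=float)
    best_d = np.full(n, np.inf)
    best_v = np.full(n, "", dtype=object)
    best_gap = np.full(n, np.nan)
    # lexicographic vessel order makes equal-distance ties deterministic
    for vid in sorted(vms["vessel_id"].unique()):
        sub = vms[vms["vessel_id"] == vid].sort_values("t")
        vt = sub["t"].to_numpy(dtype=np.int64)
        if len(vt) < 2 or np.any(np.diff(vt) <= 0):
            if len(vt) < 2:
                continue
            raise ValueError(f"vessel {vid}: VMS timestamps not strictly increasing")
        idx = np.searchsorted(vt, t, side="right")
        ok = (idx > 0) & (idx < len(vt))
        i0 = np.clip(idx - 1, 0, len(vt) - 1)
        i1 = np.clip(idx, 0, len(vt) - 1)
        gap = vt[i1] - vt[i0]
        exact = np.isin(t, vt)
        ok = (ok | exact) & ((gap <= max_bracket_s) | exact)
        if not ok.any():
            continue
        vlat, vlon = interpolate_track(vt, sub["lat"].to_numpy(), sub["lon"].to_numpy(),
                                       np.clip(t[ok], vt[0], vt[-1]))
        d = pairwise_haversine_km(lat[ok], lon[ok], vlat, vlon)
        better = np.zeros(n, dtype=bool)
        better[ok] = d < best_d[ok]
        best_d[better] = d[better[ok]]
        best_v[better] = vid
        best_gap[better] = gap[better]
    within = best_d <= match_radius_km
    out = pd.DataFrame({
        "t": t,
        "vessel_id": np.where(within, best_v, ""),
        "distance_km": np.where(within, best_d, np.nan),
        "interp_gap_s": np.where(within, best_gap, np.nan),
    })
    out["nearest_distance_km"] = np.where(np.isfinite(best_d), best_d, np.nan)
    if "bird_id" in detections.columns:
        out.insert(0, "bird_id", detections["bird_id"].to_numpy())
    if "radar_index" in detections.columns:
        out["radar_index"] = detections["radar_index"].to_numpy()
    return out


def match_detection(t: int, lat: float, lon: float, vms: pd.DataFrame,
                    match_radius_km: float = 6.0) -> MatchResult:
    """Single-detection convenience wrapper around :func:`match_detections`."""
    row = match_detections(pd.DataFrame({"t": [t], "lat": [lat], "lon": [lon]}),
                           vms, match_radius_km).iloc[0]
    vid = row["vessel_id"] or None
    return MatchResult(t=int(t), vessel_id=vid,
                       distance_km=float(row["distance_km"]) if vid else float("nan"),
                       interp_gap_s=float(row["interp_gap_s"]) if vid else float("nan"))


def distance_intensity_table(matches: pd.DataFrame,
                             bin_edges_km=DEFAULT_BIN_EDGES_KM) -> pd.DataFrame:
    """Distance-binned counts and power-index summaries of matched detections.

    Requires ``distance_km`` and ``radar_index`` columns; empty bins are
    reported with n = 0, not dropped.
    """
    edges = np.asarray(bin_edges_km, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0) or np.any(edges < 0):
        raise ValueError("bin edges must be non-negative and strictly increasing")
    m = matches.dropna(subset=["distance_km"])
    if len(m) == 0:
        raise ValueError("no matched detections to bin")
    cut = pd.cut(m["distance_km"], edges, include_lowest=True)
    grp = m.groupby(cut, observed=False)["radar_index"]
    table = pd.DataFrame({
        "bin_low_km": edges[:-1],
        "bin_high_km": edges[1:],
        "n": grp.size().to_numpy(),
        "mean_index": grp.mean().to_numpy(),
        "median_index": grp.median().to_numpy(),
    })
    return table


def attribute_events(events: list, matches: pd.DataFrame,
                     min_frac: float = 0.5) -> list:
    """Attribute each contact event to the modal matched vessel.

    The event's vessel is the most frequent vessel among its detections'
    matches, provided it accounts for at least ``min_frac`` of the *matched*
    detections; otherwise the event stays unattributed (undeclared or
    ambiguous). Ties break lexicographically. When the matches frame carries
    a ``bird_id`` column, lookups are keyed per bird (timestamps alone are
    not unique across birds).
    """
    if "bird_id" in matches.columns:
        lookup = {(b, t): v for b, t, v in
                  zip(matches["bird_id"], matches["t"], matches["vessel_id"])}
        def vessels_of(ev):
            return [lookup.get((ev.bird_id, t), "") for t in ev.detections["t"]]
    else:
        by_t = dict(zip(matches["t"], matches["vessel_id"]))
        def vessels_of(ev):
            return [by_t.get(t, "") for t in ev.detections["t"]]
    for ev in events:
        vs = pd.Series(vessels_of(ev), dtype=object)
        vs = vs[vs != ""]
        if len(vs) == 0:
            ev.matched_vessel = None
            continue
        counts = vs.value_counts()
        top = counts.max()
        modal = sorted(counts[counts == top].index)[0]
        ev.matched_vessel = modal if top / len(vs) >= min_frac else None
    return events


# ---------------------------------------------------------------------------
# VMS CSV dialect: vessel_id, timestamp, lat, lon (ISO-8601 UTC)

def read_vms_csv(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    need = {"vessel_id", "timestamp", "lat", "lon"}
    if not need.issubset(raw.columns):
        raise ValueError(f"{path}: VMS CSV needs columns {sorted(need)}")
    return pd.DataFrame({"vessel_id": raw["vessel_id"].astype(str),
                         "t": _iso_to_epoch(raw["timestamp"]),
                         "lat": raw["lat"].astype(float),
                         "lon": raw["lon"].astype(float)})


def write_vms_csv(vms: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"vessel_id": vms["vessel_id"],
                        "timestamp": _epoch_to_iso(vms["t"].to_numpy()),
                        "lat": vms["lat"], "lon": vms["lon"]})
    out.to_csv(path, index=False)
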