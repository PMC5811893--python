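"""Trip- and population-level summaries, sex comparisons, and geo export.

The behavior table is the Table-1 analog: per class, mean and min-max event
duration, frequency as a percentage of classified events, and time in
contact as a percentage of total trip time. Percent-of-trip contact uses the
union of event intervals so simultaneous contacts never double count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .encounter import BehaviorClass
from .geo import GeoPoint, pairwise_haversine_km
from .radar import BirdTrip

__all__ = [
    "TripSummary",
    "summarize_trip",
    "behavior_table",
    "chi_square_yates",
    "one_way_f",
    "sex_comparison",
    "export_geojson",
    "export_kml",
    "EmptyTableError",
]


class EmptyTableError(ValueError):
    """Raised when a summary is requested over zero events."""


@dataclass
class TripSummary:
    """Per-trip rollup of contact with radar-emitting vessels."""

    bird_id: str
    sex: str | None
    duration_h: float
    complete: bool
    detected_any: bool
    pct_time_in_contact: float
    max_range_km: float
    southernmost_lat: float
    class_duration_h: dict
    class_event_count: dict
    mean_contact_lat: float = float("nan")


def _union_seconds(intervals) -> float:
    """Total length of the union of [start, end] intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    total, cur_s, cur_e = 0.0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def summarize_trip(trip: BirdTrip, events: list, colony: GeoPoint) -> TripSummary:
    """Roll one trip up: contact fraction (interval union), range, per-class totals."""
    for ev in events:
        if ev.start < trip.t0 or ev.end > trip.t1:
            raise ValueError(f"event {ev.event_id} outside trip span")
    dur_s = trip.t1 - trip.t0
    contact_s = _union_seconds((ev.start, ev.end) for ev in events)
    lat = trip.df["lat"].to_numpy()
    lon = trip.df["lon"].to_numpy()
    rng_km = float(np.max(pairwise_haversine_km(lat, lon, colony.lat, colony.lon)))
    class_dur = {c: 0.0 for c in BehaviorClass}
    class_n = {c: 0 for c in BehaviorClass}
    contact_lats = []
    for ev in events:
        if ev.behavior is not None:
            class_dur[ev.behavior] += ev.duration_h
            class_n[ev.behavior] += 1
        contact_lats.append(float(ev.detections["lat"].mean()))
    return TripSummary(
        bird_id=trip.bird_id, sex=trip.sex, duration_h=dur_s / 3600.0,
        complete=trip.complete, detected_any=len(events) > 0,
        pct_time_in_contact=100.0 * contact_s / dur_s if dur_s else 0.0,
        max_range_km=rng_km, southernmost_lat=float(lat.min()),
        class_duration_h=class_dur, class_event_count=class_n,
        mean_contact_lat=float(np.mean(contact_lats)) if contact_lats else float("nan"))


def behavior_table(events: list, summaries: list) -> pd.DataFrame:
    """Population behavior table over classified events.

    ``frequency_pct`` is the class share of classified events (sums to 100);
    ``pct_contact_time`` is class contact time over total trip time of all
    summarized trips, so the rows sum to the overall percent-of-trip contact
    fraction.
    """
    classified = [ev for ev in events if ev.behavior is not None]
    if not classified:
        raise EmptyTableError("no classified events to tabulate")
    total_trip_h = sum(s.duration_h for s in summaries)
    rows = []
    for cls in BehaviorClass:
        durs = [ev.duration_h for ev in classified if ev.behavior == cls]
        rows.append({
            "behavior": cls,
            "n_events": len(durs),
            "mean_duration_h": float(np.mean(durs)) if durs else float("nan"),
            "min_duration_h": float(np.min(durs)) if durs else float("nan"),
            "max_duration_h": float(np.max(durs)) if durs else float("nan"),
            "frequency_pct": 100.0 * len(durs) / len(classified),
            "pct_contact_time": (100.0 * sum(durs) / total_trip_h
                                 if total_trip_h else float("nan")),
        })
    return pd.DataFrame(rows)


def chi_square_yates(table) -> float:
    """Yates-corrected chi-square statistic of a 2x2 contingency table.

    Expected counts come from the margins; each cell contributes
    ``(max(|O - E| - 0.5, 0))^2 / E`` — the correction is floored, so a table
    with |O - E| < 0.5 scores exactly 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: statistic undefined")
    expected = np.outer(rows, cols) / n
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    return float(np.sum(adj ** 2 / expected))


def one_way_f(group_a, group_b) -> tuple:
    """One-way ANOVA F statistic of two groups: (F, df1, df2)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero within-group variance in both groups: F undefined")
    f, _ = sps.f_oneway(a, b)
    return float(f), 1, len(a) + len(b) - 2


def sex_comparison(summaries: list, metric: str = "mean_contact_lat") -> dict:
    """Attendance-by-sex 2x2 (Yates chi-square) and a per-bird metric ANOVA."""
    females = [s for s in summaries if s.sex == "F"]
    males = [s for s in summaries if s.sex == "M"]
    table = [[sum(s.detected_any for s in females), sum(not s.detected_any for s in females)],
             [sum(s.detected_any for s in males), sum(not s.detected_any for s in males)]]
    out = {"contingency": table}
    try:
        stat = chi_square_yates(table)
        out["chi_square_yates"] = stat
        out["chi_square_df"] = 1
        out["chi_square_p"] = float(sps.chi2.sf(stat, 1))
    except ValueError:
        out["chi_square_yates"] = float("nan")
    fa = [getattr(s, metric) for s in females if math.isfinite(getattr(s, metric))]
    ma = [getattr(s, metric) for s in males if math.isfinite(getattr(s, metric))]
    if len(fa) >= 2 and len(ma) >= 2:
        try:
            f, df1, df2 = one_way_f(fa, ma)
            out["anova"] = {"metric": metric, "F": f, "df1": df1, "df2": df2,
                            "p": float(sps.f.sf(f, df1, df2))}
        except ValueError:
            out["anova"] = {"metric": metric, "F": float("nan")}
    return out


# ---------------------------------------------------------------------------
# geographic export

def _track_feature(kind: str, ident: str, lat, lon, props=None) -> dict:
    coords = [[round(float(x), 6), round(float(y), 6)] for y, x in zip(lat, lon)]
    return {"type": "Feature",
            "properties": {"kind": kind, "id": ident, **(props or {})},
            "geometry": {"type": "LineString", "coordinates": coords}}


def export_geojson(path, trips=(), events=(), vessels=()) -> dict:
    """Write trips and vessel paths as LineStrings and detections as Points
    (RFC 7946 [lon, lat] order) for map inspection; returns the collection."""
    features = []
    for trip in trips:
        features.append(_track_feature("bird_track", trip.bird_id,
                                       trip.df["lat"], trip.df["lon"],
                                       {"sex": trip.sex}))
    for v in vessels:
        features.append(_track_feature("vessel_track", v.vessel_id,
                                       v.df["lat"], v.df["lon"]))
    for ev in events:
        for row in ev.detections.itertuples(index=False):
            features.append({
                "type": "Feature",
                "properties": {"kind": "detection", "event_id": ev.event_id,
                               "behavior": ev.behavior,
                               "radar_index": round(float(row.radar_index), 4)},
                "geometry": {"type": "Point",
                             "coordinates": [round(float(row.lon), 6),
                                             round(float(row.lat), 6)]}})
    collection = {"type": "FeatureCollection", "features": features}
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(collection, fh, indent=1)
    except OSError as exc:
        raise OSError(f"GeoJSON export to {path} failed: {exc}") from exc
    return collection


def export_kml(path, trips=(), vessels=()) -> None:
    """Minimal KML export of bird and vessel tracks (one Placemark each)."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<kml xmlns="http://www.opengis.net/kml/2.2"><Document>']
    def placemark(name, lat, lon):
        coords = " ".join(f"{float(x):.6f},{float(y):.6f},0" for y, x in zip(lat, lon))
        lines.append(f"<Placemark><name>{name}</name><LineString><coordinates>"
                     f"{coords}</coordinates></LineString></Placemark>")
    for trip in trips:
        placemark(trip.bird_id, trip.df["lat"], trip.df["lon"])
    for v in vessels:
        placemark(v.vessel_id, v.df["lat"], v.df["lon"])
    lines.append("</Document></kml>")
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines))
    except OSError as exc:
        raise OSError(f"KML export to {path} failed: {exc}") from exc


def format_behavior_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of the behavior table."""
    hdr = f"{'Behavior':<12}{'Mean (h)':>10}{'Range (h)':>18}{'Freq (%)':>10}{'Contact (%)':>13}"
    out = [hdr, "-" * len(hdr)]
    for row in table.itertuples(index=False):
        rng = (f"{row.min_duration_h:.2f}-{row.max_duration_h:.2f}"
               if np.isfinite(row.min_duration_h) else "-")
        mean = f"{row.mean_duration_h:.2f}" if np.isfinite(row.mean_duration_h) else "-"
        pct = f"{row.pct_contact_time:.1f}" if np.isfinite(row.pct_contact_time) else "-"
        out.append(f"{row.behavior:<12}{mean:>10}{rng:>18}{row.frequency_pct:>10.1f}{pct:>13}")
    return "\n".join(out)
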