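"""Contact-event segmentation and behavioral classification.

Radar detections are grouped into maximal runs separated by no more than
``max_gap`` minutes, then each event is classified from the bird's track
kinematics over the event window:

* FLY_PAST — few detections (1-5), near-straight route, essentially no
  sitting: the bird passes the vessel without deviating;
* FOLLOW   — sustained near-linear flight at flight speed: the bird tracks a
  steaming vessel;
* ATTEND   — everything else, the area-restricted-search signature of a bird
  alternating sitting on the water with short flights at a (typically
  fishing) vessel. Events that show neither sit/fly alternation nor a tight
  bounding radius still fall here, flagged low-confidence.

The gap rule, speed threshold, and straightness cutoffs are operational
choices (the field definitions are qualitative); all are exposed in
:class:`EncounterConfig` and none is hard-coded elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import pairwise_haversine_km, straightness
from .radar import BirdTrip

__all__ = [
    "BehaviorClass",
    "EncounterConfig",
    "ContactEvent",
    "segment_contacts",
    "contact_features",
    "classify",
    "detect_and_classify",
    "events_to_frame",
]

FLY_PAST, FOLLOW, ATTEND = "FLY_PAST", "FOLLOW", "ATTEND"
BehaviorClass = (FLY_PAST, FOLLOW, ATTEND)


@dataclass(frozen=True)
class EncounterConfig:
    """Segmentation and classification thresholds.

    ``max_gap_min`` (15 = 3x the coarsest 5-min logging interval) bridges
    reception dropout without merging distinct encounters.
    ``flight_speed_threshold_kmh`` (10) bisects the bimodal drift-vs-flight
    speed distribution: drift is < 5 km/h, flight typically > 30 km/h.
    """

    max_gap_min: float = 15.0
    flight_speed_threshold_kmh: float = 10.0
    flypast_max_detections: int = 5
    flypast_min_straightness: float = 0.90
    flypast_max_sit_fraction: float = 0.10
    follow_min_straightness: float = 0.80
    follow_max_sit_fraction: float = 0.20
    attend_max_bounding_radius_km: float = 10.0


@dataclass
class ContactEvent:
    """A maximal run of radar detections with kinematic features."""

    bird_id: str
    event_id: str
    detections: pd.DataFrame
    start: int
    end: int
    # features (filled by contact_features)
    mean_speed_kmh: float = float("nan")
    straightness: float = float("nan")
    sit_fraction: float = float("nan")
    n_sit_bouts: int = 0
    n_fly_bouts: int = 0
    bounding_radius_km: float = float("nan")
    behavior: str | None = None
    matched_vessel: str | None = None
    low_confidence: bool = False

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / 3600.0

    @property
    def n_detections(self) -> int:
        return len(self.detections)


def segment_contacts(detections: pd.DataFrame, max_gap_min: float = 15.0,
                     bird_id: str = "") -> list:
    """Split time-ordered detections into maximal runs <= ``max_gap`` apart."""
    if len(detections) == 0:
        return []
    t = detections["t"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("detections must be time-ordered")
    breaks = np.nonzero(np.diff(t) > max_gap_min * 60.0)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(t) - 1]))
    events = []
    for k, (i, j) in enumerate(zip(starts, ends)):
        det = detections.iloc[i:j + 1].reset_index(drop=True)
        events.append(ContactEvent(
            bird_id=bird_id, event_id=f"{bird_id}-E{k:03d}", detections=det,
            start=int(t[i]), end=int(t[j])))
    return events


def _window_slice(trip: BirdTrip, start: int, end: int) -> pd.DataFrame:
    """Trip fixes in [start, end], padded to >= 3 fixes so that kinematics of
    single-detection events are defined."""
    t = trip.df["t"].to_numpy()
    i = int(np.searchsorted(t, start, side="left"))
    j = int(np.searchsorted(t, end, side="right"))
    while j - i < 3 and (i > 0 or j < len(t)):
        if i > 0:
            i -= 1
        if j - i < 3 and j < len(t):
            j += 1
    return trip.df.iloc[i:j]


def contact_features(event: ContactEvent, trip: BirdTrip,
                     config: EncounterConfig = EncounterConfig()) -> ContactEvent:
    """Fill the event's kinematic features from the owning trip.

    Per-fix flying/sitting labels come from the speed over the segment ending
    at each fix (>=/< the flight threshold); ``sit_fraction`` is sitting time
    over the window, bout counts are label run lengths, straightness spans
    the window, and the bounding radius is the maximal distance of window
    fixes from their centroid.
    """
    if event.start < trip.t0 or event.end > trip.t1:
        raise ValueError(f"trip {trip.bird_id} does not cover event window "
                         f"[{event.start}, {event.end}]")
    win = _window_slice(trip, event.start, event.end)
    t = win["t"].to_numpy()
    lat = win["lat"].to_numpy()
    lon = win["lon"].to_numpy()
    dt = np.diff(t)
    dist = pairwise_haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    speed = dist / (dt / 3600.0)
    total_s = float(dt.sum())
    flying = speed >= config.flight_speed_threshold_kmh
    event.mean_speed_kmh = float(dist.sum() / (total_s / 3600.0)) if total_s else 0.0
    event.sit_fraction = float(dt[~flying].sum() / total_s) if total_s else 0.0
    runs = np.nonzero(np.diff(flying.astype(int)))[0]
    n_runs = len(runs) + 1 if len(flying) else 0
    if n_runs:
        first_flying = bool(flying[0])
        n_fly = (n_runs + (1 if first_flying else 0)) // 2
        event.n_fly_bouts = n_fly
        event.n_sit_bouts = n_runs - n_fly
    event.straightness = straightness(lat, lon)
    clat, clon = float(lat.mean()), float(lon.mean())
    event.bounding_radius_km = float(np.max(pairwise_haversine_km(lat, lon, clat, clon)))
    return event


def classify(event: ContactEvent, config: EncounterConfig = EncounterConfig()) -> str:
    """Assign the behavior class; rule order breaks ties deterministically
    (FLY_PAST > FOLLOW > ATTEND)."""
    s = event.straightness
    if (event.n_detections <= config.flypast_max_detections
            and s >= config.flypast_min_straightness
            and event.sit_fraction < config.flypast_max_sit_fraction):
        event.behavior = FLY_PAST
    elif (s >= config.follow_min_straightness
          and event.sit_fraction < config.follow_max_sit_fraction
          and event.mean_speed_kmh >= config.flight_speed_threshold_kmh):
        event.behavior = FOLLOW
    else:
        event.behavior = ATTEND
        alternating = event.n_sit_bouts >= 1 and event.n_fly_bouts >= 1
        compact = event.bounding_radius_km <= config.attend_max_bounding_radius_km
        event.low_confidence = not (alternating or compact)
    return event.behavior


def detect_and_classify(trip: BirdTrip, config: EncounterConfig = EncounterConfig()) -> list:
    """Extract detections, segment into events, fill features, classify."""
    from .radar import extract_detections
    detections = extract_detections(trip)
    events = segment_contacts(detections, config.max_gap_min, bird_id=trip.bird_id)
    for ev in events:
        contact_features(ev, trip, config)
        classify(ev, config)
    return events


def events_to_frame(events: list) -> pd.DataFrame:
    """Events CSV layout (one row per classified contact event)."""
    from .radar import _epoch_to_iso
    rows = []
    for ev in events:
        rows.append({
            "bird_id": ev.bird_id,
            "event_id": ev.event_id,
            "start": _epoch_to_iso(np.array([ev.start]))[0],
            "end": _epoch_to_iso(np.array([ev.end]))[0],
            "duration_h": round(ev.duration_h, 6),
            "n_detections": ev.n_detections,
            "behavior": ev.behavior,
            "straightness": round(ev.straightness, 6) if np.isfinite(ev.straightness) else "",
            "sit_fraction": round(ev.sit_fraction, 6),
            "bounding_radius_km": round(ev.bounding_radius_km, 6),
            "matched_vessel": ev.matched_vessel or "",
        })
    return pd.DataFrame(rows, columns=[
        "bird_id", "event_id", "start", "end", "duration_h", "n_detections",
        "behavior", "straightness", "sit_fraction", "bounding_radius_km",
        "matched_vessel"])
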