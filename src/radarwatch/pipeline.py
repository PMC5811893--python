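"""End-to-end pipeline: simulate -> detect -> classify -> match -> summarize.

``run_all`` is deterministic under a fixed seed: repeated runs produce
byte-identical events CSV and report JSON.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .encounter import EncounterConfig, detect_and_classify, events_to_frame
from .evaluate import attribution_report, classification_report
from .radar import extract_detections, write_trip_csv, _epoch_to_iso
from .report import (EmptyTableError, behavior_table, export_geojson, sex_comparison,
                     summarize_trip)
from .simulate import SimConfig, StudyData, simulate_study, truths_to_frame
from .vms import (DEFAULT_BIN_EDGES_KM, attribute_events, distance_intensity_table,
                  match_detections, write_vms_csv)

__all__ = ["PipelineResult", "run_all", "write_outputs"]


@dataclass
class PipelineResult:
    study: StudyData
    events: list
    matches: pd.DataFrame
    summaries: list
    table: pd.DataFrame | None
    report: dict = field(default_factory=dict)


def _sanitize(obj):
    """Make a report JSON-strict (NaN/inf -> None) and key-stable."""
    if isinstance(obj, dict):
        return {k: _sanitize(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(x) for x in obj]
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    return obj


def config_hash(config: SimConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: SimConfig,
            enc_config: EncounterConfig = EncounterConfig(),
            match_radius_km: float = 6.0) -> PipelineResult:
    """Run the whole chain on a synthetic deployment and build the report."""
    study = simulate_study(config)
    events = []
    all_det = []
    for trip in study.trips:
        evs = detect_and_classify(trip, enc_config)
        events.extend(evs)
        det = extract_detections(trip)
        det.insert(0, "bird_id", trip.bird_id)
        all_det.append(det)
    detections = (pd.concat(all_det, ignore_index=True) if all_det
                  else pd.DataFrame(columns=["bird_id", "t", "lat", "lon", "radar_index"]))
    if len(detections) and len(study.vms):
        matches = match_detections(detections, study.vms, match_radius_km)
        attribute_events(events, matches)
    else:
        matches = pd.DataFrame(columns=["t", "vessel_id", "distance_km",
                                        "interp_gap_s", "radar_index"])
    ev_by_bird: dict = {}
    for ev in events:
        ev_by_bird.setdefault(ev.bird_id, []).append(ev)
    summaries = [summarize_trip(trip, ev_by_bird.get(trip.bird_id, []), config.colony)
                 for trip in study.trips]
    try:
        table = behavior_table(events, summaries)
    except EmptyTableError:
        table = None

    complete = [s for s in summaries if s.complete]
    with_contact = [s for s in summaries if s.detected_any]
    contact_pcts = [s.pct_time_in_contact for s in complete]
    n_matched = int((matches["vessel_id"] != "").sum()) if len(matches) else 0
    report = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_birds": len(study.trips),
        "n_complete_trips": len(complete),
        "n_truth_episodes": len(study.truths),
        "pct_loggers_with_contact": round(100.0 * len(with_contact) / len(summaries), 4)
        if summaries else None,
        "contact_pct_of_trip": {
            "mean": round(float(pd.Series(contact_pcts).mean()), 4) if contact_pcts else None,
            "sd": round(float(pd.Series(contact_pcts).std()), 4)
            if len(contact_pcts) > 1 else None,
            "min": round(min(contact_pcts), 4) if contact_pcts else None,
            "max": round(max(contact_pcts), 4) if contact_pcts else None,
        },
        "n_events": len(events),
        "n_detections": int(len(detections)),
        "n_detections_matched": n_matched,
        "n_detections_undeclared": int(len(detections)) - n_matched,
        "behavior_table": (table.round(4).to_dict(orient="records")
                           if table is not None else []),
        "sex_comparison": sex_comparison(summaries),
    }
    if study.truths:
        cls_rep = classification_report(study.truths, events)
        report["validation"] = {
            "per_class_recall": {k: round(v, 4) for k, v in
                                 cls_rep["per_class_recall"].items()},
            "macro_accuracy": round(cls_rep["macro_accuracy"], 4),
            "attribution": attribution_report(study, events),
        }
    return PipelineResult(study=study, events=events, matches=matches,
                          summaries=summaries, table=table,
                          report=_sanitize(report))


def write_outputs(result: PipelineResult, outdir: str) -> None:
    """Write the full artifact set under ``outdir`` (deterministic bytes)."""
    os.makedirs(outdir, exist_ok=True)
    tripdir = os.path.join(outdir, "trips")
    os.makedirs(tripdir, exist_ok=True)
    for trip in result.study.trips:
        write_trip_csv(trip, os.path.join(tripdir, f"{trip.bird_id}.csv"))
    write_vms_csv(result.study.vms, os.path.join(outdir, "vms.csv"))
    truth = truths_to_frame(result.study.truths)
    if len(truth):
        truth = truth.assign(start=_epoch_to_iso(truth["start"].to_numpy()),
                             end=_epoch_to_iso(truth["end"].to_numpy()))
    truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    events_to_frame(result.events).to_csv(os.path.join(outdir, "events.csv"), index=False)
    result.matches.round({"distance_km": 6, "nearest_distance_km": 6,
                          "radar_index": 6}).to_csv(
        os.path.join(outdir, "matched.csv"), index=False)
    if len(result.matches) and result.matches["distance_km"].notna().any():
        distance_intensity_table(result.matches, DEFAULT_BIN_EDGES_KM).round(6).to_csv(
            os.path.join(outdir, "distance_intensity.csv"), index=False)
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    manifest = {"config": result.study.config.to_dict(),
                "config_hash": config_hash(result.study.config)}
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(_sanitize(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    export_geojson(os.path.join(outdir, "tracks.geojson"),
                   trips=result.study.trips, events=result.events,
                   vessels=result.study.vessels)
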