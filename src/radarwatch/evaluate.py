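"""Scoring of pipeline output against simulator ground truth.

Used by the test suite and the acceptance script to measure classifier label
recovery and VMS attribution recall on synthetic deployments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encounter import BehaviorClass
from .geo import interpolate_track, pairwise_haversine_km
from .simulate import StudyData

__all__ = [
    "match_events_to_truth",
    "classification_report",
    "attribution_report",
    "truth_min_distances",
]


def _overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def match_events_to_truth(truths: list, events: list, pad_s: float = 600.0) -> list:
    """For each truth episode, the same-bird event with maximal time overlap
    (padded windows), or None if no event overlaps. Returns a parallel list."""
    by_bird: dict = {}
    for ev in events:
        by_bird.setdefault(ev.bird_id, []).append(ev)
    out = []
    for tr in truths:
        best, best_ov = None, 0.0
        for ev in by_bird.get(tr.bird_id, []):
            # pad the event too: a single-detection event has zero width
            ov = _overlap(tr.start - pad_s, tr.end + pad_s, ev.start - 60, ev.end + 60)
            if ov > best_ov:
                best, best_ov = ev, ov
        out.append(best)
    return out


def classification_report(truths: list, events: list) -> dict:
    """Per-class recall, macro accuracy (mean recall), overall accuracy and the
    confusion table of truth class vs predicted class ('MISSED' = no event)."""
    matched = match_events_to_truth(truths, events)
    labels = list(BehaviorClass) + ["MISSED"]
    confusion = pd.DataFrame(0, index=list(BehaviorClass), columns=labels)
    for tr, ev in zip(truths, matched):
        pred = ev.behavior if ev is not None else "MISSED"
        confusion.loc[tr.true_class, pred] += 1
    recall = {}
    for cls in BehaviorClass:
        n = int(confusion.loc[cls].sum())
        recall[cls] = float(confusion.loc[cls, cls] / n) if n else float("nan")
    valid = [r for r in recall.values() if np.isfinite(r)]
    correct = sum(int(confusion.loc[c, c]) for c in BehaviorClass)
    total = int(confusion.to_numpy().sum())
    return {
        "per_class_recall": recall,
        "macro_accuracy": float(np.mean(valid)) if valid else float("nan"),
        "overall_accuracy": correct / total if total else float("nan"),
        "n_truth": total,
        "confusion": confusion,
    }


def truth_min_distances(study: StudyData) -> list:
    """Minimum true bird-vessel distance within each truth episode window."""
    trips = {t.bird_id: t for t in study.trips}
    vessels = {v.vessel_id: v for v in study.vessels}
    out = []
    for tr in study.truths:
        trip = trips[tr.bird_id]
        v = vessels[tr.vessel_id]
        sel = trip.df[(trip.df["t"] >= tr.start) & (trip.df["t"] <= tr.end)]
        if len(sel) == 0:
            out.append(float("inf"))
            continue
        t = sel["t"].to_numpy()
        vlat, vlon = interpolate_track(v.t, v.df["lat"].to_numpy(),
                                       v.df["lon"].to_numpy(), t)
        d = pairwise_haversine_km(sel["lat"].to_numpy(), sel["lon"].to_numpy(), vlat, vlon)
        out.append(float(d.min()))
    return out


def attribution_report(study: StudyData, events: list, close_km: float = 2.0) -> dict:
    """Recall of vessel attribution over truth episodes that came within
    ``close_km`` of their vessel (the range at which reception is certain)."""
    matched = match_events_to_truth(study.truths, events)
    dmin = truth_min_distances(study)
    n_close = n_correct = 0
    for tr, ev, d in zip(study.truths, matched, dmin):
        if d > close_km:
            continue
        n_close += 1
        if ev is not None and ev.matched_vessel == tr.vessel_id:
            n_correct += 1
    return {"n_close_episodes": n_close,
            "n_correctly_attributed": n_correct,
            "recall": n_correct / n_close if n_close else float("nan")}
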