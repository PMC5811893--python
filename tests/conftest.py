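"""Shared fixtures: synthetic deployments computed once per session."""

import pandas as pd
import pytest

from radarwatch.encounter import detect_and_classify
from radarwatch.radar import extract_detections
from radarwatch.simulate import SimConfig, simulate_study
from radarwatch.vms import attribute_events, match_detections


class StudyBundle:
    """A simulated deployment with the full pipeline already run."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.study = simulate_study(config)
        self.events = []
        frames = []
        for trip in self.study.trips:
            self.events.extend(detect_and_classify(trip))
            det = extract_detections(trip)
            det.insert(0, "bird_id", trip.bird_id)
            frames.append(det)
        self.detections = (pd.concat(frames, ignore_index=True) if frames
                           else pd.DataFrame(columns=["bird_id", "t", "lat", "lon",
                                                      "radar_index"]))
        self.matches = match_detections(self.detections, self.study.vms)
        attribute_events(self.events, self.matches)


@pytest.fixture(scope="session")
def recovery_bundle() -> StudyBundle:
    """Large balanced-mix deployment: >= 200 scripted episodes per class,
    >= 10^4 detection intervals; drives the label-recovery and reception
    calibration checks."""
    cfg = SimConfig(seed=11, n_birds=160, n_vessels=6, trip_duration_h=72.0,
                    p_episode=0.9, episode_mix=(1.0, 1.0, 1.0),
                    incomplete_fraction=0.0)
    return StudyBundle(cfg)


@pytest.fixture(scope="session")
def small_bundle() -> StudyBundle:
    """Compact default-conditions deployment for summary/reporting tests."""
    cfg = SimConfig(seed=3, n_birds=12, n_vessels=4, trip_duration_h=48.0,
                    p_episode=0.6, incomplete_fraction=0.0)
    return StudyBundle(cfg)
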