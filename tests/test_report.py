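"""Summaries, behavior table, contingency statistics, geographic export."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radarwatch.encounter import ATTEND, ContactEvent
from radarwatch.geo import GeoPoint
from radarwatch.radar import BirdTrip
from radarwatch.report import (EmptyTableError, behavior_table, chi_square_yates,
                               export_geojson, export_kml, one_way_f, sex_comparison,
                               summarize_trip)


def _yates_brute_force(table):
    """Independent re-derivation: expected from margins, floored correction."""
    (a, b), (c, d) = table
    n = a + b + c + d
    out = 0.0
    for obs, r, col in ((a, a + b, a + c), (b, a + b, b + d),
                        (c, c + d, a + c), (d, c + d, b + d)):
        e = r * col / n
        out += max(abs(obs - e) - 0.5, 0.0) ** 2 / e
    return out


class TestChiSquareYates:
    def test_field_worked_example(self):
        # 16 of 22 females vs 16 of 18 males attending vessels
        stat = chi_square_yates([[16, 6], [16, 2]])
        assert round(stat, 2) == 0.76

    def test_proportional_table_is_zero(self):
        assert chi_square_yates([[10, 10], [10, 10]]) == 0.0

    def test_diagonal_table(self):
        assert chi_square_yates([[5, 0], [0, 5]]) == pytest.approx(6.4)

    def test_floored_correction_yields_zero(self):
        # |O - E| = 0.2 < 0.5 in every cell -> every term floored to 0
        assert chi_square_yates([[1, 1], [1, 2]]) == 0.0

    def test_exhaustive_against_brute_force(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = chi_square_yates([[a, b], [c, d]])
            assert got == pytest.approx(_yates_brute_force([[a, b], [c, d]]), abs=1e-9)

    def test_agrees_with_scipy_when_correction_not_floored(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 25:
            t = rng.integers(1, 30, (2, 2))
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            if np.abs(t - expected).min() < 0.5:
                continue
            stat, _, _, _ = sps.chi2_contingency(t, correction=True)[:4]
            assert chi_square_yates(t) == pytest.approx(stat, abs=1e-9)
            checked += 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_yates([[0, 0], [3, 4]])


class TestOneWayF:
    def test_textbook_example(self):
        f, df1, df2 = one_way_f([1, 2, 3], [4, 5, 6])
        assert f == pytest.approx(13.5)
        assert (df1, df2) == (1, 4)

    def test_identical_means_give_zero(self):
        f, _, _ = one_way_f([1, 2, 3], [3, 2, 1])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        f1, _, _ = one_way_f([1, 5, 2], [7, 3, 9])
        f2, _, _ = one_way_f([2, 1, 5], [9, 7, 3])
        assert f1 == pytest.approx(f2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_way_f([2, 2, 2], [5, 5])


def _trip(duration_h, bird_id="b", sex="F"):
    n = int(duration_h * 30) + 1
    t = np.arange(n, dtype=np.int64) * 120
    df = pd.DataFrame({"t": t, "lat": -46.0 - 0.001 * np.arange(n), "lon": 51.0,
                       "radar_index": 0.0})
    return BirdTrip(bird_id=bird_id, df=df, sex=sex, colony=GeoPoint(-46.0, 51.0))


def _event(start_h, end_h, behavior=ATTEND, bird_id="b"):
    det = pd.DataFrame({"t": np.asarray([start_h * 3600, end_h * 3600], dtype=np.int64),
                        "lat": [-46.0, -46.0], "lon": [51.0, 51.0],
                        "radar_index": [3.0, 3.0]})
    ev = ContactEvent(bird_id=bird_id, event_id=f"{bird_id}-E", detections=det,
                      start=int(start_h * 3600), end=int(end_h * 3600))
    ev.behavior = behavior
    return ev


class TestSummarizeTrip:
    def test_no_events(self):
        s = summarize_trip(_trip(10), [], GeoPoint(-46.0, 51.0))
        assert s.pct_time_in_contact == 0.0
        assert not s.detected_any

    def test_single_event_fraction(self):
        s = summarize_trip(_trip(10), [_event(2, 3)], GeoPoint(-46.0, 51.0))
        assert s.pct_time_in_contact == pytest.approx(10.0)

    def test_overlapping_events_union(self):
        s = summarize_trip(_trip(30), [_event(0, 2), _event(1, 3)], GeoPoint(-46.0, 51.0))
        assert s.pct_time_in_contact == pytest.approx(10.0)

    def test_event_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            summarize_trip(_trip(5), [_event(4, 9)], GeoPoint(-46.0, 51.0))

    def test_contact_never_exceeds_duration(self, small_bundle):
        for trip in small_bundle.study.trips:
            events = [e for e in small_bundle.events if e.bird_id == trip.bird_id]
            s = summarize_trip(trip, events, small_bundle.config.colony)
            assert 0.0 <= s.pct_time_in_contact <= 100.0

    def test_max_range_from_colony(self):
        s = summarize_trip(_trip(10), [], GeoPoint(-46.0, 51.0))
        assert s.max_range_km == pytest.approx(10 * 30 * 0.001 * 111.195, rel=0.01)


class TestBehaviorTable:
    def test_single_event_full_frequency(self):
        trips = [summarize_trip(_trip(10), [_event(1, 2)], GeoPoint(-46.0, 51.0))]
        table = behavior_table([_event(1, 2)], trips)
        att = table[table["behavior"] == ATTEND].iloc[0]
        assert att["frequency_pct"] == 100.0

    def test_mean_and_range(self):
        evs = [_event(0, 1), _event(5, 8)]
        trips = [summarize_trip(_trip(30), evs, GeoPoint(-46.0, 51.0))]
        att = behavior_table(evs, trips).set_index("behavior").loc[ATTEND]
        assert att["mean_duration_h"] == pytest.approx(2.0)
        assert (att["min_duration_h"], att["max_duration_h"]) == (1.0, 3.0)

    def test_empty_events_signalled(self):
        with pytest.raises(EmptyTableError):
            behavior_table([], [])

    def test_internal_consistency_on_simulation(self, small_bundle):
        from radarwatch.report import summarize_trip as st
        summaries = []
        for trip in small_bundle.study.trips:
            evs = [e for e in small_bundle.events if e.bird_id == trip.bird_id]
            summaries.append(st(trip, evs, small_bundle.config.colony))
        table = behavior_table(small_bundle.events, summaries)
        assert table["frequency_pct"].sum() == pytest.approx(100.0)
        # per-class contact percentages sum to the overall contact fraction
        total_trip_h = sum(s.duration_h for s in summaries)
        total_contact_h = sum(e.duration_h for e in small_bundle.events)
        assert table["pct_contact_time"].sum() == pytest.approx(
            100.0 * total_contact_h / total_trip_h)


class TestSexComparison:
    def test_contingency_margins(self):
        trips = [_trip(10, f"b{i}", "F" if i < 3 else "M") for i in range(5)]
        summaries = [summarize_trip(t, [_event(1, 2, bird_id=t.bird_id)] if i % 2 == 0
                                    else [], GeoPoint(-46.0, 51.0))
                     for i, t in enumerate(trips)]
        out = sex_comparison(summaries)
        table = np.asarray(out["contingency"])
        assert table.sum() == 5
        assert table[0].sum() == 3  # females


class TestGeoExport:
    def test_empty_collection_valid(self, tmp_path):
        path = tmp_path / "empty.geojson"
        out = export_geojson(path)
        assert out == {"type": "FeatureCollection", "features": []}
        assert json.load(open(path)) == out

    def test_two_fix_track_linestring(self, tmp_path):
        trip = _trip(1)
        out = export_geojson(tmp_path / "t.geojson", trips=[trip.__class__(
            bird_id="b", df=trip.df.iloc[:2], sex="F")])
        geom = out["features"][0]["geometry"]
        assert geom["type"] == "LineString"
        assert len(geom["coordinates"]) == 2

    def test_round_trip_preserves_coordinates(self, tmp_path, small_bundle):
        trip = small_bundle.study.trips[0]
        path = tmp_path / "trip.geojson"
        export_geojson(path, trips=[trip])
        back = json.load(open(path))
        coords = np.asarray(back["features"][0]["geometry"]["coordinates"])
        np.testing.assert_allclose(coords[:, 1], trip.df["lat"], atol=1e-6)
        np.testing.assert_allclose(coords[:, 0], trip.df["lon"], atol=1e-6)

    def test_kml_export_writes_placemarks(self, tmp_path):
        trip = _trip(1)
        path = tmp_path / "t.kml"
        export_kml(path, trips=[trip])
        text = path.read_text()
        assert "<Placemark>" in text and "kml" in text
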