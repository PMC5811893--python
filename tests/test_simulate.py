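"""Synthetic study generator: determinism, movement regimes, reception model."""

import numpy as np
import pandas as pd
import pytest

from radarwatch.geo import interpolate_track, pairwise_haversine_km, track_kinematics
from radarwatch.radar import BirdTrip, count_comparators, extract_detections
from radarwatch.simulate import (FISHING, STEAMING, SimConfig, VesselTrack, attach_radar,
                                 beam_envelope, count_from_peak_voltage, received_voltage,
                                 sample_vms, simulate_bird_trip, simulate_study,
                                 simulate_vessels, substream)


def small_cfg(**kw):
    base = dict(seed=1, n_birds=2, n_vessels=2, trip_duration_h=24.0,
                incomplete_fraction=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_same_vessels(self):
        a = simulate_vessels(small_cfg())
        b = simulate_vessels(small_cfg())
        for va, vb in zip(a, b):
            pd.testing.assert_frame_equal(va.df, vb.df)

    def test_same_seed_same_trip(self):
        cfg = small_cfg(p_episode=1.0, episode_mix=(1, 1, 1))
        vessels = simulate_vessels(cfg)
        t1, tr1 = simulate_bird_trip(cfg, vessels, "b", "F", substream(1, 2, 0))
        t2, tr2 = simulate_bird_trip(cfg, vessels, "b", "F", substream(1, 2, 0))
        pd.testing.assert_frame_equal(t1.df, t2.df)
        assert tr1 == tr2

    def test_different_birds_get_different_tracks(self):
        cfg = small_cfg()
        vessels = simulate_vessels(cfg)
        t1, _ = simulate_bird_trip(cfg, vessels, "a", "F", substream(1, 2, 0))
        t2, _ = simulate_bird_trip(cfg, vessels, "b", "F", substream(1, 2, 1))
        assert not t1.df["lat"].equals(t2.df["lat"])


class TestVessels:
    def test_steaming_speeds_in_band(self):
        cfg = small_cfg(n_vessels=3, trip_duration_h=120.0)
        for v in simulate_vessels(cfg):
            k = track_kinematics(v.df["t"], v.df["lat"], v.df["lon"])
            mode = v.df["mode"].to_numpy()
            # interior segments only: the segment into a bout's first fix
            # still moves at the previous bout's speed
            interior_steam = (mode[1:] == STEAMING) & (mode[:-1] == STEAMING)
            interior_fish = (mode[1:] == FISHING) & (mode[:-1] == FISHING)
            steam = k["speed_kmh"].to_numpy()[interior_steam]
            fish = k["speed_kmh"].to_numpy()[interior_fish]
            assert steam.min() >= cfg.steam_speed_kmh[0] - 0.5
            assert steam.max() <= cfg.steam_speed_kmh[1] + 0.5
            assert fish.max() < 6.0

    def test_zero_fishing_dwell_gives_all_steaming(self):
        cfg = small_cfg(fish_bout_h=(1e-9, 2e-9))
        v = simulate_vessels(cfg)[0]
        frac_fishing = (v.df["mode"] == FISHING).mean()
        assert frac_fishing < 0.01

    def test_mode_runs_partition_track(self):
        v = simulate_vessels(small_cfg())[0]
        runs = v.mode_runs()
        assert runs[0][1] == v.df["t"].iloc[0]
        assert runs[-1][2] == v.df["t"].iloc[-1]
        for (_, _, e0), (_, s1, _) in zip(runs, runs[1:]):
            assert s1 > e0


class TestSampleVms:
    def test_ping_count_on_hour_grid(self):
        cfg = small_cfg(trip_duration_h=10.0)
        v = simulate_vessels(cfg, window_margin_s=0)[0]
        pings = sample_vms(v, cfg)
        assert len(pings) in (10, 11)

    def test_pings_lie_on_dense_track(self):
        cfg = small_cfg()
        v = simulate_vessels(cfg)[0]
        pings = sample_vms(v, cfg)
        merged = pings.merge(v.df, on="t", suffixes=("_p", ""))
        assert len(merged) == len(pings)
        np.testing.assert_allclose(merged["lat_p"], merged["lat"], atol=1e-12)
        np.testing.assert_allclose(merged["lon_p"], merged["lon"], atol=1e-12)

    def test_empty_window(self):
        cfg = small_cfg()
        v = simulate_vessels(cfg)[0]
        short = VesselTrack(vessel_id="v", df=v.df.iloc[:2].reset_index(drop=True))
        assert len(sample_vms(short, cfg)) <= 1


class TestReceivedVoltage:
    def test_calibration_point_exact(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        assert float(received_voltage(5.5, cfg)) == pytest.approx(0.206, abs=1e-12)

    def test_upper_calibration_point(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        assert float(received_voltage(0.5, cfg)) == pytest.approx(1.65, rel=2e-3)

    def test_far_field_below_all_thresholds(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        assert float(received_voltage(1000.0, cfg)) < 0.206 / 50

    def test_monotone_falloff(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        d = np.linspace(0.05, 30, 500)
        v = received_voltage(d, cfg)
        assert np.all(np.diff(v) <= 1e-12)

    def test_at_mast_saturates(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        assert float(received_voltage(0.0, cfg)) == pytest.approx(3.3)

    def test_dropout_one_silences(self):
        cfg = small_cfg(dropout_p=1.0)
        v = received_voltage(np.full(50, 1.0), cfg, substream(1, 9))
        assert np.all(v == 0.0)


class TestBeamCounting:
    def test_counts_match_explicit_trace(self):
        cfg = small_cfg()
        env = beam_envelope(cfg)
        for v_peak in (0.3, 0.7, 1.8, 3.3):
            fast = [int(c[0]) for c in count_from_peak_voltage(v_peak, cfg)]
            slow = list(count_comparators(v_peak * env, cfg.radar))
            assert fast == slow

    def test_counts_increase_with_voltage(self):
        cfg = small_cfg()
        c_lo = count_from_peak_voltage(0.5, cfg)
        c_hi = count_from_peak_voltage(1.0, cfg)
        assert all(int(h[0]) >= int(l[0]) for h, l in zip(c_hi, c_lo))
        assert int(c_hi[3][0]) > int(c_lo[3][0])


def _stationary_vessel(cfg, lat, lon, mode=FISHING):
    n = int(cfg.trip_duration_h * 3600 / cfg.gps_interval_s) + 1
    t = cfg.t0_epoch_s + np.arange(n, dtype=np.int64) * cfg.gps_interval_s
    df = pd.DataFrame({"t": t, "lat": lat, "lon": lon, "mode": mode,
                       "heading_deg": 0.0})
    return VesselTrack(vessel_id="v00", df=df)


def _bird_at_distances(cfg, vessel_lat, vessel_lon, dist_km):
    """A trip whose fix i sits dist_km[i] due north of the vessel."""
    n = len(dist_km)
    t = cfg.t0_epoch_s + np.arange(n, dtype=np.int64) * cfg.gps_interval_s
    km_per_deg = 111.195
    df = pd.DataFrame({"t": t, "lat": vessel_lat + np.asarray(dist_km) / km_per_deg,
                       "lon": vessel_lon, "c3": 0, "c2": 0, "c1": 0, "c0": 0})
    return BirdTrip(bird_id="b", df=df)


class TestAttachRadar:
    def test_far_bird_all_counts_zero(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        vessel = _stationary_vessel(cfg, -46.0, 51.0)
        trip = _bird_at_distances(cfg, -46.0, 51.0, np.full(30, 25.0))
        out = attach_radar(trip, [vessel], cfg)
        assert (out.df[["c3", "c2", "c1", "c0"]].to_numpy() == 0).all()

    def test_bird_at_close_range_fires_all_comparators(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        vessel = _stationary_vessel(cfg, -46.0, 51.0)
        trip = _bird_at_distances(cfg, -46.0, 51.0, np.full(30, 0.3))
        out = attach_radar(trip, [vessel], cfg)
        counts = out.df[["c3", "c2", "c1", "c0"]].to_numpy()
        assert (counts > 0).all()
        assert len(set(map(tuple, counts))) == 1  # identical every interval

    def test_dropout_one_silences_everything(self):
        cfg = small_cfg(dropout_p=1.0)
        vessel = _stationary_vessel(cfg, -46.0, 51.0)
        trip = _bird_at_distances(cfg, -46.0, 51.0, np.full(30, 0.5))
        out = attach_radar(trip, [vessel], cfg, substream(1, 3, 0))
        assert (out.df[["c3", "c2", "c1", "c0"]].to_numpy() == 0).all()

    def test_radar_off_vessel_invisible(self):
        cfg = small_cfg(noise_sigma=0.0, dropout_p=0.0)
        vessel = _stationary_vessel(cfg, -46.0, 51.0)
        vessel.radar_on = False
        trip = _bird_at_distances(cfg, -46.0, 51.0, np.full(10, 0.5))
        out = attach_radar(trip, [vessel], cfg)
        assert (out.df["radar_index"] == 0).all()


class TestTripScripting:
    def test_zero_mix_is_pure_natural_foraging(self):
        cfg = small_cfg(episode_mix=(0, 0, 0))
        vessels = simulate_vessels(cfg)
        trip, truths = simulate_bird_trip(cfg, vessels, "b", "F", substream(1, 2, 0))
        assert truths == []

    def test_empty_vessel_list_with_mix_is_error(self):
        cfg = small_cfg()
        with pytest.raises(ValueError, match="vessel"):
            simulate_bird_trip(cfg, [], "b", "F", substream(1, 2, 0))

    def test_natural_foraging_never_enters_detection_range(self):
        # with no scripted episodes the bird must stay clear of every
        # emitter, so the radar channel stays silent even with noise on
        cfg = SimConfig(seed=4, n_birds=4, n_vessels=3, trip_duration_h=48.0,
                        episode_mix=(0, 0, 0), incomplete_fraction=0.0)
        study = simulate_study(cfg)
        for trip in study.trips:
            assert len(extract_detections(trip)) == 0

    def test_follow_truth_replay_distance(self):
        # during every scripted follow the bird stays glued to the vessel
        cfg = SimConfig(seed=6, n_birds=8, n_vessels=3, trip_duration_h=48.0,
                        p_episode=0.9, episode_mix=(0, 1, 0),
                        incomplete_fraction=0.0)
        study = simulate_study(cfg)
        follows = [t for t in study.truths if t.true_class == "FOLLOW"]
        assert len(follows) >= 5
        trips = {t.bird_id: t for t in study.trips}
        vessels = {v.vessel_id: v for v in study.vessels}
        for tr in follows:
            trip, v = trips[tr.bird_id], vessels[tr.vessel_id]
            sel = trip.df[(trip.df["t"] >= tr.start) & (trip.df["t"] <= tr.end)]
            vlat, vlon = interpolate_track(v.t, v.df["lat"].to_numpy(),
                                           v.df["lon"].to_numpy(), sel["t"].to_numpy())
            d = pairwise_haversine_km(sel["lat"].to_numpy(), sel["lon"].to_numpy(),
                                      vlat, vlon)
            assert d.max() < 1.5
            modes = [v.mode_at(t) for t in sel["t"]]
            assert modes.count(STEAMING) >= 0.95 * len(modes)

    def test_truth_intervals_non_overlapping_per_bird(self):
        cfg = SimConfig(seed=2, n_birds=6, n_vessels=3, trip_duration_h=48.0,
                        p_episode=0.9, episode_mix=(1, 1, 1), incomplete_fraction=0.0)
        study = simulate_study(cfg)
        by_bird = {}
        for tr in study.truths:
            by_bird.setdefault(tr.bird_id, []).append(tr)
        for trs in by_bird.values():
            trs.sort(key=lambda x: x.start)
            for a, b in zip(trs, trs[1:]):
                assert b.start > a.end

    def test_incomplete_trips_have_clipped_truth(self):
        cfg = SimConfig(seed=2, n_birds=10, n_vessels=3, trip_duration_h=48.0,
                        p_episode=0.9, episode_mix=(1, 1, 1),
                        incomplete_fraction=1.0)
        study = simulate_study(cfg)
        assert all(not t.complete for t in study.trips)
        ends = {t.bird_id: t.t1 for t in study.trips}
        for tr in study.truths:
            assert tr.end <= ends[tr.bird_id]

    def test_study_determinism(self):
        cfg = small_cfg(p_episode=0.9, episode_mix=(1, 1, 1))
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        for t1, t2 in zip(s1.trips, s2.trips):
            pd.testing.assert_frame_equal(t1.df, t2.df)
        assert s1.truths == s2.truths
        pd.testing.assert_frame_equal(s1.vms, s2.vms)
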