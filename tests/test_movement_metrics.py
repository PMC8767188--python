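"""Distance/speed summaries, straightness, confusion rates, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvftrack import (ConfusionSummary, EARTH_RADIUS_M, SyntheticScenario,
                      average_rates, evaluate_confusion, path_metrics,
                      run_pipeline, segment_bouts, simulate_scenario,
                      speed_vedba_regression, straightness_index)

M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


class TestConfusion:
    def test_rate_arithmetic(self):
        cs = ConfusionSummary(tp=19, fn=1, tn=79, fp=1)
        assert cs.tpr == pytest.approx(95.0)
        assert cs.fnr == pytest.approx(5.0)
        assert cs.tnr == pytest.approx(98.75)
        assert cs.fpr == pytest.approx(1.25)
        assert cs.accuracy == pytest.approx(98.0)

    def test_perfect_agreement(self):
        cs = evaluate_confusion([1, 1, 0, 0], ["moving", "moving",
                                               "non-moving", "non-moving"])
        assert cs.accuracy == 100.0

    def test_rate_pairing_mirrors_field_calibration(self):
        # counts chosen to land on the published 95.21/4.79 and 0.35/99.65 pairs
        cs = ConfusionSummary(tp=9521, fn=479, fp=35, tn=9965)
        assert cs.tpr == pytest.approx(95.21)
        assert cs.tpr == pytest.approx(100.0 - cs.fnr)
        assert cs.fnr == pytest.approx(4.79)
        assert cs.tnr == pytest.approx(99.65)
        assert cs.fpr == pytest.approx(100.0 - cs.tnr)

    @given(st.integers(0, 10_000), st.integers(0, 10_000),
           st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_complement_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        cs = ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)
        if tp + fn:
            assert cs.tpr + cs.fnr == pytest.approx(100.0)
        if fp + tn:
            assert cs.fpr + cs.tnr == pytest.approx(100.0)
        assert cs.accuracy == pytest.approx(
            100.0 * (tp + tn) / (tp + fp + tn + fn))

    def test_unlabelled_seconds_excluded(self):
        cs = evaluate_confusion([1, 0, 1], ["moving", None, "non-moving"])
        assert cs.tp == 1 and cs.fp == 1 and cs.tn == 0 and cs.fn == 0

    def test_no_labels_is_error(self):
        with pytest.raises(ValueError):
            evaluate_confusion([1, 0], [None, None])

    def test_average_rates_across_individuals(self):
        a = ConfusionSummary(tp=90, fn=10, fp=0, tn=100)
        b = ConfusionSummary(tp=100, fn=0, fp=10, tn=90)
        avg = average_rates([a, b])
        assert avg["tpr"] == pytest.approx(95.0)
        assert avg["fpr"] == pytest.approx(5.0)


def _track(lat, lon, mvf=None, speed=None, reason=None):
    n = len(lat)
    mvf = np.ones(n, dtype=int) if mvf is None else np.asarray(mvf)
    return pd.DataFrame({
        "time": np.arange(n), "lat": lat, "lon": lon,
        "speed": np.ones(n) if speed is None else speed,
        "mvf": mvf,
        "reason": reason if reason is not None else
        np.where(mvf == 1, "moving", "both_below"),
    })


class TestPathMetrics:
    def test_straight_path_distance_and_max_speed(self):
        lat = np.arange(101) / M_PER_DEG  # 1 m per second, due north
        tr = _track(lat, np.zeros(101))
        out = path_metrics(tr, state="moving")
        assert out.loc[0, "distance_m"] == pytest.approx(100.0, rel=1e-6)
        assert out.loc[0, "max_speed"] == pytest.approx(1.0)
        assert out.loc[0, "defined"]

    def test_empty_selection_flagged_undefined(self):
        tr = _track(np.zeros(10), np.zeros(10), mvf=np.zeros(10, dtype=int))
        out = path_metrics(tr, state="moving")
        assert out.loc[0, "distance_m"] == 0.0
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "mean_speed"])

    def test_outlier_seconds_excluded_from_non_moving(self):
        reason = np.array(["both_below"] * 8 + ["outlier_z", "missing"])
        lat = np.arange(10) / M_PER_DEG * 100.0
        tr = _track(lat, np.zeros(10), mvf=np.zeros(10, dtype=int),
                    reason=reason)
        out = path_metrics(tr, state="non-moving")
        # only the 8 behavioural seconds form the path: 7 steps of 100 m
        assert out.loc[0, "distance_m"] == pytest.approx(700.0, rel=1e-6)

    def test_hourly_distances_sum_to_total(self, small_run):
        track = small_run["track"]
        for state in ("moving", "non-moving", "all"):
            total = path_metrics(track, state=state).loc[0, "distance_m"]
            hourly = path_metrics(track, state=state, grouping="hourly")
            assert hourly["distance_m"].sum() == pytest.approx(total, rel=1e-9)

    def test_filtered_distance_never_exceeds_unfiltered(self, small_run):
        track = small_run["track"]
        unfiltered = path_metrics(track, state="all").loc[0, "distance_m"]
        filtered = path_metrics(track, state="moving").loc[0, "distance_m"]
        assert filtered <= unfiltered


class TestStraightness:
    def test_straight_path(self):
        lat = np.arange(50) / M_PER_DEG
        assert straightness_index(lat, np.zeros(50)) == pytest.approx(1.0, abs=1e-9)

    def test_closed_loop(self):
        th = np.linspace(0, 2 * np.pi, 100)
        lat = 50 * np.cos(th) / M_PER_DEG
        lon = 50 * np.sin(th) / M_PER_DEG
        assert straightness_index(lat, lon) == pytest.approx(0.0, abs=1e-6)

    def test_semicircular_arc(self):
        th = np.linspace(0, np.pi, 400)
        lat = 100 * np.cos(th) / M_PER_DEG
        lon = 100 * np.sin(th) / M_PER_DEG
        assert straightness_index(lat, lon) == pytest.approx(2 / np.pi, rel=0.01)

    def test_zero_length_path_undefined(self):
        assert np.isnan(straightness_index(np.zeros(5), np.zeros(5)))
        assert np.isnan(straightness_index([0.0], [0.0]))

    def test_bounded_on_random_walks(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            lat = np.cumsum(rng.normal(size=60)) / M_PER_DEG
            lon = np.cumsum(rng.normal(size=60)) / M_PER_DEG
            s = straightness_index(lat, lon)
            assert 0.0 <= s <= 1.0


class TestRegression:
    def _exact_line_fixture(self):
        # 3 moving bouts whose means lie exactly on y = 0.1 + 2x
        xs = [0.1, 0.2, 0.3]
        frames, bouts, t0 = [], [], 0
        for x in xs:
            n = 10
            frames.append(pd.DataFrame({
                "time": np.arange(t0, t0 + n), "vedba": x,
                "speed": 0.1 + 2 * x}))
            bouts.append({"start": t0, "end": t0 + n - 1, "state": "moving"})
            t0 += n + 5
        track = pd.concat(frames, ignore_index=True)
        return pd.DataFrame(bouts), track

    def test_exact_line_recovered(self):
        bouts, track = self._exact_line_fixture()
        fit = speed_vedba_regression(bouts, track)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 3

    def test_degenerate_fit_rejected(self):
        bouts, track = self._exact_line_fixture()
        track["vedba"] = 0.2
        with pytest.raises(ValueError, match="degenerate"):
            speed_vedba_regression(bouts, track)

    def test_too_few_bouts(self):
        bouts, track = self._exact_line_fixture()
        with pytest.raises(ValueError):
            speed_vedba_regression(bouts.iloc[:1], track)

    def test_synthetic_coupling_recovered(self):
        # outlier-free calibrated scenario: per-bout means must show the
        # positive speed~VeDBA coupling the generator encodes
        r2s, slopes = [], []
        for seed in (1, 2, 3):
            sc = SyntheticScenario(duration=43_200, seed=seed, p_outlier=0.0)
            gps, accel, _ = simulate_scenario(sc)
            track = run_pipeline(gps, accel)
            fit = speed_vedba_regression(segment_bouts(track), track)
            r2s.append(fit.r_squared)
            slopes.append(fit.slope)
        assert all(s > 0 for s in slopes)
        assert np.mean(r2s) > 0.2
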