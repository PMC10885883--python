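"""Threshold-crossing detection, birth prediction and herd evaluation."""

import numpy as np
import pandas as pd
import pytest

import kidwatch as kw
from kidwatch import detect
from kidwatch.errors import KidwatchError

STUDY_TCKG = 14_240.92


def series_of(lpis, start="2024-01-05 00:00:00", stride_min=10):
    t0 = pd.Timestamp(start)
    starts = [t0 + pd.Timedelta(minutes=stride_min * i)
              for i in range(len(lpis))]
    return pd.DataFrame({
        "goat_id": "goat01", "window_start": starts,
        "window_end": [s + pd.Timedelta(minutes=10) for s in starts],
        "ta": [max(int(v) // 40, 1) for v in lpis],
        "tlp": [40] * len(lpis), "lpi": lpis})


class TestDetectDay:
    def test_no_event_when_every_window_is_below_threshold(self):
        assert detect.detect_day(series_of([100, 5000, 12_000]),
                                 STUDY_TCKG) is None

    def test_threshold_is_strict(self):
        assert detect.detect_day(series_of([STUDY_TCKG]), STUDY_TCKG) is None

    def test_event_at_first_crossing(self):
        s = series_of([0, 20_000, 30_000])
        event = detect.detect_day(s, STUDY_TCKG)
        assert event is not None
        assert event.dpt == s["window_start"][1]
        assert event.lpi == 20_000

    def test_empty_series_warns_and_returns_no_event(self):
        with pytest.warns(UserWarning, match="empty"):
            assert detect.detect_day(series_of([]), STUDY_TCKG) is None

    def test_uncalibrated_threshold_rejected(self):
        with pytest.raises(KidwatchError):
            detect.detect_day(series_of([1.0]), 0.0)

    def test_all_zero_series_never_alarms(self):
        assert detect.detect_day(series_of([0] * 50), 1e-9) is None

    def test_first_crossing_matches_full_scan(self, rng):
        for _ in range(100):
            vals = rng.integers(0, 30_000, int(rng.integers(1, 60)))
            tckg = float(rng.integers(1, 25_000))
            event = detect.detect_day(series_of(vals.tolist()), tckg)
            above = [i for i, v in enumerate(vals) if v > tckg]
            if not above:
                assert event is None
            else:
                expect = series_of(vals.tolist())["window_start"][above[0]]
                assert event.dpt == expect
                for i in above:
                    assert event.dpt <= series_of(vals.tolist())[
                        "window_start"][i]


class TestPredictFirstBirth:
    def test_study_mean_offset_lands_on_the_expected_clock_time(self):
        ppt = detect.predict_first_birth(
            pd.Timestamp("2024-01-05 10:00:00"), 90.6)
        assert ppt == pd.Timestamp("2024-01-05 11:30:36")

    def test_zero_offset_is_identity(self):
        t = pd.Timestamp("2024-01-05 10:00:00")
        assert detect.predict_first_birth(t, 0.0) == t

    def test_shift_additivity(self):
        t = pd.Timestamp("2024-01-05 10:00:00")
        delta = pd.Timedelta(minutes=7)
        assert (detect.predict_first_birth(t + delta, 90.6)
                == detect.predict_first_birth(t, 90.6) + delta)


class FakeTruth:
    def __init__(self, goat_id, birth_time):
        self.goat_id = goat_id
        self.birth_time = pd.Timestamp(birth_time)


def _herd_events(n_goats, n_detected):
    truths = [FakeTruth(f"goat{i:02d}", "2024-01-05 12:00:00")
              for i in range(n_goats)]
    events = {}
    for i, gt in enumerate(truths):
        if i < n_detected:
            dpt = gt.birth_time - pd.Timedelta(minutes=90)
            events[gt.goat_id] = detect.DetectionEvent(
                gt.goat_id, dpt, dpt + pd.Timedelta(minutes=90),
                20_000, 500, 40)
        else:
            events[gt.goat_id] = None
    return events, truths


class TestEvaluate:
    def test_study_detection_rate_arithmetic(self):
        events, truths = _herd_events(17, 14)
        rep = detect.evaluate(events, truths)
        assert rep.detection_rate == 82.4
        assert rep.failure_rate == 17.6
        assert rep.n_missed == 3

    def test_single_miss_rate(self):
        events, truths = _herd_events(17, 16)
        rep = detect.evaluate(events, truths)
        assert rep.failure_rate == 5.9  # 1/17 rounds half-up to 5.9

    def test_zero_detections(self):
        events, truths = _herd_events(5, 0)
        rep = detect.evaluate(events, truths)
        assert rep.detection_rate == 0.0 and rep.failure_rate == 100.0

    def test_rates_sum_to_one_hundred_within_rounding(self):
        for n, d in [(17, 14), (17, 16), (3, 1), (7, 2)]:
            rep = detect.evaluate(*_herd_events(n, d))
            assert rep.detection_rate + rep.failure_rate == pytest.approx(
                100.0, abs=0.1)

    def test_clean_control_days_count_zero_false_alarms(self):
        events, truths = _herd_events(17, 17)
        rep = detect.evaluate(events, truths,
                              control_events={t.goat_id: None
                                              for t in truths})
        assert rep.false_alarms == 0

    def test_control_crossings_count_as_false_alarms(self):
        events, truths = _herd_events(3, 3)
        control = {t.goat_id: None for t in truths}
        control["goat00"] = events["goat00"]
        rep = detect.evaluate(events, truths, control)
        assert rep.false_alarms == 1

    def test_event_for_unknown_goat_rejected(self):
        events, truths = _herd_events(2, 2)
        events["goat99"] = events["goat00"]
        with pytest.raises(KidwatchError, match="goat99"):
            detect.evaluate(events, truths)

    def test_lead_times_are_birth_minus_detection(self):
        events, truths = _herd_events(4, 4)
        rep = detect.evaluate(events, truths)
        assert all(lead == pytest.approx(90.0)
                   for lead in rep.lead_times_min.values())


class TestRunPipeline:
    def test_detects_most_goats_with_no_control_alarms(
            self, study_streams, study_truths, study_model,
            study_calibration):
        calibration = study_calibration[0]
        events, control, report = detect.run_pipeline(
            study_streams, study_truths, study_model, calibration,
            day_hours=12.0)
        assert report.detection_rate >= 80.0
        assert report.false_alarms == 0
        # detections precede the recorded births
        for lead in report.lead_times_min.values():
            assert lead > 0

    def test_every_event_predicts_birth_at_dpt_plus_mdv(
            self, study_streams, study_truths, study_model,
            study_calibration):
        calibration = study_calibration[0]
        events, _, _ = detect.run_pipeline(
            study_streams, study_truths, study_model, calibration,
            day_hours=12.0)
        delta = pd.Timedelta(seconds=round(calibration.mdv_min * 60))
        for event in events.values():
            if event is not None:
                assert event.ppt - event.dpt == delta

    def test_labor_free_herd_raises_no_events(self, study_model,
                                              study_calibration):
        cfg = kw.SimulationConfig(n_goats=3, duration_hours=8.0,
                                  birth_offset_hours=6.0, seed=29,
                                  include_labor=False)
        herd = kw.simulate_herd(cfg)
        streams = [r for r, _ in herd]
        truths = [gt for _, gt in herd]
        events, _, report = detect.run_pipeline(
            streams, truths, study_model, study_calibration[0],
            day_hours=4.0)
        assert report.n_detected == 0

    def test_rerun_is_deterministic(self, study_streams, study_truths,
                                    study_model, study_calibration):
        kwargs = dict(day_hours=12.0)
        a = detect.run_pipeline(study_streams, study_truths, study_model,
                                study_calibration[0], **kwargs)
        b = detect.run_pipeline(study_streams, study_truths, study_model,
                                study_calibration[0], **kwargs)
        assert a[2] == b[2]


def test_events_frame_layout():
    events, _ = _herd_events(3, 2)
    frame = detect.events_frame(events)
    assert list(frame.columns) == ["goat_id", "dpt", "ppt", "lpi", "ta", "tlp"]
    assert len(frame) == 2


def test_notify_runs_the_alarm_template(tmp_path):
    events, _ = _herd_events(2, 2)
    log = tmp_path / "alarms.txt"
    detect.notify([e for e in events.values() if e],
                  f"echo {{goat_id}} >> {log}")
    assert log.read_text().splitlines() == ["goat00", "goat01"]
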