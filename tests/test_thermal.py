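"""Temperature-log calibration, cool-down and constancy QA."""

import numpy as np
import pytest

import coldtreat as ct
from coldtreat.synthetic import TemperatureProfile, gen_temperature_log
from coldtreat.thermal import apply_calibration


def probe(readings, hours=None, kind="fruit", pid="F1"):
    readings = np.asarray(readings, dtype=float)
    hours = np.arange(len(readings), dtype=float) * 0.5 if hours is None else hours
    return ct.TemperatureLog(probe_id=pid, kind=kind, hours=hours, readings=readings)


class TestCalibrate:
    def test_zero_bias_zero_offset(self):
        offs = ct.calibrate({"F1": np.zeros(60)})
        assert offs["F1"] == 0.0

    def test_published_mean_factor_magnitude(self):
        # probes reading +0.09 in the ice bath get the -0.09 correction
        offs = ct.calibrate({"F1": np.full(60, 0.09)})
        assert offs["F1"] == pytest.approx(-0.09)

    def test_hand_mean(self):
        offs = ct.calibrate({"F1": [0.1, 0.2] * 5})
        assert offs["F1"] == pytest.approx(-0.15)

    def test_corrected_ice_bath_mean_is_zero(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(0.07, 0.01, size=100)
        offs = ct.calibrate({"F1": raw})
        assert np.mean(raw + offs["F1"]) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_or_empty_readings_rejected(self):
        with pytest.raises(ValueError):
            ct.calibrate({"F1": []})
        with pytest.raises(ValueError):
            ct.calibrate({"F1": [0.1] * 5})

    def test_summary_invariant_to_constant_bias(self):
        # a constant bias is absorbed entirely by the calibration offset
        logs, _ = gen_temperature_log(TemperatureProfile(noise_sd=0.0), seed=0)
        biased = [
            ct.TemperatureLog(lg.probe_id, lg.kind, lg.hours, lg.readings + 0.7)
            for lg in logs
        ]
        offsets = ct.calibrate({lg.probe_id: np.full(20, 0.7) for lg in biased})
        corrected = apply_calibration(biased, offsets)
        s0 = ct.profile_summary(logs)
        s1 = ct.profile_summary(corrected)
        for field in ("start_mean", "overall_mean", "cooldown_hours",
                      "post_cooldown_mean", "post_cooldown_sd", "constancy_pct"):
            assert getattr(s1, field) == pytest.approx(getattr(s0, field), abs=1e-9)


class TestCooldown:
    def test_already_cold_zero_hours(self):
        logs = [probe([3.0] * 10, pid=f"F{i}") for i in range(3)]
        cd = ct.cooldown_time(logs)
        assert cd.reached and cd.hours == 0.0

    def test_majority_rule_brute_force(self):
        # 10 probes crossing one per hour from t=0: the 6th crossing (5 h)
        # is the first time strictly more than half read below threshold
        hours = np.arange(0.0, 12.0, 1.0)
        logs = []
        for i in range(10):
            readings = np.where(hours >= i, 3.0, 20.0)
            logs.append(probe(readings, hours=hours, pid=f"F{i}"))
        cd = ct.cooldown_time(logs, threshold=3.5, rule="majority")
        # independent brute force over samples
        mat = np.vstack([lg.readings for lg in logs])
        expect = next(
            h for j, h in enumerate(hours) if (mat[:, j] < 3.5).sum() > 5
        )
        assert cd.hours == expect == 5.0

    def test_analytic_crossing_within_one_sample(self):
        profile = TemperatureProfile(start_c=24.8, plateau_c=3.04,
                                     time_constant_h=13.0, noise_sd=0.05)
        logs, truth = gen_temperature_log(profile, seed=9)
        cd = ct.cooldown_time(logs)
        assert abs(cd.hours - truth["analytic_crossing_h"]) <= truth["sampling_interval_h"]

    def test_never_reached_flagged(self):
        logs = [probe([10.0] * 8, pid=f"F{i}") for i in range(2)]
        cd = ct.cooldown_time(logs)
        assert not cd.reached and np.isnan(cd.hours)

    def test_monotone_in_threshold(self):
        logs, _ = gen_temperature_log(seed=1)
        h = [ct.cooldown_time(logs, threshold=th).hours for th in (3.2, 3.5, 4.0, 5.0)]
        assert np.all(np.diff(h) <= 0)

    def test_mean_rule_available(self):
        logs, _ = gen_temperature_log(TemperatureProfile(noise_sd=0.0), seed=0)
        assert ct.cooldown_time(logs, rule="mean").reached


class TestConstancy:
    def test_constant_on_target(self):
        logs = [probe([3.0] * 20)]
        assert ct.constancy(logs, after=0) == 100.0

    def test_constant_off_target(self):
        logs = [probe([4.0] * 20)]
        assert ct.constancy(logs, after=0) == 0.0

    def test_alternating_half(self):
        logs = [probe([3.0, 4.0] * 10)]
        assert ct.constancy(logs, after=0) == 50.0

    def test_band_inclusive_at_edges(self):
        logs = [probe([2.5, 3.5, 2.499, 3.501])]
        assert ct.constancy(logs, after=0) == 50.0

    def test_invariant_to_probe_order(self):
        logs, _ = gen_temperature_log(seed=4)
        fruit = [lg for lg in logs if lg.kind == "fruit"]
        assert ct.constancy(fruit, after=10) == ct.constancy(fruit[::-1], after=10)


class TestProfileSummary:
    def test_generator_truth_recovered(self):
        profile = TemperatureProfile(start_c=25.0, plateau_c=3.0, noise_sd=0.1)
        logs, _ = gen_temperature_log(profile, seed=6)
        s = ct.profile_summary(logs)
        assert s.post_cooldown_mean == pytest.approx(3.0, abs=0.05)
        assert s.start_mean == pytest.approx(25.0, abs=0.2)

    def test_single_constant_probe(self):
        s = ct.profile_summary([probe([3.0] * 30)])
        assert s.cooldown_hours == 0.0
        assert s.constancy_pct == 100.0
        assert s.post_cooldown_sd == 0.0

    def test_deterministic_given_seed(self):
        a = ct.profile_summary(gen_temperature_log(seed=13)[0])
        b = ct.profile_summary(gen_temperature_log(seed=13)[0])
        assert a == b

    def test_io_round_trip(self, tmp_path):
        from coldtreat.thermal import read_temperature_logs, write_temperature_logs

        logs, _ = gen_temperature_log(seed=2)
        path = tmp_path / "log.csv"
        write_temperature_logs(logs, path)
        back = read_temperature_logs(path)
        assert ct.profile_summary(back) == ct.profile_summary(logs)
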