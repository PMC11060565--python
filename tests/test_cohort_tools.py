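"""Waveform I/O, cuff calibration, synthetic cohorts, agreement statistics."""

import math

import numpy as np
import pytest

import pulsevol as pv
from pulsevol.cohort_tools import KPA_TO_MMHG, SubjectMeta, bland_altman_log, \
    calibrate_to_cuff, generate_cohort, generate_synthetic_subject, \
    load_waveform, pearson_r, write_waveform
from pulsevol.simulation import PressureWaveform


def beat(p, T=0.8):
    n = len(p)
    return PressureWaveform(t=np.arange(n) * T / n, p=np.asarray(p, float), T=T)


class TestWaveformIO:
    def test_roundtrip_is_lossless(self, tmp_path):
        w = beat(100 + 20 * np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False)))
        path = tmp_path / "w.csv"
        write_waveform(w, path)
        r = load_waveform(path)
        assert np.allclose(r.t, w.t, atol=1e-9)
        assert np.allclose(r.p, w.p, atol=1e-9)
        assert r.T == pytest.approx(w.T, abs=1e-12)

    def test_kpa_units_converted(self, tmp_path):
        path = tmp_path / "kpa.csv"
        path.write_text("# period_s = 0.8\ntime_s,pressure_kPa\n"
                        "0.0,10.0\n0.2,12.0\n0.4,11.0\n0.6,10.5\n")
        w = load_waveform(path)
        assert w.p[0] == pytest.approx(10.0 * KPA_TO_MMHG)
        assert w.p[1] == pytest.approx(12.0 * KPA_TO_MMHG)

    def test_decreasing_time_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,pressure_mmHg\n0.0,100\n0.2,101\n0.1,99\n0.3,100\n")
        with pytest.raises(ValueError, match="increasing"):
            load_waveform(path)

    def test_missing_unit_suffix_rejected(self, tmp_path):
        path = tmp_path / "units.csv"
        path.write_text("time_s,pressure\n0.0,100\n0.2,101\n0.4,99\n0.6,100\n")
        with pytest.raises(ValueError, match="unit"):
            load_waveform(path)


class TestCuffCalibration:
    def test_unit_interval_maps_to_cuff_range(self):
        raw = beat(np.concatenate([np.linspace(0, 1, 16),
                                   np.linspace(1, 0, 16)]))
        cal = calibrate_to_cuff(raw, 120.0, 80.0)
        assert cal.p.min() == pytest.approx(80.0)
        assert cal.p.max() == pytest.approx(120.0)
        assert np.allclose(cal.p, 80.0 + 40.0 * raw.p)

    def test_idempotent_on_calibrated_waveform(self):
        w = beat(80 + 40 * np.abs(np.sin(np.linspace(0, np.pi, 32))))
        w = calibrate_to_cuff(w, 120.0, 80.0)
        again = calibrate_to_cuff(w, 120.0, 80.0)
        assert np.allclose(again.p, w.p, atol=1e-12)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            calibrate_to_cuff(beat(np.full(16, 1.0)), 120.0, 80.0)


class TestSyntheticSubjects:
    META = SubjectMeta(id="x", height=170.0, SBP=118.0, DBP=76.0, T=0.8)
    P = pv.ParameterVector(E_max=2.6, t_m=0.54, S_R=2.0, S_C=11.0)

    def test_noise_free_generation_is_deterministic(self):
        w1, m1 = generate_synthetic_subject(self.P, self.META, 0.0, seed=1,
                                            solver=pv.COARSE)
        w2, m2 = generate_synthetic_subject(self.P, self.META, 0.0, seed=2,
                                            solver=pv.COARSE)
        assert np.array_equal(w1.p, w2.p)  # no noise -> seed irrelevant
        assert m1.true_sv == m2.true_sv
        assert m1.true_params == self.P

    def test_same_seed_reproduces_noisy_waveform(self):
        w1, _ = generate_synthetic_subject(self.P, self.META, 0.02, seed=5,
                                           solver=pv.COARSE)
        w2, _ = generate_synthetic_subject(self.P, self.META, 0.02, seed=5,
                                           solver=pv.COARSE)
        w3, _ = generate_synthetic_subject(self.P, self.META, 0.02, seed=6,
                                           solver=pv.COARSE)
        assert np.array_equal(w1.p, w2.p)
        assert not np.array_equal(w1.p, w3.p)

    def test_noise_level_matches_specification(self):
        clean, _ = generate_synthetic_subject(self.P, self.META, 0.0,
                                              solver=pv.COARSE)
        noisy, _ = generate_synthetic_subject(self.P, self.META, 0.05, seed=9,
                                              solver=pv.COARSE)
        # undo the re-foot-alignment shift via circular cross-correlation
        shifts = [np.std(np.roll(noisy.p, k) / clean.p)
                  for k in range(len(clean.p))]
        rel_dev = min(shifts)
        assert 0.03 < rel_dev < 0.07  # ~5% multiplicative noise

    def test_baseline_drift_flag(self):
        clean, _ = generate_synthetic_subject(self.P, self.META, 0.0,
                                              solver=pv.COARSE)
        drifted, _ = generate_synthetic_subject(self.P, self.META, 0.0, seed=3,
                                                solver=pv.COARSE, drift_rel=0.03)
        assert not np.array_equal(clean.p, drifted.p)
        # drift is slow and bounded: pointwise deviation stays within ~3%
        shifts = [np.max(np.abs(np.roll(drifted.p, k) / clean.p - 1.0))
                  for k in range(len(clean.p))]
        assert min(shifts) < 0.035

    def test_cuff_metadata_matches_waveform(self):
        w, m = generate_synthetic_subject(self.P, self.META, 0.0,
                                          solver=pv.COARSE)
        assert m.SBP == pytest.approx(w.p.max())
        assert m.DBP == pytest.approx(w.p.min())


class TestCohortGeneration:
    def test_fixed_seed_reproducible(self):
        a = generate_cohort(6, "hd", seed=11)
        b = generate_cohort(6, "hd", seed=11)
        assert [m.true_params for m in a] == [m.true_params for m in b]
        assert [m.height for m in a] == [m.height for m in b]

    def test_control_emax_mean(self):
        cohort = generate_cohort(400, "control", seed=2)
        e = np.array([m.true_params.E_max for m in cohort])
        se = 1.06 / math.sqrt(400)
        assert abs(e.mean() - 2.56) < 3 * se + 0.05  # small truncation slack

    def test_hd_sc_mean(self):
        cohort = generate_cohort(400, "hd", seed=3)
        sc = np.array([m.true_params.S_C for m in cohort])
        se = 4.34 / math.sqrt(400)
        assert abs(sc.mean() - 10.18) < 3 * se + 0.2

    def test_parameters_respect_bounds(self):
        for m in generate_cohort(50, "hd", seed=4):
            b = pv.default_bounds(m.T)
            assert b.contains(m.true_params)

    def test_bad_group_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(3, "dialysis")


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltmanLog:
    def test_identical_pairs(self):
        r = bland_altman_log([60.0, 70.0, 80.0], [60.0, 70.0, 80.0])
        assert r.mean_log_diff == 0.0
        assert r.sd_log_diff == 0.0
        assert r.ratio == 1.0
        assert r.loa_lower == r.loa_upper == 0.0

    def test_constant_ratio(self):
        ref = np.array([55.0, 62.0, 71.0, 90.0])
        r = bland_altman_log(0.9 * ref, ref)
        assert r.mean_log_diff == pytest.approx(math.log(0.9))
        assert r.sd_log_diff == pytest.approx(0.0, abs=1e-12)
        assert r.ratio == pytest.approx(0.9)

    def test_printed_hd_ratio_from_mean_log_difference(self):
        # mean log-difference of -0.41 corresponds to a geometric-mean ratio
        # of 0.66, i.e. a 34% average underestimation
        ref = np.linspace(50.0, 100.0, 12)
        r = bland_altman_log(ref * math.exp(-0.41), ref)
        assert round(r.ratio, 2) == 0.66
        assert r.mean_percent_difference == pytest.approx(-34.0, abs=0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(40, 110, 30)
        model = ref * rng.lognormal(-0.2, 0.15, 30)
        a = bland_altman_log(model, ref)
        b = bland_altman_log(3.7 * model, 3.7 * ref)
        assert a.sd_log_diff == pytest.approx(b.sd_log_diff)
        assert b.mean_log_diff == pytest.approx(a.mean_log_diff)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_log([10.0, -1.0], [10.0, 10.0])
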