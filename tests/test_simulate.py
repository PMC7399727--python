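"""Synthetic cohort generator: determinism, protocol structure, variance
faithfulness and the noiseless round trip against the feature oracle."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from rkt.config import FEATURES, GeneratorConfig
from rkt.features import compute_features
from rkt.io import extract_third_cycle, trials_to_frame
from rkt.model import true_features
from rkt.simulate import (
    calibrate_truth,
    make_feasibility_check,
    sample_feature_table,
    sample_realized_features,
    simulate_cohort,
    simulate_trial,
)


def zero_variance_config(**overrides) -> GeneratorConfig:
    vcs = {f: {"subject": 0.0, "knee": 0.0, "day": 0.0, "residual": 0.0}
           for f in FEATURES}
    defaults = dict(n_subjects=3, n_days=2, samples_per_sweep=40,
                    variance_components=vcs, noise_rotation_sd=0.0,
                    noise_translation_sd=0.0, right_knee_offset=0.0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = GeneratorConfig(n_subjects=3, n_days=2, samples_per_sweep=30)
        a = simulate_cohort(cfg, seed=5)
        b = simulate_cohort(cfg, seed=5)
        pdt.assert_frame_equal(trials_to_frame(a.trials),
                               trials_to_frame(b.trials))
        pdt.assert_frame_equal(a.truth_frame(), b.truth_frame())

    def test_same_seed_same_truths(self):
        cfg = GeneratorConfig(n_subjects=4, n_days=3)
        t1 = sample_realized_features(cfg, np.random.default_rng(9))
        t2 = sample_realized_features(cfg, np.random.default_rng(9))
        for a, b in zip(t1, t2):
            assert a.realized_features == b.realized_features

    def test_different_seed_differs(self):
        cfg = GeneratorConfig(n_subjects=3, n_days=2, samples_per_sweep=30)
        a = simulate_cohort(cfg, seed=5)
        b = simulate_cohort(cfg, seed=6)
        assert not trials_to_frame(a.trials).equals(trials_to_frame(b.trials))


class TestProtocolStructure:
    def test_cycle_and_sweep_counts(self, small_cohort):
        for trial in small_cohort.trials[:4]:
            df = trial.samples
            assert set(df["cycle"]) == {1, 2, 3}
            run = ((df["cycle"] != df["cycle"].shift())
                   | (df["sweep"] != df["sweep"].shift())).cumsum()
            directions = df.groupby(run)["sweep"].first().tolist()
            assert directions.count("ER") == 4
            assert directions.count("IR") == 3
            assert directions[0] == "ER"  # lead-in sweep is external

    def test_one_trial_per_cell_with_matching_truth(self, small_cohort):
        trial_keys = sorted(t.key() for t in small_cohort.trials)
        truth_keys = sorted((t.subject_id, t.knee, t.day)
                            for t in small_cohort.truths)
        assert trial_keys == truth_keys
        assert len(set(trial_keys)) == len(trial_keys)

    def test_torque_spans_limits_monotonically(self, small_cohort):
        df = small_cohort.trials[0].samples
        third_ir = df[(df.cycle == 3) & (df.sweep == "IR")]["torque_nm"]
        assert third_ir.iloc[0] == -6.0 and third_ir.iloc[-1] == 6.0
        assert (np.diff(third_ir) > 0).all()


class TestRealizedFeatures:
    def test_zero_variance_reproduces_means_exactly(self):
        cfg = zero_variance_config()
        truths = sample_realized_features(cfg, np.random.default_rng(0))
        for t in truths:
            f = t.realized_features
            assert f.slack == pytest.approx(cfg.mu_features["slack"], abs=1e-12)
            assert f.er_laxity == pytest.approx(cfg.mu_features["er_laxity"], abs=1e-12)
            assert f.ir_laxity == pytest.approx(cfg.mu_features["ir_laxity"], abs=1e-12)
            assert f.rot_at_zero == pytest.approx(cfg.mu_features["rot_at_zero"], abs=1e-12)

    def test_right_knee_offset_shifts_rotation_only(self):
        cfg = zero_variance_config(right_knee_offset=3.5)
        truths = sample_realized_features(cfg, np.random.default_rng(0))
        by_knee = {k: [t for t in truths if t.knee == k] for k in ("L", "R")}
        for left, right in zip(by_knee["L"], by_knee["R"]):
            assert right.realized_features.rot_at_zero - \
                left.realized_features.rot_at_zero == pytest.approx(3.5)
            assert right.realized_features.slack == \
                left.realized_features.slack

    def test_grand_slack_variance_matches_nested_sum(self):
        # 200 replicate cohorts; the grand variance of realized slack should
        # approach the sum of the four configured components (12.2 deg^2)
        cfg = GeneratorConfig()
        rng = np.random.default_rng(2024)
        variances = []
        for _ in range(200):
            tab = sample_feature_table(cfg, rng)
            variances.append(tab["slack_deg"].var(ddof=1))
        mean_var = np.mean(variances)
        mc_se = np.std(variances, ddof=1) / np.sqrt(len(variances))
        # correlated draws within subjects shade the plain sample variance
        # slightly below the component sum; allow 3 MC SEs around it
        assert abs(mean_var - 12.2) < max(3 * mc_se, 0.6)

    def test_group_offsets_shift_means(self):
        cfg = GeneratorConfig(n_subjects=40, n_days=2,
                              group_counts={"F": 20, "M": 20})
        tab = sample_feature_table(cfg, np.random.default_rng(3))
        means = tab.groupby("group")["slack_deg"].mean()
        assert means["F"] - means["M"] == pytest.approx(2.6, abs=1.5)


class TestNoiselessRoundTrip:
    def test_extraction_recovers_truth(self):
        cfg = zero_variance_config()
        truths = sample_realized_features(cfg, np.random.default_rng(0))
        truth = calibrate_truth(truths[0], cfg)
        oracle = true_features(truth.curve_params)
        trial = simulate_trial(truth, cfg, np.random.default_rng(1))
        est = compute_features(extract_third_cycle(trial))
        assert est.max_er == pytest.approx(oracle.max_er, abs=0.05)
        assert est.max_ir == pytest.approx(oracle.max_ir, abs=0.05)
        assert est.rot_at_zero == pytest.approx(oracle.rot_at_zero, abs=0.05)
        assert est.tp_er == pytest.approx(oracle.tp_er, abs=0.5)
        assert est.tp_ir == pytest.approx(oracle.tp_ir, abs=0.5)

    def test_calibration_reproduces_realized_features(self, small_cohort):
        for truth in small_cohort.truths[:10]:
            oracle = true_features(truth.curve_params)
            want = truth.realized_features
            assert oracle.slack == pytest.approx(want.slack, abs=0.01)
            assert oracle.er_laxity == pytest.approx(want.er_laxity, abs=0.01)
            assert oracle.ir_laxity == pytest.approx(want.ir_laxity, abs=0.01)
            assert oracle.rot_at_zero == pytest.approx(want.rot_at_zero,
                                                       abs=1e-6)

    def test_central_random_draws_round_trip(self):
        # random truths from the generator's central region
        rng = np.random.default_rng(8)
        cfg = zero_variance_config(samples_per_sweep=100)
        from types import SimpleNamespace
        from rkt.model import calibrate_curve_params
        for _ in range(40):
            # the estimator's validated envelope: bias grows towards the
            # expressible-envelope corners (see docs/methods.md)
            target = SimpleNamespace(
                slack=rng.uniform(14.5, 18.5),
                er_laxity=rng.uniform(2.2, 3.0),
                ir_laxity=rng.uniform(2.2, 3.0),
                rot_at_zero=rng.uniform(-2.0, 2.0),
            )
            params = calibrate_curve_params(target, cfg.play_slope,
                                            cfg.stiffening_rate)
            oracle = true_features(params)
            truth = SimpleNamespace(curve_params=params, subject_id="X",
                                    knee="L", day=1, group="all")
            trial = simulate_trial(truth, cfg, rng)
            est = compute_features(extract_third_cycle(trial))
            assert abs(est.max_ir - oracle.max_ir) < 0.05
            assert abs(est.rot_at_zero - oracle.rot_at_zero) < 0.05
            assert abs(est.tp_er - oracle.tp_er) < 0.5
            assert abs(est.tp_ir - oracle.tp_ir) < 0.5


class TestNoiseAndFeasibility:
    def test_noise_produces_bounded_feature_scatter(self):
        from types import SimpleNamespace
        from rkt.model import calibrate_curve_params
        cfg = GeneratorConfig(noise_rotation_sd=0.5, samples_per_sweep=100)
        target = SimpleNamespace(slack=16.6, er_laxity=2.8, ir_laxity=3.0,
                                 rot_at_zero=0.0)
        params = calibrate_curve_params(target, cfg.play_slope,
                                        cfg.stiffening_rate)
        truth = SimpleNamespace(curve_params=params, subject_id="X",
                                knee="L", day=1, group="all")
        rng = np.random.default_rng(12)
        slacks = []
        for _ in range(50):
            trial = simulate_trial(truth, cfg, rng)
            try:
                slacks.append(compute_features(extract_third_cycle(trial)).slack)
            except Exception:
                pass
        # at double the nominal sensor noise a fair share of extractions hit
        # the turning-point detection limit; the survivors stay bounded
        assert len(slacks) >= 20
        assert 0.0 < np.std(slacks) < 2.0

    def test_feasibility_check_bounds_draws(self):
        cfg = GeneratorConfig()
        check = make_feasibility_check(cfg)
        assert check(16.6, 2.6, 2.8)
        assert not check(16.6, 10.0, 2.8)   # laxity beyond the envelope cap
        assert not check(2.0, 2.6, 2.8)     # slack below the feasibility floor
        assert not check(-1.0, 2.6, 2.8)

    def test_curve_cohort_truths_are_all_calibratable(self, small_cohort):
        for truth in small_cohort.truths:
            assert truth.curve_params is not None
            f = truth.realized_features
            assert f.slack > 0 and f.er_laxity > 0 and f.ir_laxity > 0
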