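import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogdrive import simulator as sim
from cogdrive.decision import DecisionHyper
from cogdrive.evaluation import (
    EvalReport,
    counterfactual_yellow_speed,
    decision_agreement_metrics,
    gaussian_kl,
    kl_separation,
    loocv_evaluate,
    stepwise_select,
)
from cogdrive.nn import TrainingConfig

FAST_TRAIN = TrainingConfig(hidden_size=6, epochs=3, batch_size=64,
                            learning_rate=3e-3, seed=0)


class TestAgreementMetrics:
    def test_perfect_agreement(self):
        k, b = decision_agreement_metrics([True, False, True], [True, False, True])
        assert k == pytest.approx(1.0)
        assert b == pytest.approx(1.0)

    def test_complement_on_balanced_labels(self):
        labels = [True, True, False, False]
        k, b = decision_agreement_metrics([not l for l in labels], labels)
        assert b == pytest.approx(0.0)
        assert k == pytest.approx(-1.0)

    def test_constant_decisions_zero_kappa(self):
        k, b = decision_agreement_metrics([True] * 4, [True, True, False, False])
        assert k == pytest.approx(0.0)
        assert b == pytest.approx(0.5)

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            decision_agreement_metrics([True, False], [True, True])

    def test_random_decisions_average_half(self):
        labels = np.array([True] * 13 + [False] * 14)
        rng = np.random.default_rng(0)
        baccs = []
        for _ in range(2000):
            dec = rng.integers(2, size=len(labels)).astype(bool)
            baccs.append(decision_agreement_metrics(dec, labels)[1])
        assert np.mean(baccs) == pytest.approx(0.5, abs=0.01)


def _two_condition_trials(subject_values):
    """subject -> (hmi_speeds, base_speeds)"""
    rows = []
    for sid, (hmi, base) in subject_values.items():
        for i, v in enumerate(hmi):
            rows.append((sid, 2, i, "hud_circle:distance", True, v, v))
        for i, v in enumerate(base):
            rows.append((sid, 1, i, "none", True, v, v))
    return pd.DataFrame(rows, columns=[
        "subject_id", "lap_id", "approach_idx", "condition", "had_yellow",
        "mean_yellow_speed", "max_yellow_speed"])


class TestCounterfactual:
    def test_deploy_uses_hmi_trials(self):
        trials = _two_condition_trials({"S0": ([14, 16], [18])})
        mean, se, excl = counterfactual_yellow_speed({"S0": True}, trials)
        assert mean == pytest.approx(15.0)
        assert excl == 0

    def test_two_subject_mean_and_se(self):
        trials = _two_condition_trials({"S0": ([15], [20]), "S1": ([17], [20])})
        mean, se, _ = counterfactual_yellow_speed({"S0": True, "S1": True}, trials)
        assert mean == pytest.approx(16.0)
        assert se == pytest.approx(1.0)

    def test_always_and_never_are_condition_averages(self, tiny_bundle):
        trials = tiny_bundle.analysis_trials
        subjects = trials["subject_id"].unique()
        yellow = trials[trials["had_yellow"]]
        always, _, _ = counterfactual_yellow_speed(
            {s: True for s in subjects}, trials)
        never, _, _ = counterfactual_yellow_speed(
            {s: False for s in subjects}, trials)
        hmi_avg = (yellow[yellow["condition"] != "none"]
                   .groupby("subject_id")["mean_yellow_speed"].mean().mean())
        base_avg = (yellow[yellow["condition"] == "none"]
                    .groupby("subject_id")["mean_yellow_speed"].mean().mean())
        assert always == pytest.approx(hmi_avg, abs=1e-12)
        assert never == pytest.approx(base_avg, abs=1e-12)

    def test_unmatched_subject_excluded_with_count(self):
        trials = _two_condition_trials({"S0": ([15], [20])})
        trials = trials[trials["condition"] == "none"]  # S0 has no HMI trials
        trials = pd.concat([trials, _two_condition_trials({"S1": ([14], [19])})])
        with pytest.warns(UserWarning, match="S0"):
            mean, _, excl = counterfactual_yellow_speed(
                {"S0": True, "S1": True}, trials)
        assert excl == 1
        assert mean == pytest.approx(14.0)


class TestKLSeparation:
    def test_identical_groups_zero(self, rng):
        x = rng.standard_normal((200, 2))
        vals = np.tile([0.0, 1.0], 100)
        assert kl_separation(x, vals) < 0.2

    def test_unit_separation_anchor(self):
        # groups with exactly N(0, I) and N((1,0), I) moments -> 1.0
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((100, 2))
        raw = (raw - raw.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(raw.T, ddof=0)).T)
        a = raw
        b = raw + np.array([1.0, 0.0])
        latents = np.concatenate([a, b])
        vals = np.array([0.0] * 100 + [1.0] * 100)
        assert kl_separation(latents, vals) == pytest.approx(1.0, abs=1e-9)

    def test_two_sd_gap_matches_closed_form(self):
        # independent oracle: symmetrized closed-form KL on the fitted moments
        rng = np.random.default_rng(4)
        a = rng.standard_normal((2000, 2))
        b = rng.standard_normal((2000, 2)) + np.array([2.0, 0.0])
        vals = np.array([0.0] * 2000 + [1.0] * 2000)
        got = kl_separation(np.concatenate([a, b]), vals)

        def _kl(m0, c0, m1, c1):
            inv1 = np.linalg.inv(c1)
            diff = m1 - m0
            return 0.5 * (np.trace(inv1 @ c0) + diff @ inv1 @ diff - 2
                          + np.log(np.linalg.det(c1) / np.linalg.det(c0)))

        ma, ca = a.mean(0), np.cov(a.T, ddof=0)
        mb, cb = b.mean(0), np.cov(b.T, ddof=0)
        oracle = 0.5 * (_kl(ma, ca, mb, cb) + _kl(mb, cb, ma, ca)) / 0.5
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(4.0, abs=0.3)  # population value at n=2000

    def test_rotation_invariance(self, rng):
        a = rng.standard_normal((100, 2)) * [1.0, 0.3]
        b = a + np.array([1.5, 0.2])
        lat = np.concatenate([a, b])
        vals = np.array([0.0] * 100 + [1.0] * 100)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert kl_separation(lat @ R.T, vals) == pytest.approx(
            kl_separation(lat, vals), abs=1e-9)

    def test_group_relabel_invariance(self, rng):
        a = rng.standard_normal((50, 2))
        b = rng.standard_normal((50, 2)) + 1.0
        lat = np.concatenate([a, b])
        vals = np.array([0.0] * 50 + [1.0] * 50)
        assert kl_separation(lat, vals) == pytest.approx(
            kl_separation(lat, 1.0 - vals), abs=1e-9)

    def test_gaussian_kl_closed_form(self):
        # KL(N(0,I) || N((1,0),I)) = 0.5
        assert gaussian_kl(np.zeros(2), np.eye(2),
                           np.array([1.0, 0.0]), np.eye(2)) == pytest.approx(0.5)

    def test_small_group_errors(self, rng):
        with pytest.raises(ValueError):
            kl_separation(rng.standard_normal((3, 2)), [0.0, 1.0, 1.0])


class TestStepwise:
    def test_pure_noise_selects_nothing(self):
        picked_any = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((200, 5)),
                             columns=[f"c{i}" for i in range(5)])
            y = rng.standard_normal(200)
            if stepwise_select(X, y):
                picked_any += 1
        assert picked_any <= 1  # >= 95% of seeds empty

    def test_single_informative_candidate(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=["a", "b", "c"])
        y = X["b"].to_numpy() + 0.1 * rng.standard_normal(100)
        assert stepwise_select(X, y) == ["b"]

    def test_four_driving_factors_recovered(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 7)),
                         columns=[f"f{i}" for i in range(7)])
        y = (X["f0"] + 0.8 * X["f2"] - 0.6 * X["f4"] + 0.5 * X["f6"]
             + 0.3 * rng.standard_normal(300)).to_numpy()
        assert set(stepwise_select(X, y)) == {"f0", "f2", "f4", "f6"}

    def test_aic_criterion(self, rng):
        X = pd.DataFrame(rng.standard_normal((150, 3)), columns=["a", "b", "c"])
        y = 2.0 * X["a"].to_numpy() + 0.2 * rng.standard_normal(150)
        assert stepwise_select(X, y, criterion="aic") == ["a"]


class TestLOOCV:
    @pytest.fixture(scope="class")
    def loocv_result(self, tiny_bundle):
        audit = []
        report = loocv_evaluate(tiny_bundle, FAST_TRAIN, DecisionHyper(),
                                seeds=[0], window=20, audit=audit)
        return report, audit, tiny_bundle

    def test_one_fold_per_subject(self, loocv_result):
        report, audit, bundle = loocv_result
        assert report.n_subjects == bundle.config.n_subjects
        assert len(audit) == bundle.config.n_subjects

    def test_no_leakage(self, loocv_result):
        _, audit, _ = loocv_result
        for fold in audit:
            held = fold["held_out"]
            assert all(sid != held for sid, _, _ in fold["train_set"])

    def test_default_seed_count_is_ten(self):
        import inspect

        sig = inspect.signature(loocv_evaluate)
        assert sig.parameters["seeds"].default == 10

    def test_baseline_identities_inside_report(self, loocv_result):
        report, _, bundle = loocv_result
        trials = bundle.analysis_trials
        subjects = trials["subject_id"].unique()
        never, _, _ = counterfactual_yellow_speed(
            {s: False for s in subjects}, trials)
        always, _, _ = counterfactual_yellow_speed(
            {s: True for s in subjects}, trials)
        assert report.policies["no_hmi"]["mean_speed"] == pytest.approx(never)
        assert report.policies["always"]["mean_speed"] == pytest.approx(always)

    def test_report_serializes(self, loocv_result):
        report, _, _ = loocv_result
        out = report.to_json()
        assert "window_averaged" in out
        assert isinstance(report.policy_table(), pd.DataFrame)

    def test_metrics_in_range(self, loocv_result):
        report, _, _ = loocv_result
        for pol, m in report.policies.items():
            assert 0.0 <= m["balanced_accuracy"] <= 1.0
            assert -1.0 <= m["kappa"] <= 1.0
            assert m["se"] >= 0.0


class TestNullDatasetNoSpuriousBenefit:
    def test_personalized_matches_random_on_null_data(self, small_course):
        """Factors unrelated to behavior: no policy should beat random."""
        spec = sim.FactorSpec("bas_fun_seeking", 11.704, 2.165, 0)
        coeffs = sim.ResponseCoefficients(
            "bas_fun_seeking", 17.36, 0.0, 0.0, 0.0, 1.0, 1.0)
        cfg = sim.SimulatorConfig(
            n_subjects=8, factors=(spec,), coefficients=(coeffs,),
            weights=(1.0,), course=small_course)
        bundle = sim.generate_dataset(cfg, seed=13)
        report = loocv_evaluate(bundle, FAST_TRAIN, DecisionHyper(),
                                seeds=[0, 1, 2], window=20)
        personal = [r["policies"]["window_averaged"]["mean_speed"]
                    for r in report.per_seed]
        random_ = [r["policies"]["random"]["mean_speed"]
                   for r in report.per_seed]
        if np.std(np.asarray(personal) - np.asarray(random_)) > 0:
            _, p = stats.ttest_rel(personal, random_)
            assert p > 0.05
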