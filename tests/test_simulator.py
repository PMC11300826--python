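import numpy as np
import pandas as pd
import pytest

from cogdrive import simulator as sim


class TestSamplePopulation:
    def test_population_moments_match_spec(self):
        spec = sim.FactorSpec("bas_fun_seeking", 11.704, 2.165, +1)
        table = sim.sample_population(10000, [spec], seed=42)
        assert table["bas_fun_seeking"].mean() == pytest.approx(11.704, abs=0.1)
        assert table["bas_fun_seeking"].std(ddof=0) == pytest.approx(2.165, abs=0.1)

    def test_same_seed_identical(self):
        a = sim.sample_population(27, sim.DEFAULT_FACTORS, seed=3)
        b = sim.sample_population(27, sim.DEFAULT_FACTORS, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_row_count(self):
        table = sim.sample_population(27, sim.DEFAULT_FACTORS, seed=0)
        assert len(table) == 27
        assert table["subject_id"].is_unique

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            sim.FactorSpec("bad", 1.0, 0.0)

    def test_correlation_structure(self):
        specs = sim.DEFAULT_FACTORS[:2]
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        t = sim.sample_population(5000, specs, seed=5, correlation=corr)
        r = np.corrcoef(t[specs[0].name], t[specs[1].name])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)


class TestResponseModel:
    def test_no_hmi_drops_hmi_terms(self):
        c = sim.ResponseCoefficients("f", 10.0, -5.0, 0.3, 0.7, 0.0, 0.0)
        mu = sim.response_model_mean_speed({"f": 4.0}, False, c)
        assert mu == pytest.approx(10.0 + 0.3 * 4.0)

    def test_bas_fun_hmi_effect_at_plus_minus_one_sd(self):
        # hand arithmetic on the printed coefficients
        c = next(x for x in sim.DEFAULT_COEFFICIENTS if x.factor == "bas_fun_seeking")
        low = (sim.response_model_mean_speed({"bas_fun_seeking": 9.539}, True, c)
               - sim.response_model_mean_speed({"bas_fun_seeking": 9.539}, False, c))
        high = (sim.response_model_mean_speed({"bas_fun_seeking": 13.869}, True, c)
                - sim.response_model_mean_speed({"bas_fun_seeking": 13.869}, False, c))
        assert low == pytest.approx(-2.555, abs=1e-3)
        assert high == pytest.approx(1.342, abs=1e-3)

    def test_positive_urgency_hmi_effect_at_mean(self):
        c = next(x for x in sim.DEFAULT_COEFFICIENTS
                 if x.factor == "upps_positive_urgency")
        eff = (sim.response_model_mean_speed({"upps_positive_urgency": 6.630}, True, c)
               - sim.response_model_mean_speed({"upps_positive_urgency": 6.630}, False, c))
        assert eff == pytest.approx(-0.555, abs=1e-3)

    def test_unknown_factor_errors(self):
        c = sim.DEFAULT_COEFFICIENTS[0]
        with pytest.raises(KeyError):
            sim.response_model_mean_speed({"other": 1.0}, True, c)


class TestSimulateLap:
    def _subject(self, cfg, **scores):
        row = {"subject_id": "S000", "random_intercept": 0.0}
        row.update(scores)
        return row

    def test_yellow_transition_count(self, small_course):
        cfg = sim.single_factor_config("bas_fun_seeking")
        subj = self._subject(cfg, bas_fun_seeking=11.7)
        lap = sim.simulate_lap(subj, sim.HMICondition("none"), cfg, seed=1)
        phase = lap["light_phase"].to_numpy()
        trans = ((phase[1:] == "Y") & (phase[:-1] == "G")).sum()
        assert trans == cfg.course.n_yellow_per_lap == 4

    def test_noise_free_mean_yellow_speed_exact(self):
        base = sim.single_factor_config("bas_fun_seeking")
        coeffs = sim.ResponseCoefficients("bas_fun_seeking", 17.36, -11.14, 0.0,
                                          0.9, 0.0, 0.0)
        cfg = sim.SimulatorConfig(factors=base.factors, coefficients=(coeffs,),
                                  weights=(1.0,))
        subj = self._subject(cfg, bas_fun_seeking=13.0)
        lap = sim.simulate_lap(subj, sim.HMICondition("hud_circle", "distance"),
                               cfg, seed=9)
        expected = sim.response_model_mean_speed({"bas_fun_seeking": 13.0}, True, coeffs)
        for _, grp in lap[lap["light_phase"] == "Y"].groupby("approach_idx"):
            assert grp["speed_mps"].mean() == pytest.approx(expected, abs=1e-9)

    def test_monte_carlo_mean_matches_response_model(self):
        cfg = sim.single_factor_config("bas_fun_seeking")
        coeffs = cfg.coefficients[0]
        subj = self._subject(cfg, bas_fun_seeking=11.704)
        means = []
        for seed in range(300):
            lap = sim.simulate_lap(subj, sim.HMICondition("none"), cfg, seed=seed)
            y = lap[lap["light_phase"] == "Y"]
            means.extend(g["speed_mps"].mean() for _, g in y.groupby("approach_idx"))
        means = np.asarray(means)
        expected = sim.response_model_mean_speed({"bas_fun_seeking": 11.704},
                                                 False, coeffs)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se + 0.02  # + mean-clipping slack

    def test_speeds_nonnegative_and_kinematics_consistent(self, small_course):
        cfg = sim.single_factor_config("bas_fun_seeking", course=small_course)
        subj = self._subject(cfg, bas_fun_seeking=8.0)
        lap = sim.simulate_lap(subj, sim.HMICondition("road_markings", "light_change"),
                               cfg, seed=2)
        v = lap["speed_mps"].to_numpy()
        a = lap["accel_mps2"].to_numpy()
        assert (v >= 0).all()
        np.testing.assert_allclose(v[1:], v[:-1] + a[:-1] * cfg.dt, atol=1e-8)

    def test_distance_trigger_activates_at_trigger_distance(self):
        cfg = sim.single_factor_config("bas_fun_seeking")
        subj = self._subject(cfg, bas_fun_seeking=11.7)
        lap = sim.simulate_lap(subj, sim.HMICondition("hud_circle", "distance"),
                               cfg, seed=4)
        d = lap["dist_to_light_m"].to_numpy()
        h = lap["hmi_active"].to_numpy().astype(bool)
        assert (h == (d <= cfg.course.trigger_distance)).all()

    def test_light_change_trigger_only_after_yellow(self):
        cfg = sim.single_factor_config("bas_fun_seeking")
        subj = self._subject(cfg, bas_fun_seeking=11.7)
        lap = sim.simulate_lap(subj, sim.HMICondition("hud_circle", "light_change"),
                               cfg, seed=4)
        on_green = lap[(lap["light_phase"] == "G") & (lap["hmi_active"] == 1)]
        # HMI never active while the light is still green
        assert on_green.empty

    def test_no_interface_means_no_hmi(self):
        cfg = sim.single_factor_config("bas_fun_seeking")
        subj = self._subject(cfg, bas_fun_seeking=11.7)
        lap = sim.simulate_lap(subj, sim.HMICondition("none"), cfg, seed=4)
        assert (lap["hmi_active"] == 0).all()


class TestGenerateDataset:
    def test_bookkeeping(self, tiny_bundle):
        cfg = tiny_bundle.config
        n_rows = cfg.n_subjects * cfg.n_laps * cfg.course.n_lights_per_lap
        assert len(tiny_bundle.trials) == n_rows
        assert tiny_bundle.analysis_trials["lap_id"].min() == 1
        per_subj = tiny_bundle.analysis_trials.groupby("subject_id")["lap_id"].nunique()
        assert (per_subj == cfg.n_laps - 1).all()

    def test_determinism(self, small_course):
        cfg = sim.single_factor_config("bas_fun_seeking", n_subjects=3,
                                       course=small_course)
        a = sim.generate_dataset(cfg, seed=11)
        b = sim.generate_dataset(cfg, seed=11)
        pd.testing.assert_frame_equal(a.logs, b.logs)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_interaction_recovery_single_dataset(self):
        import statsmodels.formula.api as smf

        cfg = sim.single_factor_config("bas_fun_seeking")
        bundle = sim.generate_dataset(cfg, seed=21)
        t = bundle.analysis_trials
        t = t[t["had_yellow"]].copy()
        t["hmi"] = (t["condition"] != "none").astype(float)
        t = t.merge(bundle.subjects[["subject_id", "bas_fun_seeking"]],
                    on="subject_id")
        m = smf.mixedlm("mean_yellow_speed ~ hmi * bas_fun_seeking", t,
                        groups=t["subject_id"]).fit(reml=True)
        bi = m.params["hmi:bas_fun_seeking"]
        se = m.bse["hmi:bas_fun_seeking"]
        assert abs(bi - 0.9) <= 2 * se

    def test_sign_recovery(self):
        cfg = sim.default_config(n_subjects=200)
        bundle = sim.generate_dataset(cfg, seed=5)
        t = bundle.analysis_trials
        per_subj = (t[t["had_yellow"]]
                    .groupby("subject_id")["mean_yellow_speed"].mean())
        merged = bundle.subjects.set_index("subject_id").join(per_subj)
        for spec in cfg.factors:
            r = np.corrcoef(merged[spec.name], merged["mean_yellow_speed"])[0, 1]
            assert np.sign(r) == spec.sign_vs_yellow_speed, spec.name
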