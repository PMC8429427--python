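import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import fcbrainage as f
import _oracles as orc


def pad_frame(age, pred, group, **extra):
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(age))],
            "chronological_age": np.asarray(age, dtype=float),
            "predicted_age": np.asarray(pred, dtype=float),
            "group_label": group,
        }
    )
    for k, v in extra.items():
        frame[k] = v
    return f.compute_pad(frame)


class TestComputePad:
    def test_subtraction_and_shift_linearity(self):
        t = pad_frame([40.0, 60.0], [50.0, 60.0], ["a", "a"])
        assert list(t.frame["pad"]) == [10.0, 0.0]
        t2 = pad_frame([40.0, 60.0], [53.0, 63.0], ["a", "a"])
        assert np.allclose(t2.frame["pad"], t.frame["pad"] + 3.0)

    def test_missing_age_rejected(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a"],
                "chronological_age": [np.nan],
                "predicted_age": [50.0],
            }
        )
        with pytest.raises(ValueError, match="missing"):
            f.compute_pad(frame)

    def test_pad_table_invariant_enforced(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a"],
                "chronological_age": [40.0],
                "predicted_age": [50.0],
                "pad": [3.0],
            }
        )
        with pytest.raises(ValueError, match="pad"):
            f.PadTable(frame)


class TestGroupGlm:
    def test_identical_groups_give_null_result(self, rng):
        age = rng.uniform(30, 70, 40)
        pred = age + rng.normal(0, 5, 40)
        t = pad_frame(np.tile(age, 2), np.tile(pred, 2), ["a"] * 40 + ["b"] * 40)
        comp = f.group_glm(t, "a", "b")
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle_on_toy_table(self):
        age = np.array([30.0, 35, 42, 50, 55, 61, 68, 72])
        pad = np.array([1.2, -0.5, 3.1, 0.4, 2.2, -1.0, 4.0, 1.5])
        group = ["a", "b", "a", "b", "a", "b", "a", "b"]
        t = pad_frame(age, age + pad, group)
        comp = f.group_glm(t, "a", "b")
        g = (np.array(group) == "b").astype(float)
        f_o, p_o = orc.glm_group_f(pad, g, [age])
        assert comp.f_statistic == pytest.approx(f_o, abs=1e-8)
        assert comp.p_value == pytest.approx(p_o, abs=1e-8)
        assert comp.df == (1, 5)

    def test_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf

        age = rng.uniform(20, 80, 60)
        group = np.array(["a"] * 30 + ["b"] * 30)
        pad = 0.1 * age + (group == "b") * 4 + rng.normal(0, 3, 60)
        t = pad_frame(age, age + pad, group)
        comp = f.group_glm(t, "a", "b")
        df = pd.DataFrame({"pad": pad, "grp": group, "age": age})
        fit = smf.ols("pad ~ C(grp) + age", data=df).fit()
        assert comp.f_statistic == pytest.approx(fit.tvalues["C(grp)[T.b]"] ** 2, abs=1e-8)
        assert comp.p_value == pytest.approx(fit.pvalues["C(grp)[T.b]"], abs=1e-8)

    def test_age_covariate_affine_invariance(self, rng):
        age = rng.uniform(20, 80, 50)
        group = np.array(["a", "b"] * 25)
        pad = (group == "b") * 5 + rng.normal(0, 4, 50)
        t1 = pad_frame(age, age + pad, group)
        c1 = f.group_glm(t1, "a", "b")
        t2 = pad_frame(age, age + pad, group)
        t2.frame["scaled_age"] = 3.0 * age - 17.0
        c2 = f.group_glm(t2, "a", "b", covariates=("scaled_age",))
        assert c1.f_statistic == pytest.approx(c2.f_statistic, abs=1e-8)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-8)

    def test_one_sided_halves_p_in_effect_direction(self, rng):
        age = rng.uniform(20, 80, 60)
        group = np.array(["a"] * 30 + ["b"] * 30)
        pad = (group == "b") * 6 + rng.normal(0, 5, 60)
        t = pad_frame(age, age + pad, group)
        two = f.group_glm(t, "a", "b", sided="two")
        one = f.group_glm(t, "a", "b", sided="one")
        assert one.p_value == pytest.approx(two.p_value / 2)

    def test_planted_offset_recovered_in_simulation(self, rng):
        """Adjusted difference near the planted 8 years with p < 0.05 in
        most scaled-down replicates."""
        hits, in_window = 0, 0
        reps = 25
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            n_a, n_b = 120, 30
            age = r.uniform(20, 80, n_a + n_b)
            group = np.array(["control"] * n_a + ["carrier"] * n_b)
            pad = -0.05 * age + (group == "carrier") * 8.0 + r.normal(0, 7, n_a + n_b)
            t = pad_frame(age, age + pad, group)
            comp = f.group_glm(t, "control", "carrier")
            diff = comp.adjusted_mean_b - comp.adjusted_mean_a
            hits += comp.p_value < 0.05
            in_window += 5.0 <= diff <= 11.0
        assert hits >= 0.8 * reps
        assert in_window >= 0.8 * reps

    def test_confounded_design_rejected(self):
        age = np.array([30.0, 30, 60, 60])
        group = ["a", "a", "b", "b"]
        t = pad_frame(age, age + 1, group)
        t.frame["const_cov"] = 1.0
        with pytest.raises(ValueError, match="singular"):
            f.group_glm(t, "a", "b", covariates=("const_cov",))


class TestPartialCorrelation:
    def test_matches_double_residualization_oracle(self, rng):
        age = rng.uniform(20, 80, 10)
        pad = rng.normal(0, 5, 10)
        x = rng.normal(0, 1, 10)
        t = pad_frame(age, age + pad, ["a"] * 10, amyloid_load=x)
        r, dof, p = f.partial_correlation(t, "amyloid_load")
        assert r == pytest.approx(orc.partial_corr(pad, x, age), abs=1e-10)
        assert dof == 7

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        age = rng.uniform(20, 80, 40)
        pad = 0.2 * age + rng.normal(0, 3, 40)
        x = 0.5 * pad + rng.normal(0, 2, 40)
        t = pad_frame(age, age + pad, ["a"] * 40, amyloid_load=x)
        r, dof, p = f.partial_correlation(t, "amyloid_load")
        ref = pg.partial_corr(
            data=pd.DataFrame({"pad": pad, "x": x, "age": age}),
            x="pad", y="x", covar="age",
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_null_simulation_mean_r_small(self):
        rs = []
        for rep in range(200):
            r = np.random.default_rng(rep)
            n = 40
            age = r.uniform(20, 80, n)
            pad = 0.3 * age + r.normal(0, 4, n)
            x = -0.1 * age + r.normal(0, 1, n)  # independent of PAD given age
            t = pad_frame(age, age + pad, ["a"] * n, amyloid_load=x)
            rs.append(f.partial_correlation(t, "amyloid_load")[0])
        assert abs(np.mean(rs)) < 2 / np.sqrt(40)

    def test_self_correlation_limit(self, rng):
        age = rng.uniform(20, 80, 30)
        pad = rng.normal(0, 5, 30)
        t = pad_frame(age, age + pad, ["a"] * 30, amyloid_load=pad + rng.normal(0, 1e-4, 30))
        r, _, p = f.partial_correlation(t, "amyloid_load")
        assert r > 0.999


class TestMannWhitney:
    def test_exhaustive_enumeration_case(self):
        u, p = f.mann_whitney([1.0, 2.0], [3.0, 4.0], sided="less")
        assert u == 0.0
        assert p == pytest.approx(1.0 / 6.0)

    def test_identical_samples_two_sided_p_one(self):
        a = [1.0, 2.0, 3.0]
        u, p = f.mann_whitney(a, list(a), sided="two")
        assert p == pytest.approx(1.0)

    def test_u_duality(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 6)
        u_ab, _ = f.mann_whitney(a, b)
        u_ba, _ = f.mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_matches_scipy_exact_without_ties(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 7)
        u, p = f.mann_whitney(a, b, sided="two")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_samples_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.6, 1, 50)
        u, p = f.mann_whitney(a, b, sided="two")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestEyo:
    def test_sign_convention(self):
        assert f.compute_eyo(50.0, 60.0) == -10.0
        assert f.compute_eyo(60.0, 60.0) == 0.0

    def test_cohort_mean(self, rng):
        age = rng.uniform(30, 60, 50)
        onset = age + 10.0
        assert np.mean(f.compute_eyo(age, onset)) == pytest.approx(-10.0)

    def test_missing_onset_propagates_nan(self):
        out = f.compute_eyo(np.array([50.0, 55.0]), np.array([60.0, np.nan]))
        assert out[0] == -10.0 and np.isnan(out[1])
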