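import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelqg import quantgen as qg
from panelqg import synthetic_data as sd
from panelqg import survival as sv


class TestOneWayAnova:
    def test_balanced_toy_closed_form(self):
        values = [1, 2, 3, 5, 6, 7]
        line = ["A"] * 3 + ["B"] * 3
        vc = qg.anova_mixed(values, line, model="single_sex")
        t = vc.table.set_index("source")
        assert t.loc["Line", "ms"] == pytest.approx(24.0)
        assert t.loc["Error", "ms"] == pytest.approx(1.0)
        assert vc.components["error"] == pytest.approx(1.0)
        assert vc.components["line"] == pytest.approx((24 - 1) / 3)

    def test_matches_scipy_f_test(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.0, 0.2)]
        values = np.concatenate(groups)
        line = np.repeat(list("ABCD"), 8)
        vc = qg.anova_mixed(values, line, model="single_sex")
        f, p = stats.f_oneway(*groups)
        t = vc.table.set_index("source")
        assert t.loc["Line", "f"] == pytest.approx(f)
        assert t.loc["Line", "p"] == pytest.approx(p)

    def test_singleton_lines_dropped(self):
        with pytest.warns(UserWarning, match="single"):
            vc = qg.anova_mixed([1.0, 2.0, 3.0, 4.0, 9.0],
                                ["A", "A", "B", "B", "C"],
                                model="single_sex")
        assert vc.table.set_index("source").loc["Error", "df"] == 2

    def test_all_identical_rejected(self):
        with pytest.raises(qg.ZeroVarianceError):
            qg.anova_mixed([5, 5, 5, 5], ["A", "A", "B", "B"],
                           model="single_sex")

    def test_negative_component_truncated(self):
        # identical group means with huge within-group spread force the
        # line moment negative; it must come back as 0 with a flag
        vals = [-10.0, 10.0] * 4
        lines = ["A", "A", "B", "B", "C", "C", "D", "D"]
        vc = qg.anova_mixed(vals, lines, model="single_sex")
        assert "line" in vc.truncated
        assert vc.components["line"] == 0.0


def _balanced_two_way(rng, n_lines=6, per_cell=5,
                      line_sd=2.0, sl_sd=1.0, err_sd=1.0):
    vals, lines, sexes = [], [], []
    le = rng.normal(0, line_sd, n_lines)
    for li in range(n_lines):
        for sex in ("M", "F"):
            cell = le[li] + rng.normal(0, sl_sd) \
                + rng.normal(0, err_sd, per_cell)
            vals.extend(cell + (0.7 if sex == "M" else 0.0))
            lines.extend([f"L{li}"] * per_cell)
            sexes.extend([sex] * per_cell)
    return np.array(vals), np.array(lines), np.array(sexes)


class TestPooledAnova:
    def test_balanced_design_matches_closed_form_ems(self):
        """Moment components solve the EMS equations exactly when balanced."""
        rng = np.random.default_rng(7)
        vals, lines, sexes = _balanced_two_way(rng)
        vc = qg.anova_mixed(vals, lines, sexes, model="pooled_sex")
        t = vc.table.set_index("source")
        n = 5
        ms_e, ms_sl, ms_l = (t.loc["Error", "ms"], t.loc["Sex*Line", "ms"],
                             t.loc["Line", "ms"])
        assert vc.n_effective == pytest.approx(n)
        assert vc.components["error"] == pytest.approx(ms_e)
        if "sexline" not in vc.truncated:
            assert vc.components["sexline"] == pytest.approx((ms_sl - ms_e) / n)
        if "line" not in vc.truncated:
            assert vc.components["line"] == pytest.approx(
                (ms_l - ms_sl) / (2 * n))

    def test_line_tested_over_interaction(self):
        rng = np.random.default_rng(8)
        vals, lines, sexes = _balanced_two_way(rng)
        vc = qg.anova_mixed(vals, lines, sexes, model="pooled_sex")
        t = vc.table.set_index("source")
        assert t.loc["Line", "f"] == pytest.approx(
            t.loc["Line", "ms"] / t.loc["Sex*Line", "ms"])
        assert t.loc["Sex", "f"] == pytest.approx(
            t.loc["Sex", "ms"] / t.loc["Sex*Line", "ms"])
        assert t.loc["Sex*Line", "f"] == pytest.approx(
            t.loc["Sex*Line", "ms"] / t.loc["Error", "ms"])

    def test_mean_squares_match_statsmodels_when_balanced(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(9)
        vals, lines, sexes = _balanced_two_way(rng)
        vc = qg.anova_mixed(vals, lines, sexes, model="pooled_sex")
        df = pd.DataFrame({"y": vals, "line": lines, "sex": sexes})
        fit = ols("y ~ C(sex) * C(line)", data=df).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        t = vc.table.set_index("source")
        assert t.loc["Line", "ms"] == pytest.approx(
            aov.loc["C(line)", "sum_sq"] / aov.loc["C(line)", "df"])
        assert t.loc["Sex*Line", "ms"] == pytest.approx(
            aov.loc["C(sex):C(line)", "sum_sq"]
            / aov.loc["C(sex):C(line)", "df"])
        assert t.loc["Error", "ms"] == pytest.approx(
            aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])

    def test_shuffled_line_labels_kill_line_component(self):
        rng = np.random.default_rng(10)
        vals, lines, sexes = _balanced_two_way(rng, line_sd=3.0)
        comps = []
        for _ in range(20):
            perm = rng.permutation(len(vals))
            vc = qg.anova_mixed(vals[perm], lines, sexes, model="pooled_sex")
            comps.append(vc.components["line"])
        vc_orig = qg.anova_mixed(vals, lines, sexes, model="pooled_sex")
        assert np.mean(comps) < 0.2 * vc_orig.components["line"]


class TestHeritability:
    @pytest.mark.parametrize("l2,e2,expect", [
        (0.47, 1.6, 0.227), (3.75, 4.24, 0.469), (3.03, 4.89, 0.383)])
    def test_single_sex_ratio(self, l2, e2, expect):
        assert qg.heritability_from_components(l2, e2) == pytest.approx(
            expect, abs=5e-4)

    def test_zero_line_variance(self):
        assert qg.heritability_from_components(0.0, 1.0) == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(qg.ZeroVarianceError):
            qg.heritability_from_components(0.0, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        vals, lines, sexes = _balanced_two_way(rng)
        h1 = qg.broad_sense_heritability(
            qg.anova_mixed(vals, lines, sexes, "pooled_sex"))
        h2 = qg.broad_sense_heritability(
            qg.anova_mixed(vals * 7.3, lines, sexes, "pooled_sex"))
        assert h1 == pytest.approx(h2)


def _covariate_design(rng, n_lines=40, per_cell=5, shift=0.0):
    infection = rng.binomial(1, 0.5, n_lines)
    if infection.min() == infection.max():
        infection[0] = 1 - infection[0]
    vals, lines, sexes, infs = [], [], [], []
    le = rng.normal(0, 1.0, n_lines)
    for li in range(n_lines):
        for sex in ("M", "F"):
            cell = le[li] + rng.normal(0, 1.0, per_cell) \
                + shift * infection[li]
            vals.extend(cell)
            lines.extend([f"L{li}"] * per_cell)
            sexes.extend([sex] * per_cell)
            infs.extend([infection[li]] * per_cell)
    return (np.array(vals), np.array(sexes), np.array(lines), np.array(infs))


class TestCovariateAnova:
    def test_null_infection_p_uniform(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            vals, sexes, lines, infs = _covariate_design(rng)
            vc = qg.covariate_anova(vals, sexes, lines, infs)
            ps.append(qg.infection_p_value(vc))
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_injected_shift_detected(self):
        rng = np.random.default_rng(22)
        vals, sexes, lines, infs = _covariate_design(rng, n_lines=100,
                                                     shift=2.0)
        vc = qg.covariate_anova(vals, sexes, lines, infs)
        assert qg.infection_p_value(vc) < 0.001

    def test_permuting_infection_labels_destroys_shift(self):
        rng = np.random.default_rng(23)
        vals, sexes, lines, infs = _covariate_design(rng, n_lines=100,
                                                     shift=2.0)
        line_ids = pd.unique(lines)
        line_inf = pd.Series(infs, index=lines).groupby(level=0).first()
        ps = []
        for _ in range(20):
            permuted = pd.Series(rng.permutation(line_inf[line_ids].to_numpy()),
                                 index=line_ids)
            vc = qg.covariate_anova(vals, sexes, lines,
                                    permuted[lines].to_numpy())
            ps.append(qg.infection_p_value(vc))
        assert np.median(ps) > 0.1

    def test_single_infection_class_rejected(self):
        rng = np.random.default_rng(24)
        vals, sexes, lines, _ = _covariate_design(rng, n_lines=10)
        with pytest.raises(qg.DesignError):
            qg.covariate_anova(vals, sexes, lines, np.zeros(len(vals)))


class TestLevene:
    def test_homogeneous_groups_near_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = qg.levene_test([g, g + 10])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_power_against_tenfold_sd(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 10, 50)
        _, p = qg.levene_test([a, b])
        assert p < 0.001

    def test_matches_brute_force_anova_on_deviations(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            groups = [rng.normal(0, s, rng.integers(3, 20))
                      for s in rng.uniform(0.5, 3, 4)]
            stat, p = qg.levene_test(groups)
            devs = [np.abs(g - g.mean()) for g in groups]
            f, fp = stats.f_oneway(*devs)
            assert stat == pytest.approx(f)
            assert p == pytest.approx(fp)

    def test_small_groups_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            qg.levene_test([[1.0, 2.0], [3.0, 4.0], [5.0]])


class TestVarianceLevelHeritability:
    def _simulate(self, seed, target):
        spec = sd.ArchitectureSpec(
            n_lines=60, n_markers=2, line_var=0, sexline_var=0, sex_effect=0,
            family="normal", mu=127.0, resid_var=0.92 * 576,
            target_variance_h2=target, seed=seed)
        panel, cov = sd.simulate_panel(spec)
        events, _ = sd.simulate_survival(panel, cov, spec)
        rep = sv.replicate_ln_sigma(events)
        return qg.variance_level_heritability(rep[rep["sex"] == "M"])

    def test_shared_sigma_gives_near_zero(self):
        h2s = [self._simulate(s, 0.0)[0] for s in range(10)]
        assert np.mean(h2s) < 0.12

    def test_dispersion_monotonicity(self):
        lo = np.mean([self._simulate(s, 0.3)[0] for s in range(10)])
        hi = np.mean([self._simulate(100 + s, 0.7)[0] for s in range(10)])
        assert hi > lo


class TestCrossSexCorrelation:
    def test_identical_sexes_r_one(self):
        df = pd.DataFrame({
            "line_id": list("ABCDE") * 2,
            "sex": ["M"] * 5 + ["F"] * 5,
            "lt50_h": list(range(5)) + list(range(5))})
        r, p, n = qg.cross_sex_correlation(df)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_independent_sexes_near_zero(self):
        rng = np.random.default_rng(41)
        n = 200
        df = pd.DataFrame({
            "line_id": [f"L{i}" for i in range(n)] * 2,
            "sex": ["M"] * n + ["F"] * n,
            "lt50_h": rng.normal(size=2 * n)})
        r, _, _ = qg.cross_sex_correlation(df)
        assert abs(r) < 3 / np.sqrt(n - 3)

    def test_too_few_lines_rejected(self):
        df = pd.DataFrame({"line_id": ["A", "A", "B", "B"],
                           "sex": ["M", "F", "M", "F"],
                           "lt50_h": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(qg.DesignError):
            qg.cross_sex_correlation(df)
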