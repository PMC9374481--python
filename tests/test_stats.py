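"""Group statistics: exclusion, t-tests, effect sizes, Bayes factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from visent.stats import (
    CONTRAST_METRICS,
    cohen_d_from_t,
    cohort_report,
    exclude_outliers,
    jzs_bf01,
    regress,
    student_t,
    write_report,
)


class TestExcludeOutliers:
    def test_all_equal_excludes_nothing(self):
        keep = exclude_outliers(np.full(10, 3.0), np.repeat("a", 10))
        assert keep.all()

    def test_single_far_outlier_excluded(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 20), [50.0]])
        keep = exclude_outliers(v, np.repeat("a", 21))
        assert not keep[20]
        assert keep[:20].all()

    def test_rule_is_per_group_not_pooled(self):
        # value far from the pooled mean but typical for its own group
        a = np.array([0.0, 0.1, -0.1, 0.05])
        b = np.array([100.0, 100.2, 99.8, 100.1])
        keep = exclude_outliers(np.concatenate([a, b]), ["a"] * 4 + ["b"] * 4)
        assert keep.all()


class TestStudentT:
    def test_identical_groups_give_t_zero_p_one(self):
        res = student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        # pooled SD = 1 -> t = -1/sqrt(2/3) = -1.2247, df = 4
        res = student_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == (4,)

    def test_study_sized_groups_have_df_56(self):
        rng = np.random.default_rng(1)
        res = student_t(rng.normal(size=38), rng.normal(size=20))
        assert res.df == (56,)

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=14), rng.normal(0.5, 1.2, size=9)
        res = student_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            student_t([1.0, 1.0], [1.0, 1.0])


class TestCohenD:
    @pytest.mark.parametrize(
        "t, n1, n2, expected",
        [(2.21, 38, 19, 0.621), (2.75, 38, 19, 0.773), (0.0, 10, 10, 0.0)],
    )
    def test_values(self, t, n1, n2, expected):
        assert round(cohen_d_from_t(t, n1, n2), 3) == expected

    def test_inverts_to_t(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.uniform(-4, 4)
            n1, n2 = rng.integers(3, 50, size=2)
            d = cohen_d_from_t(t, n1, n2)
            assert d / np.sqrt(1 / n1 + 1 / n2) == pytest.approx(abs(t))


class TestJZS:
    @pytest.mark.parametrize(
        "t, n1, n2, expected, tol",
        [
            (2.21, 38, 19, 0.497, 0.005),
            (0.32, 38, 20, 3.46, 0.03),
            (2.75, 38, 19, 0.18, 0.01),
        ],
    )
    def test_printed_values(self, t, n1, n2, expected, tol):
        assert abs(jzs_bf01(t, n1, n2) - expected) <= tol

    def test_matches_monte_carlo_prior_integration(self):
        """10^6-draw Monte-Carlo marginal likelihood agrees within 1%."""
        t, n1, n2, scale = 1.7, 14, 11, 0.707
        df, neff = n1 + n2 - 2, np.sqrt(n1 * n2 / (n1 + n2))
        rng = np.random.default_rng(4)
        delta = sps.cauchy.rvs(0.0, scale, size=1_000_000, random_state=rng)
        marg = sps.nct.pdf(t, df, delta * neff).mean()
        bf01_mc = sps.t.pdf(t, df) / marg
        assert abs(jzs_bf01(t, n1, n2, scale) - bf01_mc) / bf01_mc < 0.01

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n1, n2 in [(1.2, 20, 15), (-2.4, 30, 30)]:
            ref = 1.0 / float(pingouin.bayesfactor_ttest(t, n1, n2))
            assert jzs_bf01(t, n1, n2) == pytest.approx(ref, rel=1e-3)

    def test_monotone_in_effect_size(self):
        bfs = [jzs_bf01(t, 20, 20) for t in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))
        assert bfs[0] > 1.0  # t = 0 favors the null

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf01(1.0, 1, 10)
        with pytest.raises(ValueError):
            jzs_bf01(1.0, 10, 10, cauchy_scale=0.0)


class TestRegress:
    def test_eta_squared_from_study_f(self):
        # F(1,35) = 6.36 -> partial eta squared 0.154
        eta = 6.36 / (6.36 + 35)
        assert round(eta, 3) == 0.154
        rng = np.random.default_rng(5)
        x = rng.normal(size=37)
        res = regress(0.5 * x + rng.normal(size=37), x)
        assert res.eta2p == pytest.approx(
            res.statistic / (res.statistic + res.df[1]), rel=1e-12
        )

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = regress(2 * x + 1, x)
        assert res.eta2p == 1.0
        assert np.isinf(res.statistic)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        y = 1.3 * x + rng.normal(size=12)
        res = regress(y, x)
        X = np.stack([np.ones_like(x), x], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        F = ((ss_tot - ss_res) / 1) / (ss_res / (12 - 2))
        assert res.statistic == pytest.approx(F, abs=1e-9)
        assert res.slope == pytest.approx(beta[1], abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            regress(np.arange(5.0), np.ones(5))


def _metrics_table(rng, effects=None, n_ads=12, n_hc=10):
    effects = effects or {}
    rows = []
    for g, n in (("ADS", n_ads), ("HC", n_hc)):
        for i in range(n):
            row = {"subject_id": f"{g}{i}", "group": g}
            for m in CONTRAST_METRICS:
                row[m] = rng.normal() + (effects.get(m, 0.0) if g == "ADS" else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_null_cohorts_show_small_effects_on_average(self):
        rng = np.random.default_rng(7)
        d_all, bf_all = [], []
        for _ in range(25):
            rep = cohort_report(_metrics_table(rng, n_ads=38, n_hc=20))
            d_all += rep["contrasts"].cohen_d.tolist()
            bf_all += rep["contrasts"].bf01.tolist()
        assert np.mean(d_all) < 0.3
        assert np.mean(bf_all) > 1.0

    def test_effect_pattern_signs_recovered(self):
        rng = np.random.default_rng(8)
        rep = cohort_report(
            _metrics_table(
                rng,
                effects={"rel_amp": 2.0, "cv": -2.0, "base_periodic": -2.0},
                n_ads=30,
                n_hc=20,
            )
        )
        c = rep["contrasts"].set_index("metric")
        assert c.loc["rel_amp", "t"] > 0
        assert c.loc["cv", "t"] < 0
        assert c.loc["base_periodic", "t"] < 0
        assert abs(c.loc["abs_amp", "t"]) < 2.0

    def test_missing_metric_column_rejected(self):
        rng = np.random.default_rng(9)
        table = _metrics_table(rng).drop(columns=["itpl"])
        with pytest.raises(ValueError, match="itpl"):
            cohort_report(table)

    def test_report_writing_is_deterministic(self, tmp_path):
        rng = np.random.default_rng(10)
        table = _metrics_table(rng)
        cov = pd.DataFrame(
            {"subject_id": table.subject_id, "score": rng.normal(25, 3, len(table))}
        )
        rep = cohort_report(table, cov)
        for tag in ("a", "b"):
            write_report(rep, tmp_path / f"{tag}.csv", tmp_path / f"{tag}.json")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_type_one_error_rate_calibrated(self):
        """Exclusion + pooled t on null cohorts keeps its nominal level."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            v = rng.normal(size=20)
            g = np.array(["a"] * 12 + ["b"] * 8)
            keep = exclude_outliers(v, g)
            res = student_t(v[keep & (g == "a")], v[keep & (g == "b")])
            hits += res.p < 0.05
        margin = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) <= margin + 1e-9
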