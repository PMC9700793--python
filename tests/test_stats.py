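"""ANCOVA, effect sizes, chi-square matching, correlations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from prsf.stats import (
    ancova_one_way,
    chisq_equal_expected,
    correlate,
    partial_eta_squared,
)


class TestAncova:
    def _sim(self, rng, n=80, effect=0.5):
        group = np.repeat(["a", "b"], n // 2)
        cov = rng.normal(size=(n, 2))
        y = cov @ [0.8, -0.4] + effect * (group == "b") + rng.normal(size=n)
        return y, group, cov

    def test_constant_covariates_reduce_to_anova(self, rng):
        y, group, _ = self._sim(rng)
        cov = np.ones((y.size, 2))
        res = ancova_one_way(y, group, cov)
        f_ref, p_ref = sps.f_oneway(y[group == "a"], y[group == "b"])
        assert res.F == pytest.approx(f_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-10)
        assert res.df_error == y.size - 2

    def test_no_group_signal_yields_zero_F(self):
        y = np.tile([1.0, 2.0, 3.0], 4)
        group = np.array(["a", "b"] * 6)
        # y depends only on the covariate, identically across groups
        res = ancova_one_way(y, group, y.copy()[:, None])
        assert res.F == pytest.approx(0.0, abs=1e-18)
        assert res.eta_p2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin_reference(self, rng):
        """Independent oracle: pingouin's ANCOVA on a simulated design."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        y, group, cov = self._sim(rng)
        res = ancova_one_way(y, group, cov, covariate_names=["moca", "ifs"])
        df = pd.DataFrame(
            {"y": y, "group": group, "moca": cov[:, 0], "ifs": cov[:, 1]}
        )
        ref = pingouin.ancova(data=df, dv="y", between="group", covar=["moca", "ifs"])
        row = ref[ref.Source == "group"].iloc[0]
        assert res.F == pytest.approx(row.F, abs=1e-8)
        assert res.p == pytest.approx(row["p_unc"], abs=1e-10)
        assert res.eta_p2 == pytest.approx(row.np2, abs=1e-8)
        assert res.df_error == int(ref[ref.Source == "Residual"].DF.iloc[0])

    def test_eta_identity_holds(self, rng):
        for _ in range(10):
            y, group, cov = self._sim(rng, n=40, effect=rng.uniform(0, 2))
            res = ancova_one_way(y, group, cov)
            assert res.eta_p2 == pytest.approx(
                partial_eta_squared(res.F, res.df_effect, res.df_error), abs=1e-9
            )
            assert res.eta_p2 == pytest.approx(
                res.ss_effect / (res.ss_effect + res.ss_error), abs=1e-12
            )

    def test_singular_design_names_columns(self, rng):
        y, group, cov = self._sim(rng, n=20)
        cov = np.column_stack([cov[:, 0], cov[:, 0] * 2])  # collinear pair
        with pytest.raises(ValueError, match="cov1"):
            ancova_one_way(y, group, cov)

    def test_three_groups_df(self, rng):
        n = 30
        group = np.repeat(["a", "b", "c"], 10)
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        res = ancova_one_way(y, group, cov)
        assert res.df_effect == 2
        assert res.df_error == n - 3 - 2


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(10.55, 1, 76, 0.12), (4.47, 1, 28, 0.14)],
    )
    def test_reported_effect_sizes(self, F, df1, df2, expected):
        assert round(partial_eta_squared(F, df1, df2), 2) == expected

    def test_zero_F(self):
        assert partial_eta_squared(0.0, 1, 10) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 10)


class TestChisqEqualExpected:
    def test_known_value(self):
        chi2, p = chisq_equal_expected(208, 204)
        assert chi2 == pytest.approx(0.04, abs=0.005)
        assert p == pytest.approx(sps.chi2.sf(chi2, 1))

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_symmetric_and_zero_iff_equal(self, a, b):
        if a + b == 0:
            with pytest.raises(ValueError):
                chisq_equal_expected(a, b)
            return
        c_ab, _ = chisq_equal_expected(a, b)
        c_ba, _ = chisq_equal_expected(b, a)
        assert c_ab == pytest.approx(c_ba)
        assert (c_ab == 0) == (a == b)

    def test_rejects_negative_or_fractional(self):
        with pytest.raises(ValueError):
            chisq_equal_expected(-1, 2)
        with pytest.raises(ValueError):
            chisq_equal_expected(1.5, 2)


class TestCorrelate:
    def test_identity_is_pearson_one(self, rng):
        x = rng.normal(size=50)
        res = correlate(x, x + 0.0)
        assert res.method == "pearson"
        assert res.r == pytest.approx(1.0)

    def test_monotone_transform_of_heavy_tails_is_spearman_one(self, rng):
        x = rng.standard_cauchy(size=60)
        res = correlate(x, np.exp(np.clip(x, -20, 20)))
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=40)
        x, y = xy[:, 0], xy[:, 1]
        res = correlate(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        if res.method == "pearson":
            assert res.r == pytest.approx(num / den, abs=1e-10)
        assert abs(res.r - 0.5) < 0.25

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate(np.ones(10), rng.normal(size=10))
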