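import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidecomp.decomposition import (
    decompose,
    fit_lpm,
    group_contributions,
    percent_contributions,
)
from cidecomp.rank_cindex import cindex_direct, generalized_cindex, weighted_fractional_rank
from cidecomp.survey_data import DesignMatrix, FactorSpec, build_design_matrix

from conftest import random_cindex_fixture


def _design_from(df_cols: dict, group_map=None) -> DesignMatrix:
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in df_cols.items()})
    gm = group_map or {k: [k] for k in values.columns}
    return DesignMatrix(values=values, reference_levels={}, group_map=gm)


def _random_problem(seed, n=200, k_extra=3):
    rng = np.random.default_rng(seed)
    scores, weights, h = random_cindex_fixture(rng, n)
    if h.sum() == 0:
        h[0] = 1.0
    cols = {"x_rank": (scores > np.median(scores)).astype(float)}
    for j in range(k_extra):
        cols[f"z{j}"] = rng.random(n).round(0) if j % 2 else rng.normal(size=n)
    design = _design_from(cols)
    ranked = weighted_fractional_rank(scores, weights)
    return h, design, ranked, weights


class TestLPM:
    def test_saturated_fit_recovers_column(self, rng):
        n = 50
        x = (rng.random(n) > 0.5).astype(float)
        design = _design_from({"x": x})
        fit = fit_lpm(x, design, np.ones(n))
        assert fit.alpha == pytest.approx(0.0, abs=1e-10)
        assert fit.betas["x"] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_independent_outcome_gives_null_coefficients(self, rng):
        n = 2000
        x = rng.normal(size=(n, 2))
        h = (rng.random(n) < 0.4).astype(float)
        design = _design_from({"a": x[:, 0], "b": x[:, 1]})
        fit = fit_lpm(h, design, np.ones(n))
        # slope SE for a standardized column is about sqrt(mu(1-mu)/n)
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(fit.betas["a"]) < 3 * se and abs(fit.betas["b"]) < 3 * se
        assert fit.alpha == pytest.approx(h.mean(), abs=3 * se)

    def test_weighted_residuals_average_zero(self, rng):
        h, design, ranked, weights = _random_problem(7)
        fit = fit_lpm(h, design, weights)
        wn = weights / weights.sum()
        assert abs(float(wn @ fit.residuals)) < 1e-12
        np.testing.assert_allclose(fit.fitted + fit.residuals, h, atol=1e-12)

    def test_duplicated_column_rank_error(self, rng):
        n = 40
        x = rng.normal(size=n)
        design = _design_from({"x1": x, "x2": x})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lpm((x > 0).astype(float), design, np.ones(n))


class TestDecomposition:
    def test_outcome_as_its_own_factor_explains_everything(self, rng):
        scores, weights, h = random_cindex_fixture(rng, 300)
        if h.sum() == 0:
            h[0] = 1.0
        ranked = weighted_fractional_rank(scores, weights)
        res = decompose(h, _design_from({"h": h}), ranked, weights)
        assert res.table.loc["h", "contribution"] == pytest.approx(res.total_C, rel=1e-10)
        assert res.residual_contribution == pytest.approx(0.0, abs=1e-12)

    def test_rank_independent_column_contributes_nothing(self, rng):
        n = 4000
        scores = rng.normal(size=n)
        z = (rng.random(n) > 0.5).astype(float)  # independent of wealth
        h = (rng.random(n) < 0.3 + 0.3 * (scores > 0)).astype(float)
        ranked = weighted_fractional_rank(scores, np.ones(n))
        res = decompose(h, _design_from({"z": z}), ranked, np.ones(n))
        assert abs(res.table.loc["z", "contribution"]) < 0.01
        assert abs(res.table.loc["z", "factor_index"]) < 0.03

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_exact_additivity_and_residual_gc_identity(self, seed):
        h, design, ranked, weights = _random_problem(seed)
        res = decompose(h, design, ranked, weights)
        assert float(res.table["contribution"].sum()) + res.residual_contribution == pytest.approx(
            res.total_C, abs=1e-10
        )
        # residual (remainder) agrees with GC of the LPM residuals / mu
        fit = fit_lpm(h, design, weights)
        gc = generalized_cindex(fit.residuals, ranked) / res.mu_h
        assert res.residual_contribution == pytest.approx(gc, abs=1e-8)

    def test_weight_scale_invariance(self, rng):
        h, design, ranked, weights = _random_problem(99)
        res1 = decompose(h, design, ranked, weights)
        res2 = decompose(h, design, ranked, weights * 1234.5)
        pd.testing.assert_frame_equal(res1.table, res2.table)
        assert res1.residual_contribution == pytest.approx(res2.residual_contribution, rel=1e-12)

    def test_zero_mean_column_contribution_zeroed_with_warning(self, rng):
        n = 100
        scores = rng.normal(size=n)
        x = rng.normal(size=n)
        x = x - (np.ones(n) / n) @ x  # exactly zero (unweighted) mean
        h = (rng.random(n) < 0.5).astype(float)
        ranked = weighted_fractional_rank(scores, np.ones(n))
        with pytest.warns(UserWarning, match="zero weighted mean"):
            res = decompose(h, _design_from({"x0": x}), ranked, np.ones(n))
        assert res.table.loc["x0", "contribution"] == 0.0
        assert res.residual_contribution == pytest.approx(res.total_C, rel=1e-10)


class TestGroupingAndPercent:
    def test_grouping_preserves_additivity_and_sums_blocks(self, rng):
        h, design, ranked, weights = _random_problem(5, k_extra=3)
        gm = {"block": ["x_rank", "z0"], "rest": ["z1", "z2"]}
        res = percent_contributions(decompose(h, design, ranked, weights))
        grouped = group_contributions(res, gm)
        assert grouped.table.loc["block", "contribution"] == pytest.approx(
            res.table.loc[["x_rank", "z0"], "contribution"].sum()
        )
        total = grouped.table["contribution"].sum() + grouped.residual_contribution
        assert total == pytest.approx(res.total_C, abs=1e-12)
        assert grouped.table["percent"].sum() + grouped.residual_percent == pytest.approx(100.0)

    def test_singleton_groups_identity(self, rng):
        h, design, ranked, weights = _random_problem(6)
        res = decompose(h, design, ranked, weights)
        grouped = group_contributions(res, {c: [c] for c in res.table.index})
        np.testing.assert_allclose(
            grouped.table["contribution"].reindex(res.table.index), res.table["contribution"]
        )

    def test_mixed_sign_group_is_signed_sum(self):
        # constructed fixture: the two dummies of one factor pull opposite ways
        n = 8
        scores = np.arange(float(n))
        lo = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)  # poor side
        hi = np.array([0, 0, 0, 0, 0, 1, 1, 1], dtype=float)  # rich side
        # outcome elevated in BOTH tails: positive betas on lo and hi, but
        # C_lo < 0 (poor) and C_hi > 0 (rich) -> opposite-sign contributions
        h = np.array([1, 1, 1, 0, 0, 1, 1, 1], dtype=float)
        ranked = weighted_fractional_rank(scores, np.ones(n))
        design = _design_from({"f[lo]": lo, "f[hi]": hi}, group_map={"f": ["f[lo]", "f[hi]"]})
        res = decompose(h, design, ranked, np.ones(n))
        parts = res.table["contribution"]
        assert parts["f[lo]"] * parts["f[hi]"] < 0  # opposite signs by construction
        grouped = group_contributions(res)
        assert grouped.table.loc["f", "contribution"] == pytest.approx(parts.sum())

    def test_unassigned_column_error(self, rng):
        h, design, ranked, weights = _random_problem(8)
        with pytest.raises(ValueError, match="not assigned"):
            group_contributions(decompose(h, design, ranked, weights), {"only": ["x_rank"]})

    def test_percent_shares_and_instability_flag(self, rng):
        h, design, ranked, weights = _random_problem(10)
        res = percent_contributions(decompose(h, design, ranked, weights))
        assert res.table["percent"].sum() + res.residual_percent == pytest.approx(100.0)
        # force a tiny total C: flag raises, percents still reported
        tiny = percent_contributions(decompose(h, design, ranked, weights), floor=10.0)
        assert tiny.unstable

    def test_fifty_percent_share_example(self):
        # a contribution of 0.02 out of C = 0.04 is a 50% share
        table = pd.DataFrame({"contribution": [0.02, 0.01]}, index=["a", "b"])
        table.index.name = "factor"
        from cidecomp.decomposition import DecompositionResult

        res = DecompositionResult(
            table=table, residual_contribution=0.01, total_C=0.04, mu_h=0.5, n=100
        )
        out = percent_contributions(res)
        assert out.table.loc["a", "percent"] == pytest.approx(50.0)
        assert out.residual_percent == pytest.approx(25.0)


class TestEndToEndDesign:
    def test_survey_design_matrix_roundtrip(self, survey_frame):
        from cidecomp.survey_data import derive_outcomes

        df = derive_outcomes(survey_frame)
        df["overweight_f"] = df["overweight"].astype(float)
        design = build_design_matrix(
            df, [FactorSpec("age_years", kind="continuous"), FactorSpec("race"), FactorSpec("residence")]
        )
        ranked = weighted_fractional_rank(df["wealth_score"], df["weight"])
        res = decompose(df["overweight_f"].to_numpy(), design, ranked, df["weight"].to_numpy())
        assert res.total_C == pytest.approx(
            cindex_direct(df["overweight_f"].to_numpy(), ranked).C, rel=1e-12
        )
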