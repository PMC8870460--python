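import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methstage import linmod
from methstage.linmod import (
    StageLinearModel,
    bh_adjust,
    build_design,
    contrast_test,
    ebayes,
    fit_linear,
    stage_contrast_vector,
)
from tests.conftest import make_sample_sheet


def bh_oracle(p):
    """Exhaustive step-up definition: adj_i = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        cands = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        adj[idx] = min(1.0, min(cands))
    return adj


class TestBuildDesign:
    def test_indicator_coding(self):
        sheet = pd.DataFrame(
            {"sample_id": ["c1", "c2", "i1"], "parent_stage": ["CONTROL", "CONTROL", "I"]}
        )
        sheet_full = make_sample_sheet(2, 1)
        d = build_design(sheet_full)
        # controls: intercept only
        np.testing.assert_array_equal(d.values[0], [1, 0, 0, 0, 0])
        np.testing.assert_array_equal(d.values[1], [1, 0, 0, 0, 0])
        # first stage-I sample
        np.testing.assert_array_equal(d.values[2], [1, 1, 0, 0, 0])

    def test_permuting_samples_permutes_rows(self):
        sheet = make_sample_sheet(3, 2)
        d = build_design(sheet)
        perm = np.random.default_rng(0).permutation(len(sheet))
        d2 = build_design(sheet.iloc[perm].reset_index(drop=True))
        np.testing.assert_array_equal(d2.values, d.values[perm])

    def test_cohort_composition_counts(self):
        # 50 / 86 / 60 / 36 stage samples + 42 controls -> 274 rows, full rank
        rows = []
        for stage, n in [("CONTROL", 42), ("I", 50), ("II", 86), ("III", 60), ("IV", 36)]:
            rows += [(f"{stage}_{i}", stage) for i in range(n)]
        sheet = pd.DataFrame(rows, columns=["sample_id", "parent_stage"])
        d = build_design(sheet)
        assert d.values.shape == (274, 5)
        assert np.linalg.matrix_rank(d.values) == 5

    def test_empty_stage_raises_with_name(self):
        sheet = make_sample_sheet(2, 2)
        sheet = sheet[sheet.parent_stage != "III"]
        with pytest.raises(ValueError, match="III"):
            build_design(sheet)


class TestFitLinear:
    def test_exact_group_means_zero_residual(self, sample_sheet, stage_design):
        means = {"CONTROL": 1.0, "I": 3.0, "II": 0.0, "III": -2.0, "IV": 5.0}
        y = np.array([means[s] for s in sample_sheet.parent_stage])
        m = pd.DataFrame([y], index=["f"], columns=sample_sheet.sample_id)
        fit = fit_linear(m, stage_design)
        assert fit.sigma2["f"] == pytest.approx(0.0, abs=1e-20)
        assert fit.coefficients.loc["f", "intercept"] == pytest.approx(1.0)
        assert fit.coefficients.loc["f", "stageI"] == pytest.approx(2.0)
        assert fit.coefficients.loc["f", "stageIV"] == pytest.approx(4.0)

    def test_matches_normal_equations_oracle(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(
            rng.normal(size=(100, len(sample_sheet))),
            index=[f"f{i}" for i in range(100)],
            columns=sample_sheet.sample_id,
        )
        fit = fit_linear(m, stage_design)
        x = stage_design.values
        for i in range(100):
            y = m.iloc[i].to_numpy()
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            np.testing.assert_allclose(fit.coefficients.iloc[i].to_numpy(), beta, atol=1e-10)
            resid = y - x @ beta
            s2 = resid @ resid / (len(y) - 5)
            assert fit.sigma2.iloc[i] == pytest.approx(s2, abs=1e-10)

    def test_intercept_is_control_mean(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(
            rng.normal(size=(5, len(sample_sheet))), columns=sample_sheet.sample_id
        )
        fit = fit_linear(m, stage_design)
        ctrl = sample_sheet.parent_stage == "CONTROL"
        np.testing.assert_allclose(
            fit.coefficients["intercept"].to_numpy(),
            m.loc[:, ctrl.to_numpy()].mean(axis=1).to_numpy(),
            atol=1e-12,
        )


class TestEbayes:
    def test_common_variance_pools_fully(self, rng):
        sheet = make_sample_sheet(5, 5)
        design = build_design(sheet)
        m = pd.DataFrame(
            rng.normal(0, 2.0, size=(5000, 25)), columns=sheet.sample_id
        )
        fit = fit_linear(m, design)
        mod = ebayes(fit)
        assert mod.d0 >= 200  # may be inf: variances consistent with one value
        assert np.abs(mod.s2_post.mean() - 4.0) / 4.0 < 0.05

    def test_d0_zero_recovers_ordinary_t(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(
            rng.normal(size=(50, len(sample_sheet))), columns=sample_sheet.sample_id
        )
        fit = fit_linear(m, stage_design)
        mod = ebayes(fit, d0=0)
        tab = contrast_test(fit, mod, stage_contrast_vector("I"), "I")
        c = stage_contrast_vector("I")
        xtx_inv = np.linalg.inv(stage_design.values.T @ stage_design.values)
        u = np.sqrt(c @ xtx_inv @ c)
        t_ord = (fit.coefficients.to_numpy() @ c) / (u * np.sqrt(fit.sigma2.to_numpy()))
        np.testing.assert_allclose(tab["t"].to_numpy(), t_ord, atol=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        sheet = make_sample_sheet(40, 40)
        design = build_design(sheet)
        m = pd.DataFrame(rng.normal(size=(10000, 200)), columns=sheet.sample_id)
        fit = fit_linear(m, design)
        mod = ebayes(fit)
        tab = contrast_test(fit, mod, stage_contrast_vector("III"), "III")
        frac = float((tab["p"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.007

    def test_shrinkage_reduces_t_variance(self):
        rng = np.random.default_rng(8)
        sheet = make_sample_sheet(5, 5)
        design = build_design(sheet)
        # heterogeneous variances so d0 is finite and shrinkage bites
        s2 = 1.0 / rng.chisquare(6, size=2000) * 6
        m = pd.DataFrame(
            rng.normal(size=(2000, 25)) * np.sqrt(s2)[:, None], columns=sheet.sample_id
        )
        fit = fit_linear(m, design)
        mod = ebayes(fit)
        assert np.isfinite(mod.d0)
        c = stage_contrast_vector("II")
        t_mod = contrast_test(fit, mod, c, "II")["t"].to_numpy()
        mod0 = ebayes(fit, d0=0)
        t_ord = contrast_test(fit, mod0, c, "II")["t"].to_numpy()
        assert np.var(t_mod) <= np.var(t_ord)

    def test_posterior_variance_between_prior_and_sample(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(
            rng.normal(size=(200, len(sample_sheet))) * rng.uniform(0.5, 3, size=(200, 1)),
            columns=sample_sheet.sample_id,
        )
        fit = fit_linear(m, stage_design)
        mod = ebayes(fit)
        lo = np.minimum(fit.sigma2.to_numpy(), mod.s0_2)
        hi = np.maximum(fit.sigma2.to_numpy(), mod.s0_2)
        post = mod.s2_post.to_numpy()
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)


class TestContrastTest:
    def test_sign_flip_antisymmetry(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(
            rng.normal(size=(30, len(sample_sheet))), columns=sample_sheet.sample_id
        )
        fit = fit_linear(m, stage_design)
        mod = ebayes(fit)
        c = stage_contrast_vector("II", "III")
        a = contrast_test(fit, mod, c, "fwd")
        b = contrast_test(fit, mod, -c, "rev")
        np.testing.assert_allclose(a["lfc"], -b["lfc"], atol=1e-12)
        np.testing.assert_allclose(a["t"], -b["t"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_stage_vs_control_equals_coefficient(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(
            rng.normal(size=(20, len(sample_sheet))), columns=sample_sheet.sample_id
        )
        fit = fit_linear(m, stage_design)
        mod = ebayes(fit)
        tab = contrast_test(fit, mod, stage_contrast_vector("IV"), "IV")
        np.testing.assert_allclose(tab["lfc"], fit.coefficients["stageIV"], atol=1e-14)

    def test_planted_mean_difference_recovered(self, rng):
        sheet = make_sample_sheet(40, 40)
        design = build_design(sheet)
        y = rng.normal(size=(1, 200))
        y[0, sheet.parent_stage.to_numpy() == "II"] += 1.5
        y[0, sheet.parent_stage.to_numpy() == "I"] += 0.5
        m = pd.DataFrame(y, index=["f"], columns=sheet.sample_id)
        fit = fit_linear(m, design)
        mod = ebayes(fit, d0=0)
        tab = contrast_test(fit, mod, stage_contrast_vector("II", "I"), "II-I")
        se = np.sqrt(2.0 / 40)
        assert abs(tab.loc["f", "lfc"] - 1.0) < 3 * se

    def test_zero_contrast_rejected(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(rng.normal(size=(15, len(sample_sheet))), columns=sample_sheet.sample_id)
        fit = fit_linear(m, stage_design)
        mod = ebayes(fit)
        with pytest.raises(ValueError):
            contrast_test(fit, mod, np.zeros(5), "null")

    def test_monotone_t_vs_p(self, rng, sample_sheet, stage_design):
        m = pd.DataFrame(rng.normal(size=(100, len(sample_sheet))), columns=sample_sheet.sample_id)
        fit = fit_linear(m, stage_design)
        mod = ebayes(fit)
        tab = contrast_test(fit, mod, stage_contrast_vector("I"), "I")
        order = tab["t"].abs().sort_values().index
        p_sorted = tab.loc[order, "p"].to_numpy()
        assert np.all(np.diff(p_sorted) <= 1e-12)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestModelFrontEnd:
    def test_summary_mentions_fit_dimensions(self, rng):
        sheet = make_sample_sheet(5, 5)
        m = pd.DataFrame(
            rng.normal(size=(20, 25)),
            index=[f"f{i}" for i in range(20)],
            columns=sheet.sample_id,
        )
        res = StageLinearModel(m, sheet).fit()
        text = res.summary(top=2)
        assert "features: 20" in text and "prior df" in text

    def test_beta_and_m_mode_share_code_path(self, rng):
        # the engine is agnostic to the input scale: running on a beta
        # matrix is the same computation on different numbers
        sheet = make_sample_sheet(5, 5)
        beta = pd.DataFrame(
            rng.uniform(0.05, 0.95, size=(30, 25)), columns=sheet.sample_id
        )
        res_beta = StageLinearModel(beta, sheet).fit()
        tab = res_beta.contrast("I")
        assert np.all(np.abs(tab["lfc"]) < 1)  # beta-scale differences are bounded
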