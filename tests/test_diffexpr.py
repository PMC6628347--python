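import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from evmir import (
    EBayesPrior,
    ExpressionMatrix,
    ModeratedTTest,
    bh_adjust,
    estimate_prior,
    fit_group_model,
    inverse_trigamma,
    moderated_t,
    select_significant,
    to_expression,
)
from evmir.preprocess import NormalizedMatrix, ReferenceSet


def _nm(dct: pd.DataFrame) -> NormalizedMatrix:
    refs = ReferenceSet([], pd.Series(dtype=int), pd.Series(dtype=float))
    return NormalizedMatrix(dct=dct, reference=refs)


def _em(case: np.ndarray, ctrl: np.ndarray, probe_ids=None) -> ExpressionMatrix:
    case, ctrl = np.atleast_2d(case), np.atleast_2d(ctrl)
    n_p = case.shape[0]
    probe_ids = probe_ids or [f"g{i}" for i in range(n_p)]
    cols = [f"c{i}" for i in range(case.shape[1])] + [f"k{i}" for i in range(ctrl.shape[1])]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=probe_ids, columns=cols)
    groups = pd.Series(["case"] * case.shape[1] + ["control"] * ctrl.shape[1], index=cols)
    return ExpressionMatrix(values=values, groups=groups)


class TestToExpression:
    def test_sign_flip_and_involution(self):
        dct = pd.DataFrame({"s1": [0.0, 2.0], "s2": [-1.5, 3.0]}, index=["a", "b"])
        meta = pd.Series(["case", "control"], index=["s1", "s2"])
        em = to_expression(_nm(dct), meta)
        assert em.values.loc["a", "s1"] == 0.0
        pd.testing.assert_frame_equal(-em.values, dct)

    def test_lower_ct_in_cases_gives_higher_case_expression(self):
        # case sample has lower dCt (more abundant) -> higher expression
        dct = pd.DataFrame({"s1": [1.0], "s2": [4.0]}, index=["a"])
        meta = pd.Series(["case", "control"], index=["s1", "s2"])
        em = to_expression(_nm(dct), meta)
        assert em.values.loc["a", "s1"] > em.values.loc["a", "s2"]

    def test_sample_without_group_is_hard_error(self):
        dct = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["a"])
        meta = pd.Series(["case"], index=["s1"])
        with pytest.raises(ValueError, match="without a group"):
            to_expression(_nm(dct), meta)


class TestFitGroupModel:
    def test_hand_computation(self):
        em = _em([[3.0, 4.0, 5.0]], [[1.0, 2.0, 3.0]])
        fit = fit_group_model(em)
        assert fit.loc["g0", "logfc"] == pytest.approx(2.0)
        assert fit.loc["g0", "s_sq"] == pytest.approx(1.0)
        assert fit.loc["g0", "df_residual"] == 4

    def test_identical_groups_zero_logfc(self):
        x = np.array([[1.0, 5.0, 2.0]])
        fit = fit_group_model(_em(x, x))
        assert fit.loc["g0", "logfc"] == 0.0

    def test_masked_probe_flagged_and_df_complete(self):
        case = np.array([[1.0, 2.0, 3.0], [np.nan, np.nan, 1.0]])
        ctrl = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        fit = fit_group_model(_em(case, ctrl))
        assert fit.loc["g0", "df_residual"] == 4  # n - 2 for complete data
        assert not fit.loc["g1", "ok"]
        assert np.isnan(fit.loc["g1", "s_sq"])

    def test_tiny_group_is_hard_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_group_model(_em([[1.0]], [[1.0, 2.0]]))


class TestEstimatePrior:
    def test_equal_variances_hit_infinite_branch(self):
        prior = estimate_prior(np.full(50, 2.0), np.full(50, 4.0))
        assert np.isinf(prior.d0)
        fit = pd.DataFrame(
            {"logfc": [1.0, 2.0], "s_sq": [2.0, 2.0], "df_residual": [4.0, 4.0],
             "n_case": [3, 3], "n_control": [3, 3], "ok": [True, True]},
            index=["a", "b"],
        )
        res = moderated_t(fit, prior)
        assert res["s_tilde_sq"].nunique() == 1  # all moderated variances equal

    def test_recovers_known_truth_from_simulation(self):
        rng = np.random.default_rng(2024)
        d0, s0_sq, dg = 4.0, 2.0, 4.0
        s_sq = s0_sq * d0 / rng.chisquare(d0, 2000)  # draw true variances
        sample = s_sq * rng.chisquare(dg, 2000) / dg  # then sampling noise
        prior = estimate_prior(sample, np.full(2000, dg))
        assert abs(prior.d0 - d0) / d0 < 0.25
        assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.10

    @pytest.mark.parametrize("y", [0.1, 1.0, 5.0])
    def test_inverse_trigamma_forward_map(self, y):
        assert special.polygamma(1, inverse_trigamma(y)) == pytest.approx(y, abs=1e-8)

    def test_all_zero_variances_is_hard_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_prior(np.zeros(10), np.full(10, 4.0))


class TestModeratedT:
    def test_d0_zero_recovers_ordinary_pooled_t(self):
        rng = np.random.default_rng(7)
        case = rng.normal(0.3, 1.2, size=(100, 6))
        ctrl = rng.normal(0.0, 1.2, size=(100, 5))
        fit = fit_group_model(_em(case, ctrl))
        res = moderated_t(fit, EBayesPrior(d0=1e-300, s0_sq=1.0))
        t_ref, p_ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        assert np.max(np.abs(res["t"].to_numpy() - t_ref)) < 1e-10
        assert np.max(np.abs(res["p_value"].to_numpy() - p_ref)) < 1e-10

    def test_worked_example(self):
        fit = pd.DataFrame(
            {"logfc": [2.0], "s_sq": [2.0], "df_residual": [4.0],
             "n_case": [3], "n_control": [3], "ok": [True]},
            index=["g"],
        )
        res = moderated_t(fit, EBayesPrior(d0=4.0, s0_sq=1.0))
        assert res.loc["g", "s_tilde_sq"] == pytest.approx(1.5)
        assert res.loc["g", "t"] == pytest.approx(2.0)
        assert res.loc["g", "df_total"] == 8
        assert res.loc["g", "p_value"] == pytest.approx(2 * stats.t.sf(2.0, 8))
        assert res.loc["g", "p_value"] == pytest.approx(0.0805, abs=5e-4)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(8)
        case, ctrl = rng.normal(size=(20, 5)), rng.normal(size=(20, 5))
        fit_a = fit_group_model(_em(case, ctrl))
        fit_b = fit_group_model(_em(ctrl, case))
        prior = estimate_prior(fit_a["s_sq"], fit_a["df_residual"])
        ta = moderated_t(fit_a, prior)["t"]
        tb = moderated_t(fit_b, prior)["t"]
        assert np.allclose(ta.to_numpy(), -tb.to_numpy())

    def test_monotone_interpolation_in_d0(self):
        # for s_g^2 > s0^2 the moderated |t| rises monotonically with d0
        fit = pd.DataFrame(
            {"logfc": [1.0], "s_sq": [3.0], "df_residual": [4.0],
             "n_case": [3], "n_control": [3], "ok": [True]},
            index=["g"],
        )
        d0s = [1e-12, 0.5, 2.0, 8.0, 64.0, 1e6]
        ts = [moderated_t(fit, EBayesPrior(d0=d, s0_sq=1.0)).loc["g", "t"] for d in d0s]
        assert all(b > a for a, b in zip(ts, ts[1:]))
        t_inf = moderated_t(fit, EBayesPrior(d0=np.inf, s0_sq=1.0)).loc["g", "t"]
        assert ts[-1] < t_inf
        assert ts[0] == pytest.approx(1.0 / np.sqrt(3.0 * (2 / 3)), rel=1e-9)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_hand_step_up_lists(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([0.001, 0.01, 0.9]), [0.003, 0.015, 0.9])

    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    @settings(max_examples=100)
    def test_matches_bruteforce_step_up(self, seed, n):
        p = np.random.default_rng(seed).uniform(size=n)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):  # independent step-up from the top
            i = order[rank]
            running = min(running, p[i] * n / (rank + 1))
            adj[i] = running
        assert np.allclose(bh_adjust(p), adj, atol=1e-12)

    def test_order_preserving(self):
        p = np.random.default_rng(1).uniform(size=200)
        adj = bh_adjust(p)
        srt = np.argsort(p)
        assert (np.diff(adj[srt]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSelectSignificant:
    def test_strict_and_inclusive_boundaries(self):
        table = pd.DataFrame(
            {"logfc": [2.0, 1.0, 0.5, -3.0], "adj_p_value": [0.05, 0.01, 0.01, 0.049]},
            index=list("abcd"),
        )
        kept = select_significant(table, 0.05, 1.0)
        assert list(kept.index) == ["b", "d"]  # a: p==0.05 out; b: |lfc|==1 in

    def test_published_rule_retains_full_fixture(self, table2):
        kept = select_significant(table2, 0.05, 1.0)
        assert len(kept) == 114


class TestModeratedTTestEstimator:
    def test_matches_r_limma_oracle(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript with limma is required for the oracle check"
        rng = np.random.default_rng(42)
        G, n1, n2 = 30, 5, 5
        s2 = 2.0 * 4 / rng.chisquare(4, G)
        case = rng.normal(0.0, np.sqrt(s2)[:, None], (G, n1))
        ctrl = rng.normal(0.5, np.sqrt(s2)[:, None], (G, n2))
        mat = pd.DataFrame(np.hstack([case, ctrl]), index=[f"g{i}" for i in range(G)])
        mat.to_csv(tmp_path / "m.csv")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'x <- as.matrix(read.csv("m.csv", row.names=1))\n'
            f'design <- cbind(Intercept=1, Case=c(rep(1,{n1}), rep(0,{n2})))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(logFC=fit$coefficients[,"Case"], t=fit$t[,"Case"],'
            ' p=fit$p.value[,"Case"], d0=fit$df.prior, s0=fit$s2.prior)\n'
            'write.csv(out, "out.csv")\n'
        )
        subprocess.run([rscript, script.name], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        y = np.array(["case"] * n1 + ["control"] * n2)
        est = ModeratedTTest().fit(mat.T, y)
        res = est.results_
        assert np.allclose(res["logfc"], ref["logFC"], atol=1e-10)
        assert np.allclose(res["t"], ref["t"], atol=1e-10)
        assert np.allclose(res["p_value"], ref["p"], atol=1e-12)
        assert est.prior_.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert est.prior_.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)

    def test_numeric_labels_and_ndarray_input(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 8))
        y = np.array([0] * 6 + [1] * 6)
        est = ModeratedTTest().fit(X, y)
        assert len(est.results_) == 8
        assert est.results_["adj_p_value"].between(0, 1).all()

    def test_sign_convention_end_to_end(self):
        # a probe with lower Ct (higher -dCt) in cases gets positive logFC
        rng = np.random.default_rng(4)
        dct = pd.DataFrame(
            rng.normal(5.0, 0.3, size=(10, 12)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(12)],
        )
        meta = pd.Series(["case"] * 6 + ["control"] * 6, index=dct.columns)
        dct.loc["g0", meta == "case"] -= 3.0  # 3 cycles lower Ct in cases
        em = to_expression(_nm(dct), meta)
        est = ModeratedTTest().fit(em.values.T, em.groups.to_numpy())
        assert est.results_.loc["g0", "logfc"] == pytest.approx(3.0, abs=0.5)
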