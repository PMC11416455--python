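"""The NB quasi-likelihood layer: GLM fits against closed forms and a
grid-search oracle, dispersion recovery, EB moderation, and the F-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from evmirna.errors import AnalysisError
from evmirna.glm import (
    NBQLModel,
    _squeeze_quasi,
    bh_adjust,
    design_matrix,
    estimate_dispersions,
    fit_nb_glm,
    pairwise_contrast,
)

from _helpers import two_group_design


def nb_loglik_scalar(y, mu, phi):
    """Direct NB log-likelihood for one observation (oracle helper)."""
    if phi < 1e-12:
        return y * np.log(mu) - mu - special.gammaln(y + 1)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(mu / (r + mu))
        + r * np.log(r / (r + mu))
    )


class TestFitNbGlm:
    def test_one_group_poisson_closed_form(self):
        y = np.array([[3, 7, 5, 9, 6, 4]], float)
        lib = np.array([1e4, 2e4, 1.5e4, 3e4, 1e4, 2e4])
        X = np.ones((6, 1))
        beta, mu, dev = fit_nb_glm(y, X, np.log(lib), 0.0)
        # Poisson MLE with offsets: rate = total count / total exposure
        assert beta[0, 0] == pytest.approx(np.log(y.sum() / lib.sum()), abs=1e-8)

    def test_saturated_design_zero_deviance(self):
        y = np.array([[4, 9, 2, 11]], float)
        X = np.eye(4)
        _, _, dev = fit_nb_glm(y, X, np.zeros(4), 0.1)
        assert dev[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_group_deviance_matches_grid_search(self):
        # fixed 3v3 fixture; oracle maximizes the NB log-likelihood over a
        # fine grid of the two group means
        y = np.array([[12, 19, 15, 31, 42, 37]], float)
        X = two_group_design(3).to_numpy()
        phi = 0.1
        beta, mu, dev = fit_nb_glm(y, X, np.zeros(6), phi)
        grids = [np.linspace(5, 30, 2001), np.linspace(20, 60, 2001)]
        best = -np.inf
        for mu_a in grids[0]:
            ll_a = sum(nb_loglik_scalar(v, mu_a, phi) for v in y[0, :3])
            for mu_b in grids[1]:
                ll = ll_a + sum(nb_loglik_scalar(v, mu_b, phi) for v in y[0, 3:])
                best = max(best, ll)
        # saturated loglik for deviance on the oracle side
        sat = sum(nb_loglik_scalar(v, v, phi) for v in y[0])
        dev_oracle = 2 * (sat - best)
        assert dev[0] == pytest.approx(dev_oracle, abs=1e-3)
        # grid MLEs are the group means for NB with common dispersion
        assert np.exp(beta[0, 0]) == pytest.approx(y[0, :3].mean(), rel=1e-6)

    def test_rank_deficient_design_rejected(self):
        y = np.array([[1, 2, 3, 4]], float)
        X = np.ones((4, 2))
        with pytest.raises(AnalysisError):
            fit_nb_glm(y, X, np.zeros(4), 0.1)


class TestDispersionEstimation:
    def test_poisson_counts_give_near_zero_trend(self):
        rng = np.random.default_rng(21)
        G, n = 2000, 6
        mean = rng.uniform(50, 5000, G)[:, None]
        y = rng.poisson(np.tile(mean, (1, n)))
        X = np.ones((n, 1))
        d = estimate_dispersions(y, X, np.full(n, np.log(mean.sum())), n_bins=10)
        assert np.mean(d.bin_dispersion <= 0.01) >= 0.95

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(22)
        G, n, phi = 2000, 12, 0.1
        mean = 2.0 ** rng.uniform(5, 12, G)[:, None]
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + np.tile(mean, (1, n))))
        X = np.ones((n, 1))
        d = estimate_dispersions(y, X, np.full(n, 14.0), n_bins=10)
        assert 0.07 <= float(np.median(d.trended)) <= 0.13

    def test_identical_quasi_dispersions_not_shrunk(self):
        s2 = np.full(50, 1.7)
        post, d0, s0 = _squeeze_quasi(s2, df=4)
        assert np.isinf(d0)
        assert np.allclose(post, s2)

    def test_zero_residual_df_errors(self):
        y = np.array([[1, 2]], float)
        with pytest.raises(AnalysisError):
            estimate_dispersions(y, np.eye(2), np.zeros(2), n_bins=1)


class TestQLFTest:
    def test_identical_groups_give_null_result(self):
        y = np.tile([[20, 30, 25]], (1, 2)).astype(float)  # same counts per group
        counts = pd.DataFrame(y, index=["m0"], columns=[f"s{j}" for j in range(6)])
        X = two_group_design(3)
        fit = NBQLModel(counts, X, offset=np.zeros(6)).fit(dispersion=0.1)
        tab = fit.test(pairwise_contrast(X, "B", "A"))
        assert tab.loc["m0", "log2fc"] == pytest.approx(0.0, abs=1e-6)
        assert tab.loc["m0", "f_stat"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["m0", "p_value"] == pytest.approx(1.0)

    def test_zero_contrast_rejected(self):
        counts = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["m0"],
                              columns=[f"s{j}" for j in range(6)])
        X = two_group_design(3)
        fit = NBQLModel(counts, X, offset=np.zeros(6)).fit(dispersion=0.1)
        with pytest.raises(AnalysisError):
            fit.test(np.zeros(2))

    def test_power_on_planted_fourfold_effects(self):
        # 4-fold effects, dispersion 0.1, n=3/group, depth 1e6, baseline
        # CPM >= 50: the regime where a 3v3 NB comparison has high power
        # (at 2-fold the BH-thresholded power of this design tops out near
        # 0.25 for any NB QL implementation)
        rng = np.random.default_rng(31)
        G, n_sig = 1000, 100
        cpm = 2.0 ** rng.uniform(np.log2(50), 14, G)
        mu_a = cpm / 1e6 * 1e6  # counts at depth 1e6
        fc = np.ones(G)
        fc[:n_sig] = 4.0
        mu = np.column_stack([np.tile(mu_a, (3, 1)).T, np.tile(mu_a * fc, (3, 1)).T])
        r = 1 / 0.1
        y = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(y, index=[f"m{i}" for i in range(G)],
                              columns=[f"s{j}" for j in range(6)])
        X = two_group_design(3)
        fit = NBQLModel(counts, X, offset=np.full(6, np.log(1e6))).fit()
        tab = fit.test(pairwise_contrast(X, "B", "A"))
        sens = (tab.q_value.iloc[:n_sig] < 0.05).mean()
        assert sens >= 0.8

    def test_log2fc_antisymmetric_in_contrast(self):
        rng = np.random.default_rng(32)
        counts = pd.DataFrame(rng.poisson(100, (20, 6)),
                              index=[f"m{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(6)])
        X = two_group_design(3)
        fit = NBQLModel(counts, X, offset=np.zeros(6)).fit(dispersion=0.05)
        ab = fit.test(pairwise_contrast(X, "A", "B"))
        ba = fit.test(pairwise_contrast(X, "B", "A"))
        assert np.allclose(ab.log2fc, -ba.log2fc, atol=1e-9)
        assert np.allclose(ab.p_value, ba.p_value, atol=1e-12)

    def test_agrees_with_anova_at_low_dispersion(self):
        # near-Poisson, large counts: QLF p-values track one-way ANOVA on logs
        rng = np.random.default_rng(33)
        G, k, n = 400, 3, 4
        mu = rng.uniform(5000, 20000, G)
        y = rng.poisson(np.repeat(mu[:, None], k * n, axis=1))
        counts = pd.DataFrame(y, index=[f"m{i}" for i in range(G)],
                              columns=[f"s{j}" for j in range(k * n)])
        X = pd.DataFrame(0.0, index=counts.columns, columns=list("ABC"))
        for g in range(k):
            X.iloc[g * n:(g + 1) * n, g] = 1.0
        fit = NBQLModel(counts, X, offset=np.zeros(k * n)).fit()
        C = np.array([[1.0, -1.0, 0.0], [1.0, 0.0, -1.0]])
        tab = fit.test(C)
        logy = np.log(y)
        f_anova = [stats.f_oneway(*[logy[i, g * n:(g + 1) * n] for g in range(k)]).pvalue
                   for i in range(G)]
        a = (tab.p_value < 0.05).mean()
        b = np.mean(np.array(f_anova) < 0.05)
        assert abs(a - b) < 0.04


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_without_affecting_ranking(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_adjust([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_properties(self, ps):
        q = bh_adjust(ps)
        assert (q <= 1.0 + 1e-12).all()
        assert (q >= np.asarray(ps) - 1e-12).all()  # q >= p
        # order preserving: sorting by p sorts q
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


def test_design_matrix_and_contrast_shapes(small_sim):
    cm, _ = small_sim
    X = design_matrix(cm.samples, by="condition")
    assert X.shape == (42, 14)
    assert (X.sum(axis=1) == 1).all()
    c = pairwise_contrast(X, X.columns[1], X.columns[0])
    assert c.sum() == 0 and np.abs(c).sum() == 2
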