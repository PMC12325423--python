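"""Non-negative PARAFAC: fitting, RSS, CORCONDIA, sweeps, factor matching."""

import numpy as np
import pytest

import bileem as bm
from bileem.errors import DegenerateModelError
from bileem.parafac import ParafacModel


def outer3(a, b, c):
    return np.einsum("i,j,k->ijk", a, b, c)


def brute_force_rss(X, model):
    """Triple-loop reconstruction error (independent of the einsum path)."""
    Xhat = np.zeros_like(X)
    I, J, K = X.shape
    for i in range(I):
        for j in range(J):
            for k in range(K):
                for f in range(model.F):
                    Xhat[i, j, k] += model.A[i, f] * model.B[j, f] * model.C[k, f]
    return float(((X - Xhat) ** 2).sum())


def brute_force_core(X, A, B, C):
    """Least-squares Tucker core by explicit Kronecker normal equations."""
    F = A.shape[1]
    design = np.kron(A, np.kron(B, C))          # vec over (i,j,k), C-order
    g, *_ = np.linalg.lstsq(design, X.ravel(), rcond=None)
    return g.reshape(F, F, F)


class TestFit:
    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(3)
        a, b, c = (rng.uniform(0.5, 2.0, n) for n in (4, 6, 5))
        X = outer3(a, b, c)
        m = bm.fit_parafac(X, 1, bm.FitOptions(n_starts=3, seed=3))
        assert m.rss / (X ** 2).sum() < 1e-10
        assert bm.tucker_congruence(m.A[:, 0], a) > 0.9999
        assert bm.tucker_congruence(m.B[:, 0], b) > 0.9999
        assert bm.tucker_congruence(m.C[:, 0], c) > 0.9999

    def test_all_zero_tensor(self):
        m = bm.fit_parafac(np.zeros((3, 4, 5)), 1, bm.FitOptions(n_starts=2, seed=0))
        assert m.rss == 0.0
        assert np.all(m.A == 0)

    def test_noiseless_rank3_recovery(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(0.2, 2.0, (8, 3))
        B = rng.uniform(0.0, 1.0, (12, 3)) + np.eye(12, 3)  # distinct columns
        C = rng.uniform(0.0, 1.0, (10, 3)) + np.eye(10, 3)
        X = np.einsum("if,jf,kf->ijk", A, B, C)
        m = bm.fit_parafac(X, 3, bm.FitOptions(seed=5))
        assert m.rss / (X ** 2).sum() < 1e-10
        perm_scores = []
        for f in range(3):
            congs = [bm.tucker_congruence(
                np.concatenate([B[:, f] / B[:, f].max(), C[:, f] / C[:, f].max()]),
                np.concatenate([m.B[:, g], m.C[:, g]])) for g in range(3)]
            perm_scores.append(max(congs))
        assert min(perm_scores) > 0.999

    def test_default_synthetic_study_recovery(self, default_fit):
        """3-factor fit of the default noisy study recovers the planted
        Gaussian loadings with congruence > 0.95 per factor."""
        model = default_fit["model"]
        scenario = bm.default_scenario(seed=42)
        em, ex = scenario.emission_grid(), scenario.excitation_grid()
        for fl in scenario.fluorophores:
            bt = bm.gaussian_profile(fl.peak_em, fl.fwhm_em, em)
            ct = bm.gaussian_profile(fl.peak_ex, fl.fwhm_ex, ex)
            congs = [bm.tucker_congruence(
                np.concatenate([bt, ct]),
                np.concatenate([model.B[:, g], model.C[:, g]]))
                for g in range(model.F)]
            assert max(congs) > 0.95, fl.name

    def test_monotone_rss_within_fit(self, default_fit):
        trace = default_fit["model"].rss_trace
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_nonnegativity_enforced(self, default_fit):
        m = default_fit["model"]
        assert m.A.min() >= 0 and m.B.min() >= 0 and m.C.min() >= 0

    def test_loading_columns_unit_max(self, default_fit):
        m = default_fit["model"]
        np.testing.assert_allclose(m.B.max(axis=0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(m.C.max(axis=0), 1.0, rtol=1e-12)

    def test_reconstruction_invariant_to_scaling_convention(self):
        rng = np.random.default_rng(2)
        X = outer3(rng.uniform(1, 2, 3), rng.uniform(1, 2, 4), rng.uniform(1, 2, 5))
        m = bm.fit_parafac(X, 1, bm.FitOptions(n_starts=2, seed=2))
        np.testing.assert_allclose(m.reconstruct(), X, rtol=1e-6)

    def test_nan_tensor_rejected(self):
        X = np.ones((2, 3, 4))
        X[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            bm.fit_parafac(X, 1)

    def test_overfactoring_warns(self):
        with pytest.warns(UserWarning, match="rank-deficient"):
            bm.fit_parafac(np.ones((2, 3, 4)), 3, bm.FitOptions(n_starts=1, seed=0))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = outer3(rng.uniform(1, 2, 3), rng.uniform(1, 2, 4), rng.uniform(1, 2, 5))
        X += rng.normal(0, 0.01, X.shape)
        m1 = bm.fit_parafac(X, 2, bm.FitOptions(n_starts=3, seed=9))
        m2 = bm.fit_parafac(X, 2, bm.FitOptions(n_starts=3, seed=9))
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.B, m2.B)


class TestRss:
    def test_perfect_reconstruction_zero(self):
        a, b, c = np.ones(2), np.ones(3), np.ones(4)
        X = outer3(a, b, c)
        m = ParafacModel(1, a[:, None], b[:, None], c[:, None],
                         np.arange(3.0), np.arange(4.0), 0.0, 1, True, 0)
        assert bm.rss(m, X) == 0.0

    def test_constant_offset_analytic(self):
        a, b, c = np.ones(2), np.ones(3), np.ones(4)
        X = outer3(a, b, c) + 0.5
        m = ParafacModel(1, a[:, None], b[:, None], c[:, None],
                         np.arange(3.0), np.arange(4.0), 0.0, 1, True, 0)
        assert bm.rss(m, X) == pytest.approx(24 * 0.25, rel=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(3, 4, 5))
        m = bm.fit_parafac(X, 2, bm.FitOptions(nonneg=(False, False, False),
                                               n_starts=2, seed=21))
        assert bm.rss(m, X) == pytest.approx(brute_force_rss(X, m), rel=1e-10)
        assert m.rss == pytest.approx(brute_force_rss(X, m), rel=1e-8)


class TestCoreConsistency:
    def test_exact_rank_noiseless_is_100(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0.5, 2.0, (5, 2))
        B = rng.uniform(0.0, 1.0, (6, 2)) + np.eye(6, 2)
        C = rng.uniform(0.0, 1.0, (7, 2)) + np.eye(7, 2)
        X = np.einsum("if,jf,kf->ijk", A, B, C)
        m = bm.fit_parafac(X, 2, bm.FitOptions(seed=4))
        assert bm.core_consistency(m, X) == pytest.approx(100.0, abs=1e-6)

    def test_any_fitted_one_factor_model_is_100(self):
        rng = np.random.default_rng(6)
        X = np.abs(rng.normal(size=(4, 5, 6))) + 0.1   # not rank-1 at all
        m = bm.fit_parafac(X, 1, bm.FitOptions(n_starts=2, seed=6))
        assert bm.core_consistency(m, X) == pytest.approx(100.0, abs=1e-8)

    def test_matches_brute_force_core_on_2x2x2(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(0.5, 1.5, (2, 2))
        B = rng.uniform(0.5, 1.5, (2, 2))
        C = rng.uniform(0.5, 1.5, (2, 2))
        X = np.einsum("if,jf,kf->ijk", A, B, C)
        X = X + rng.normal(0, 0.05, X.shape)   # non-trilinear perturbation
        m = ParafacModel(2, A, B, C, np.arange(2.0), np.arange(2.0),
                         0.0, 1, True, 0)
        core = brute_force_core(X, A, B, C)
        target = np.zeros((2, 2, 2))
        target[[0, 1], [0, 1], [0, 1]] = 1.0
        expected = 100.0 * (1.0 - ((core - target) ** 2).sum() / 2.0)
        assert bm.core_consistency(m, X) == pytest.approx(expected, rel=1e-9)

    def test_degenerate_loadings_error(self):
        A = np.ones((3, 2))   # rank 1 < F=2
        m = ParafacModel(2, A, A.copy(), A.copy(), np.arange(3.0),
                         np.arange(3.0), 0.0, 1, True, 0)
        with pytest.raises(DegenerateModelError):
            bm.core_consistency(m, np.ones((3, 3, 3)))


class TestModelSweep:
    def test_single_f_sweep(self):
        X = outer3(np.ones(2), np.ones(3), np.ones(4))
        table = bm.model_sweep(X, range(1, 2), bm.FitOptions(n_starts=1, seed=0))
        assert len(table) == 1 and table["F"].iloc[0] == 1

    def test_noiseless_3factor_sweep_structure(self):
        scenario = bm.default_scenario(seed=13, noise_sd=0.0,
                                       inner_filter=False, blank_amplitude=0.0,
                                       ridge_amplitudes={})
        study = bm.make_study(scenario)
        from conftest import thin_limit_tensor

        tensor, _ = thin_limit_tensor(study, processed=study["eems"])
        table = bm.model_sweep(tensor, range(1, 5),
                               bm.FitOptions(n_starts=4, seed=13))
        rel = table["rss"] / (tensor.values ** 2).sum()
        assert rel.iloc[2] < 1e-8                   # rss ~ 0 at true F=3
        cc = table["core_consistency"]
        assert cc.iloc[3] < cc.iloc[2] or np.isnan(cc.iloc[3])  # overfactoring drop

    def test_sweep_cc_above_70_at_true_f(self, default_fit):
        cc = bm.core_consistency(default_fit["model"], default_fit["tensor"])
        assert cc >= 70.0


class TestMatchFactors:
    def test_self_match_identity(self, default_fit):
        perm, scores = bm.match_factors(default_fit["model"], default_fit["model"])
        np.testing.assert_array_equal(perm, np.arange(default_fit["model"].F))
        np.testing.assert_allclose(scores, 1.0, rtol=1e-12)

    def test_permuted_copy_recovered(self, default_fit):
        import dataclasses

        m = default_fit["model"]
        p = np.array([2, 0, 1])
        shuffled = dataclasses.replace(
            m, A=m.A[:, p], B=m.B[:, p], C=m.C[:, p])
        perm, scores = bm.match_factors(m, shuffled)
        # perm[f] locates factor f of m inside the shuffled model
        np.testing.assert_array_equal(p[perm], np.arange(3))
        np.testing.assert_allclose(scores, 1.0, rtol=1e-12)

    def test_shifted_gaussian_congruence_matches_closed_form(self):
        em = np.arange(250.0, 601.0, 5.0)
        ex = np.arange(190.0, 401.0, 5.0)
        b1 = bm.gaussian_profile(360.0, 55.0, em)
        c1 = bm.gaussian_profile(225.0, 40.0, ex)
        b2 = bm.gaussian_profile(370.0, 55.0, em)
        c2 = bm.gaussian_profile(235.0, 40.0, ex)
        ma = ParafacModel(1, np.ones((2, 1)), b1[:, None], c1[:, None],
                          em, ex, 0.0, 1, True, 0)
        mb = ParafacModel(1, np.ones((2, 1)), b2[:, None], c2[:, None],
                          em, ex, 0.0, 1, True, 0)
        _, scores = bm.match_factors(ma, mb)
        u = np.concatenate([b1, c1])
        v = np.concatenate([b2, c2])
        direct = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        assert scores[0] == pytest.approx(direct, rel=1e-12)


class TestPeakLocation:
    def test_planted_peaks(self, default_fit):
        peaks = {bm.peak_location(default_fit["model"], f + 1)
                 for f in range(3)}
        assert (225.0, 360.0) in peaks     # tryptophan-like factor
        assert (345.0, 410.0) in peaks     # PIO-dominant factor

    def test_constant_loading_tie_breaks_to_lowest_wavelength(self):
        em = np.array([300.0, 350.0, 400.0])
        ex = np.array([200.0, 250.0])
        m = ParafacModel(1, np.ones((2, 1)), np.ones((3, 1)), np.ones((2, 1)),
                         em, ex, 0.0, 1, True, 0)
        assert bm.peak_location(m, 1) == (200.0, 300.0)

    def test_bad_factor_index(self, default_fit):
        with pytest.raises(ValueError):
            bm.peak_location(default_fit["model"], 0)


class TestScoreProportionality:
    def test_thin_limit_scores_proportional_to_concentration(self, clean_linear_fit):
        """With no noise and no inner filter, fitted scores regress through
        the origin onto true concentration x DF within 2%."""
        model = clean_linear_fit["model"]
        records = clean_linear_fit["records"]
        scenario_sources = {s.source_id: s for s in
                            bm.default_scenario().sources}
        # map fitted factors to fluorophores via peak location
        peak_to_name = {(225.0, 360.0): "trp", (270.0, 450.0): "f2",
                        (345.0, 410.0): "f3"}
        for f in range(model.F):
            name = peak_to_name[bm.peak_location(model, f + 1)]
            truth = np.array([
                scenario_sources[r.source_pool_id].concentrations[name] * r.df
                for r in records])
            fitted = model.A[:, f]
            slope = (truth @ fitted) / (truth @ truth)
            np.testing.assert_allclose(fitted, slope * truth,
                                       atol=2e-2 * fitted.max())
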