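"""Partial correlation, graphical lasso, λ selection, calibration, FDR."""

import numpy as np
import pytest
from scipy import stats

from leakmend import envelope as env
from leakmend import netinfer as ni
from leakmend import simulate as sim
from leakmend.errors import ParameterError

from _oracles import blackbox_glasso, partial_corr_by_residualisation


class TestPartialCorrelation:
    def test_identity_precision_gives_no_edges(self):
        rho = ni.partial_correlation(np.eye(4))
        assert np.allclose(rho, np.eye(4))

    def test_two_by_two_closed_form(self):
        rho = ni.partial_correlation(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        assert abs(rho[0, 1] - 0.5) < 1e-12

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_residualisation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(5, 12))
        S = A @ A.T / 12 + 0.5 * np.eye(5)
        rho = ni.partial_correlation(np.linalg.inv(S))
        assert np.abs(rho - partial_corr_by_residualisation(S)).max() < 1e-8

    def test_chain_precision_zeros_mean_conditional_independence(self):
        # 3-variable chain x1 - x2 - x3: precision has a zero at (1,3)
        S = np.array([[1.0, 0.6, 0.36], [0.6, 1.0, 0.6], [0.36, 0.6, 1.0]])
        rho = ni.partial_correlation(np.linalg.inv(S))
        assert abs(rho[0, 2]) < 1e-10

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ParameterError):
            ni.partial_correlation(np.diag([1.0, -1.0]))


class TestGraphicalLasso:
    def test_unpenalised_is_inverse_covariance(self, rng):
        A = rng.normal(size=(5, 30))
        S = A @ A.T / 30
        om = ni.graphical_lasso(S, 0.0)
        assert np.abs(om - np.linalg.inv(S)).max() < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_large_lambda_empties_offdiagonals(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 20))
        S = np.corrcoef(A)
        lam = np.abs(S - np.diag(np.diag(S))).max()
        om = ni.graphical_lasso(S, lam + 1e-6)
        assert np.abs(om - np.diag(np.diag(om))).max() == 0.0

    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("penalize_diagonal", [True, False])
    def test_objective_matches_blackbox_optimiser(self, seed, penalize_diagonal):
        rng = np.random.default_rng(100 + seed)
        A = rng.normal(size=(4, 8))
        S = np.corrcoef(A)
        for lam in (0.05, 0.2):
            mine = ni.graphical_lasso(S, lam, penalize_diagonal=penalize_diagonal)
            orac = blackbox_glasso(S, lam, penalize_diagonal=penalize_diagonal)
            f1 = ni.glasso_objective(mine, S, lam, penalize_diagonal)
            f2 = ni.glasso_objective(orac, S, lam, penalize_diagonal)
            assert abs(f1 - f2) < 1e-6

    def test_matches_sklearn_without_diagonal_penalty(self, rng):
        from sklearn.covariance import graphical_lasso as sk_glasso

        A = rng.normal(size=(200, 4))
        S = np.cov(A, rowvar=False)
        _, sk_prec = sk_glasso(S, alpha=0.1)
        mine = ni.graphical_lasso(S, 0.1, penalize_diagonal=False)
        gap = ni.glasso_objective(mine, S, 0.1, False) - ni.glasso_objective(
            sk_prec, S, 0.1, False
        )
        assert gap < 1e-6  # at least as good as sklearn's solution

    @pytest.mark.parametrize("seed", range(3))
    def test_support_shrinks_monotonically_in_lambda(self, seed):
        rng = np.random.default_rng(seed)
        S = np.corrcoef(rng.normal(size=(4, 10)))
        prev = None
        for lam in np.geomspace(1e-3, 1.0, 12):
            om = ni.graphical_lasso(S, lam)
            supp = {tuple(ij) for ij in np.argwhere(np.triu(om, 1) != 0)}
            if prev is not None:
                assert supp.issubset(prev)
            prev = supp

    def test_singular_covariance_needs_penalty(self):
        S = np.ones((3, 3))
        with pytest.raises(ParameterError):
            ni.graphical_lasso(S, 0.0)
        om = ni.graphical_lasso(S, 0.1)
        assert np.linalg.eigvalsh(om).min() > 0


class TestSelectLambda:
    def test_zero_refinements_returns_grid_member(self, rng):
        X = rng.normal(size=(200, 5))
        grid = np.geomspace(1e-4, 1.0, 16)
        lam = ni.select_lambda(X, folds=5, refinements=0)
        assert np.any(np.isclose(grid, lam))

    def test_white_noise_selects_sparse_regime(self):
        grid = np.geomspace(1e-4, 1.0, 16)
        picks = []
        for seed in (5, 6, 7):
            X = np.random.default_rng(seed).normal(size=(400, 8))
            lam = ni.select_lambda(X, folds=10, refinements=0)
            picks.append(int(np.argmin(np.abs(grid - lam))))
        # independent envelopes: the chosen strength sits in the sparsest
        # (upper) third of the initial grid
        assert np.median(picks) >= 11

    def test_recovers_true_support_on_networked_data(self):
        # strongly networked simulated envelopes: chosen λ keeps every true edge
        edges = ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4))
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            b = sim.simulate_bundle(
                n_nodes=8, duration=300.0, sampling_rate=100.0, edges=edges,
                networked_nodes=[0, 2, 4, 5, 7], snr=4.0, spread=0.5, seed=900 + seed,
            )
            Xb = env.bandpass(b.observed, 100.0, (4, 30))
            E = env.envelope_pipeline(Xb, 100.0)
            lam = ni.select_lambda(E.values, folds=10, refinements=2)
            om = ni.graphical_lasso(np.corrcoef(E.values, rowvar=False), lam)
            supp = {tuple(sorted(ij)) for ij in np.argwhere(np.triu(om, 1) != 0)}
            truth = {tuple(sorted(e)) for e in b.truth.edges}
            hits += truth.issubset(supp)
        assert hits >= int(0.9 * n_seeds)

    def test_too_few_samples_per_fold_rejected(self, rng):
        with pytest.raises(ParameterError):
            ni.select_lambda(rng.normal(size=(30, 4)), folds=10)


class TestFisherZ:
    def test_values_and_antisymmetry(self):
        assert ni.fisher_z(0.0) == 0.0
        assert round(ni.fisher_z(0.5), 4) == 0.5493
        r = 0.73
        assert ni.fisher_z(-r) == -ni.fisher_z(r)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            ni.fisher_z(1.0)


class TestNullScaling:
    def test_calibrates_held_out_null_draws(self):
        sd = ni.null_scaling(8, 500, 0.6, metric="full", n_null=50, seed=3)
        iu = np.triu_indices(8, 1)
        pooled = []
        for child in np.random.SeedSequence(77).spawn(30):
            X = sim.ar1_null(8, 500, 0.6, seed=child)
            pooled.append(np.arctanh(np.corrcoef(X, rowvar=False)[iu]))
        ratio = np.concatenate(pooled).std() / sd
        assert 0.9 < ratio < 1.1

    def test_smoothness_inflates_null_spread(self):
        hi = ni.null_scaling(8, 500, 0.9, n_null=50, seed=1)
        lo = ni.null_scaling(8, 500, 0.0, n_null=50, seed=1)
        assert hi > lo

    def test_more_samples_concentrate_the_null(self):
        short = ni.null_scaling(8, 500, 0.5, n_null=50, seed=2)
        long = ni.null_scaling(8, 2000, 0.5, n_null=50, seed=2)
        assert long < short

    def test_full_pipeline_false_positive_rate_is_nominal(self):
        # AR(1) data with no mixing, pushed through band-limit/envelope and
        # calibrated: the 5% one-sided detection rate stays nominal
        fprs = []
        null_sd = None
        for child in np.random.SeedSequence(123).spawn(50):
            X = sim.ar1_null(8, 6000, 0.3, seed=child)
            E = env.envelope_pipeline(X, 50.0, band=(4, 20))
            if null_sd is None:
                null_sd = ni.null_scaling(
                    8, E.n_samples, ni.lag1_autocorrelation(E.values),
                    metric="full", n_null=50, seed=9,
                )
            R = np.corrcoef(E.values, rowvar=False)
            z = np.arctanh(np.clip(R[np.triu_indices(8, 1)], -0.99, 0.99)) / null_sd
            fprs.append(np.mean(z > stats.norm.isf(0.05)))
        n_edges = 50 * 28
        lo, hi = stats.binom.ppf([0.025, 0.975], n_edges, 0.05) / n_edges
        assert lo <= np.mean(fprs) <= hi


class TestGroupFixedEffects:
    def test_zero_subjects_give_zero_group(self):
        z = ni.group_fixed_effects([np.zeros((4, 4))] * 3)
        assert np.allclose(z.z, 0.0) and z.n_subjects == 3

    def test_identical_subjects_scale_by_sqrt_s(self, rng):
        m = rng.normal(size=(5, 5))
        m = m + m.T
        np.fill_diagonal(m, 0)
        z = ni.group_fixed_effects([m] * 4)
        assert np.allclose(z.z, 2.0 * m)

    def test_null_subjects_stay_standard_normal(self, rng):
        n, S, reps = 10, 8, 40
        iu = np.triu_indices(n, 1)
        pooled = []
        for _ in range(reps):
            mats = []
            for _ in range(S):
                m = np.zeros((n, n))
                vals = rng.normal(size=len(iu[0]))
                m[iu] = vals
                m = m + m.T
                mats.append(m)
            pooled.append(ni.group_fixed_effects(mats).z[iu])
        sd = np.concatenate(pooled).std()
        assert 0.85 < sd < 1.15


class TestFdrThreshold:
    def test_benjamini_hochberg_worked_example(self):
        # edge p-values {0.001, 0.02, 0.04, 0.8} at q=0.05:
        # largest i with p(i) <= i*q/4 is i=2, so exactly 2 rejections
        p = np.array([0.001, 0.02, 0.04, 0.8])
        z = stats.norm.isf(p)
        thr, reject = ni.fdr_threshold(z, q=0.05)
        assert reject.tolist() == [True, True, False, False]
        assert np.isclose(thr, stats.norm.isf(0.02))

    def test_matrix_input_matches_flat_input(self, rng):
        n = 5
        iu = np.triu_indices(n, 1)
        flat = rng.normal(size=len(iu[0])) + 1.0
        z = np.zeros((n, n))
        z[iu] = flat
        z = z + z.T
        thr_m, mask = ni.fdr_threshold(z, q=0.1)
        thr_f, reject = ni.fdr_threshold(flat, q=0.1)
        assert thr_m == thr_f
        assert np.array_equal(mask[iu], reject)

    def test_no_signal_no_rejections(self):
        z = np.zeros((5, 5))
        thr, mask = ni.fdr_threshold(z, q=0.05)
        assert not mask.any() and np.isinf(thr)

    def test_overwhelming_signal_keeps_everything(self):
        z = np.full((5, 5), 10.0)
        np.fill_diagonal(z, 0.0)
        _, mask = ni.fdr_threshold(z, q=0.05)
        iu = np.triu_indices(5, 1)
        assert mask[iu].all()


class TestNetworkEstimate:
    def test_metrics_are_consistent(self, rng):
        X = rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5))
        est_full = ni.network_estimate(X, metric="full")
        est_part = ni.network_estimate(X, metric="partial")
        # full metric exposes the correlation matrix
        assert np.allclose(np.diag(est_full.covariance), 1.0)
        assert np.allclose(
            ni.edge_values(est_part),
            ni.partial_correlation(np.linalg.inv(est_full.covariance)),
            atol=1e-10,
        )

    def test_regularised_fixed_lambda(self, rng):
        X = rng.normal(size=(200, 4))
        est = ni.network_estimate(X, metric="partial_regularised", lambda_=0.3)
        assert est.lambda_ == 0.3
        off = est.partial_correlation - np.diag(np.diag(est.partial_correlation))
        assert np.count_nonzero(off) <= 2  # strongly sparsified
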