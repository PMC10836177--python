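import numpy as np
import pytest

from stcar.stcar_model import (
    McmcConfig,
    PosteriorSamples,
    ar1_precision,
    convergence_report,
    fit_criteria,
    gelman_rubin,
    geweke,
    leroux_precision,
    load_samples,
    sample_posterior,
    save_samples,
    update_tau2,
)
from stcar.synthetic_region import make_lattice, simulate_design, simulate_panel_counts

# quick MCMC profile used for structural checks (not inference quality)
TINY = McmcConfig(n_iter=400, burn_in=100, thin=1, n_chains=2, seed=5)


def tiny_problem(seed=0, K_side=4, T=4, tau2=0.1):
    _, W = make_lattice(K_side, K_side)
    K = K_side**2
    X = simulate_design(K, T, W, 1, seed=seed)
    E = np.full((K, T), 8.0)
    Y, truth = simulate_panel_counts(
        np.array([0.0, 0.4]), 0.6, 0.7, tau2, E, X, W, seed=seed
    )
    return Y, E, X, W, truth


class TestLerouxPrecision:
    def test_independence_limit_is_identity(self, lattice_4x4):
        _, W = lattice_4x4
        np.testing.assert_allclose(leroux_precision(W, 0.0), np.eye(16))

    def test_intrinsic_limit_has_zero_row_sums(self, lattice_4x4):
        _, W = lattice_4x4
        Q = leroux_precision(W, 1.0)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_two_node_graph_hand_computation(self):
        W = np.array([[0, 1], [1, 0]])
        np.testing.assert_allclose(
            leroux_precision(W, 0.5), [[1.0, -0.5], [-0.5, 1.0]]
        )

    def test_positive_definite_below_one(self, lattice_4x4):
        _, W = lattice_4x4
        for rho in (0.0, 0.5, 0.99):
            assert np.linalg.eigvalsh(leroux_precision(W, rho)).min() > 0

    def test_rho_out_of_range_rejected(self, lattice_4x4):
        _, W = lattice_4x4
        with pytest.raises(ValueError):
            leroux_precision(W, 1.5)


class TestAr1Precision:
    def test_unit_determinant_for_any_rho(self):
        for rho in (0.0, 0.5, 0.95):
            assert np.linalg.det(ar1_precision(6, rho)) == pytest.approx(1.0)

    def test_quadratic_form_matches_kronecker_construction(self, lattice_4x4):
        # the sampler's sufficient statistics assume vec(psi) has precision
        # M kron Q; verify against the explicit Kronecker product
        from stcar.stcar_model import _quadforms

        _, W = lattice_4x4
        rng = np.random.default_rng(0)
        Q = leroux_precision(W, 0.6)
        T, K = 5, 16
        M = ar1_precision(T, 0.8)
        psi = rng.normal(size=(K, T))
        v = psi.T.ravel()  # time-major vec
        expected = v @ np.kron(M, Q) @ v
        assert _quadforms(psi, Q, 0.8) == pytest.approx(expected, rel=1e-12)


class TestTau2Update:
    def test_zero_psi_reduces_to_prior(self):
        rng = np.random.default_rng(1)
        Q = np.eye(4)
        psi = np.zeros((4, 3))
        draws = [update_tau2(psi, Q, 0.5, a=1.0, b=0.01, rng=rng) for _ in range(4000)]
        # IG(1 + 6, 0.01): mean = 0.01/6
        assert np.mean(draws) == pytest.approx(0.01 / 6, rel=0.1)

    def test_long_run_mean_matches_closed_form(self, lattice_4x4):
        _, W = lattice_4x4
        rng = np.random.default_rng(2)
        Q = leroux_precision(W, 0.7)
        psi = rng.normal(size=(16, 5))
        from stcar.stcar_model import _quadforms

        ss = _quadforms(psi, Q, 0.8)
        a_post = 1.0 + 16 * 5 / 2
        b_post = 0.01 + ss / 2
        draws = [update_tau2(psi, Q, 0.8, rng=rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(b_post / (a_post - 1), rel=0.05)

    def test_nonnegative_quadratic_form(self, lattice_4x4):
        _, W = lattice_4x4
        from stcar.stcar_model import _quadforms

        Q = leroux_precision(W, 0.9)
        rng = np.random.default_rng(3)
        for _ in range(50):
            psi = rng.normal(size=(16, 4))
            assert _quadforms(psi, Q, rng.uniform(0, 0.99)) >= 0


class TestSampler:
    def test_same_seed_reproduces_samples_exactly(self):
        Y, E, X, W, _ = tiny_problem(seed=4)
        s1 = sample_posterior(Y, E, X, W, TINY)
        s2 = sample_posterior(Y, E, X, W, TINY)
        np.testing.assert_array_equal(s1.stacked("beta"), s2.stacked("beta"))
        np.testing.assert_array_equal(s1.stacked("psi"), s2.stacked("psi"))
        np.testing.assert_array_equal(s1.stacked("tau2"), s2.stacked("tau2"))

    def test_retained_draw_count_and_supports(self):
        Y, E, X, W, _ = tiny_problem(seed=5)
        s = sample_posterior(Y, E, X, W, TINY)
        assert s.stacked("beta").shape == (2 * TINY.n_keep, 2)
        assert (s.stacked("tau2") > 0).all()
        for name in ("rho_S", "rho_T"):
            d = s.stacked(name)
            assert ((d > 0) & (d < 1)).all()

    def test_acceptance_rates_in_tuned_band(self):
        Y, E, X, W, _ = tiny_problem(seed=6)
        cfg = McmcConfig(n_iter=2000, burn_in=1000, thin=1, n_chains=1, seed=9)
        s = sample_posterior(Y, E, X, W, cfg)
        for rates in s.acceptance:
            for block, r in rates.items():
                assert 0.2 <= r <= 0.6, f"{block} acceptance {r}"

    def test_island_adjacency_rejected(self):
        from stcar.geo_io import AdjacencyMatrix

        W = AdjacencyMatrix(n=2, W=np.zeros((2, 2), int), area_ids=("a", "b"))
        Y = np.ones((2, 2))
        E = np.ones((2, 2))
        X = np.ones((2, 2, 1))
        with pytest.raises(ValueError, match="island"):
            sample_posterior(Y, E, X, W, TINY)

    def test_prior_recovery_with_negligible_data(self):
        # E -> 0 removes the likelihood, so rho_S, rho_T should look U(0,1).
        # The prior-only regime mixes slowly (rho moves only through psi's
        # correlation structure), hence the long chain for stable moments.
        _, W = make_lattice(4, 4)
        K, T = 16, 4
        X = np.ones((K, T, 1))
        Y = np.zeros((K, T))
        E = np.full((K, T), 1e-8)
        cfg = McmcConfig(n_iter=40_000, burn_in=6_000, thin=1, n_chains=2, seed=11)
        s = sample_posterior(Y, E, X, W, cfg)
        for name in ("rho_S", "rho_T"):
            d = s.stacked(name)
            assert d.mean() == pytest.approx(0.5, abs=0.1)
            assert d.var() == pytest.approx(1 / 12, abs=0.035)

    def test_save_load_round_trip(self, tmp_path):
        Y, E, X, W, _ = tiny_problem(seed=7)
        s = sample_posterior(Y, E, X, W, TINY)
        p = tmp_path / "draws.npz"
        save_samples(s, p)
        back = load_samples(p)
        assert back.beta_names == s.beta_names
        np.testing.assert_array_equal(back.stacked("psi"), s.stacked("psi"))
        assert back.acceptance[0].keys() == s.acceptance[0].keys()


class TestDiagnostics:
    def test_iid_chains_have_rhat_near_one(self):
        rng = np.random.default_rng(12)
        chains = rng.normal(size=(2, 10_000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(13)
        chains = rng.normal(size=(2, 1000))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 1.1

    def test_single_chain_is_an_error(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_geweke_iid_chain_is_calibrated(self):
        zs = [geweke(np.random.default_rng(s).normal(size=10_000)) for s in range(20)]
        assert np.mean(np.abs(np.array(zs)) <= 2) >= 0.9

    def test_geweke_flags_trend(self):
        x = np.linspace(0, 5, 5000) + np.random.default_rng(14).normal(size=5000)
        assert abs(geweke(x)) > 2

    def test_geweke_zero_for_mirror_segments(self):
        # periodic chain: the first 10% and last 50% are copies of the same
        # segment, so the segment means agree exactly and z = 0
        seg = np.random.default_rng(15).normal(size=1000)
        x = np.tile(seg, 10)
        assert geweke(x) == pytest.approx(0.0, abs=1e-9)

    def test_too_short_chain_is_an_error(self):
        with pytest.raises(ValueError):
            geweke(np.arange(20.0))

    def test_convergence_report_lists_all_scalars(self):
        Y, E, X, W, _ = tiny_problem(seed=8)
        s = sample_posterior(Y, E, X, W, McmcConfig(
            n_iter=1500, burn_in=300, thin=1, n_chains=2, seed=21))
        rep = convergence_report(s)
        assert set(rep.table["parameter"]) == {
            "beta[b0]", "beta[b1]", "tau2", "rho_S", "rho_T"
        }


class TestFitCriteria:
    def _samples_from_arrays(self, beta, psi, names=("b0",)):
        n = beta.shape[0]
        return PosteriorSamples(
            beta=[beta], psi=[psi], tau2=[np.ones(n)],
            rho_S=[np.full(n, 0.5)], rho_T=[np.full(n, 0.5)],
            beta_names=names, acceptance=[{}],
        )

    def test_dic_identity(self):
        Y, E, X, W, _ = tiny_problem(seed=9)
        s = sample_posterior(Y, E, X, W, TINY)
        fit = fit_criteria(s, Y, E, X)
        # DIC = Dbar + p_D and also D(thetabar) + 2 p_D
        dbar = fit.dic - fit.p_d
        dhat = dbar - fit.p_d
        assert fit.dic == pytest.approx(dhat + 2 * fit.p_d, abs=1e-9)

    def test_degenerate_posterior_has_zero_penalties(self):
        K, T = 4, 3
        rng = np.random.default_rng(16)
        Y = rng.poisson(5.0, size=(K, T)).astype(float)
        E = np.full((K, T), 5.0)
        X = np.ones((K, T, 1))
        beta = np.zeros((200, 1))
        psi = np.zeros((200, K, T))
        s = self._samples_from_arrays(beta, psi)
        fit = fit_criteria(s, Y, E, X)
        assert fit.p_d == pytest.approx(0.0, abs=1e-9)
        assert fit.p_waic == pytest.approx(0.0, abs=1e-12)

    def test_generating_model_beats_intercept_only(self):
        # the model that generated the data should win on DIC most of the time
        wins = 0
        reps = 6
        for r in range(reps):
            _, W = make_lattice(4, 4)
            X = simulate_design(16, 4, W, 1, seed=100 + r)
            E = np.full((16, 4), 10.0)
            Y, _ = simulate_panel_counts(
                np.array([0.0, 0.8]), 0.5, 0.5, 0.05, E, X, W, seed=200 + r
            )
            cfg = McmcConfig(n_iter=1500, burn_in=500, thin=1, n_chains=1, seed=r)
            full = fit_criteria(sample_posterior(Y, E, X, W, cfg), Y, E, X)
            X0 = X[:, :, :1]
            null = fit_criteria(sample_posterior(Y, E, X0, W, cfg), Y, E, X0)
            wins += full.dic < null.dic
        assert wins >= reps - 1
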