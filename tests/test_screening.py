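import numpy as np
import pandas as pd
import pytest

from stcar.geo_io import AdjacencyMatrix, AreaYearPanel, PanelSchema
from stcar.screening import (
    fit_poisson_glm,
    moran_by_year,
    morans_i,
    residuals_by_year,
    vif,
)
from stcar.stcar_model import leroux_precision, sample_car_field
from stcar.synthetic_region import make_lattice

from conftest import make_toy_panel


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------

def vif_oracle(M):
    """Direct 1/(1-R^2) via numpy lstsq, independent of statsmodels."""
    out = []
    for j in range(M.shape[1]):
        y = M[:, j]
        X = np.column_stack([np.ones(len(y)), np.delete(M, j, axis=1)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        out.append(np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2))
    return np.array(out)


def moran_oracle(x, W, row_standardize=True):
    """O(n^2) double-loop Moran's I."""
    x = np.asarray(x, float)
    n = x.size
    W = np.asarray(W, float).copy()
    if row_standardize:
        for i in range(n):
            s = W[i].sum()
            if s > 0:
                W[i] = W[i] / s
    z = x - x.mean()
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            S0 += W[i, j]
    return n / S0 * num / (z @ z)


# ---------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------

class TestVif:
    def test_orthogonal_centered_covariates_have_unit_vif(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(64, 3))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        rep = vif(Q)
        np.testing.assert_allclose(rep.table["vif"], 1.0, atol=1e-9)
        assert not rep.any_flagged

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        rep = vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(rep.table["vif"].iloc[0])
        assert rep.table["flagged"].iloc[0]

    def test_known_correlation_gives_closed_form_vif(self):
        # two covariates with empirical correlation exactly 0.6
        rng = np.random.default_rng(2)
        A = rng.normal(size=(200, 2))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        u, v = Q[:, 0], Q[:, 1]
        x2 = 0.6 * u + np.sqrt(1 - 0.36) * v
        rep = vif(np.column_stack([u, x2]))
        np.testing.assert_allclose(rep.table["vif"], 1.5625, rtol=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_independent_lstsq_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(80, 4)) @ rng.normal(size=(4, 4))
        np.testing.assert_allclose(
            vif(M).table["vif"].to_numpy(), vif_oracle(M), rtol=1e-9
        )

    def test_names_come_from_dataframe(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["ipdm", "phc"])
        assert vif(df).table["covariate"].tolist() == ["ipdm", "phc"]


# ---------------------------------------------------------------------
# Poisson GLM
# ---------------------------------------------------------------------

class TestPoissonGlm:
    def test_intercept_only_closed_form(self, toy_panel):
        E = np.full(len(toy_panel.data), 5.0)
        fit = fit_poisson_glm(toy_panel, covariates=[], expected=E)
        O = toy_panel.data["deaths"].sum()
        assert fit.params["intercept"] == pytest.approx(np.log(O / E.sum()), abs=1e-8)

    def test_recovers_simulated_coefficients_within_three_se(self):
        rng = np.random.default_rng(8)
        K, T = 200, 10  # 2,000 records
        df = make_toy_panel(K=K, T=T, seed=8)
        x1 = rng.normal(size=K * T)
        x2 = rng.normal(size=K * T)
        E = np.full(K * T, 10.0)
        beta = (0.3, -0.2)
        mu = E * np.exp(0.1 + beta[0] * x1 + beta[1] * x2)
        df["deaths"] = rng.poisson(mu)
        df["ipdm"] = (x1 - x1.min()) / (x1.max() - x1.min())  # keep schema happy
        df["cov1"] = x1
        df["cov2"] = x2
        panel = AreaYearPanel(df, PanelSchema())
        fit = fit_poisson_glm(panel, covariates=["cov1", "cov2"], expected=E)
        for name, true in zip(("cov1", "cov2"), beta):
            assert abs(fit.params[name] - true) < 3 * fit.bse[name]

    def test_constant_zero_column_is_rank_deficient(self, toy_panel):
        df = toy_panel.data.copy()
        df["dead_col"] = 0.0
        panel = AreaYearPanel(df, toy_panel.schema)
        with pytest.raises(ValueError, match="rank"):
            fit_poisson_glm(panel, covariates=["ipdm", "dead_col"],
                            expected=np.full(len(df), 5.0))

    def test_nonpositive_expected_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="positive"):
            fit_poisson_glm(toy_panel, ["ipdm"], expected=np.zeros(len(toy_panel.data)))


class TestResiduals:
    def test_zero_when_observed_equals_fitted(self, toy_panel):
        fit = fit_poisson_glm(
            toy_panel, [], expected=toy_panel.data["deaths"].to_numpy().astype(float) + 0.0001
        )
        # intercept-only with offset=log(O) fits mu ~= O
        assert np.allclose(fit.pearson_resid, 0.0, atol=0.02)

    def test_pearson_arithmetic_and_grouping(self, toy_panel):
        fit = fit_poisson_glm(toy_panel, ["ipdm"], expected=np.full(len(toy_panel.data), 5.0))
        by_year = residuals_by_year(fit)
        assert sorted(by_year) == toy_panel.years
        for vec in by_year.values():
            assert vec.shape == (toy_panel.n_areas,)
        manual = (toy_panel.data["deaths"].to_numpy() - fit.fitted) / np.sqrt(fit.fitted)
        np.testing.assert_allclose(np.sort(np.concatenate(list(by_year.values()))),
                                   np.sort(manual), rtol=1e-9)


# ---------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------

class TestMoran:
    def test_constant_vector_is_an_error(self, lattice_4x4):
        _, W = lattice_4x4
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(16), W, seed=0)

    def test_checkerboard_on_rook_lattice_is_negative(self):
        n = 4
        W = np.zeros((16, 16), int)
        for iy in range(n):
            for ix in range(n):
                k = iy * n + ix
                for dx, dy in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
                    jx, jy = ix + dx, iy + dy
                    if 0 <= jx < n and 0 <= jy < n:
                        W[k, jy * n + jx] = 1
        x = np.array([(ix + iy) % 2 for iy in range(n) for ix in range(n)], float)
        res = morans_i(x, W, seed=1)
        assert res.I < 0
        assert res.I == pytest.approx(moran_oracle(x, W), abs=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_brute_force_double_loop(self, seed, lattice_4x4):
        _, W = lattice_4x4
        x = np.random.default_rng(seed).normal(size=16)
        res = morans_i(x, W, n_perm=19, seed=seed)
        assert res.I == pytest.approx(moran_oracle(x, W.W), abs=1e-12)

    def test_smooth_car_field_detected_as_autocorrelated(self):
        _, W = make_lattice(10, 10)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Q = leroux_precision(W, 0.999)
            x = sample_car_field(Q, 1.0, rng)
            res = morans_i(x, W, n_perm=199, seed=seed)
            hits += res.I > 0 and res.p_value <= 0.05
        assert hits >= 9

    def test_permutation_null_mean_is_minus_one_over_n_minus_one(self, lattice_4x4):
        _, W = lattice_4x4
        rng = np.random.default_rng(3)
        sims = [
            morans_i(rng.permutation(np.arange(16.0)), W, n_perm=9, seed=s).I
            for s in range(400)
        ]
        assert np.mean(sims) == pytest.approx(-1 / 15, abs=0.02)

    def test_moran_by_year_table_shape(self, lattice_4x4):
        _, W = lattice_4x4
        rng = np.random.default_rng(4)
        vals = {2010 + t: rng.normal(size=16) for t in range(3)}
        tab = moran_by_year(vals, W, n_perm=49, seed=0)
        assert tab["year"].tolist() == [2010, 2011, 2012]
        assert ((tab["p_value"] > 0) & (tab["p_value"] <= 1)).all()
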