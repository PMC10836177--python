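"""Exploratory screening: collinearity, Poisson log-linear regression, and
yearly spatial autocorrelation of model residuals.

The screening stage mirrors standard disease-mapping practice: covariates are
gated on the variance inflation factor (flagged above 5), a Poisson GLM with a
log-expected-counts offset gives frequentist effect estimates, and Moran's I
with a permutation test — computed year by year on the Pearson residuals —
checks for leftover spatial structure that motivates the CAR model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geo_io import AdjacencyMatrix, AreaYearPanel

__all__ = [
    "VifReport",
    "GlmFit",
    "MoranResult",
    "vif",
    "fit_poisson_glm",
    "residuals_by_year",
    "morans_i",
    "moran_by_year",
]

VIF_THRESHOLD = 5.0


@dataclass(frozen=True)
class VifReport:
    table: pd.DataFrame  # columns: covariate, vif, flagged

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "covariate"].tolist()

    @property
    def any_flagged(self) -> bool:
        return bool(self.table["flagged"].any())


def vif(X: pd.DataFrame | np.ndarray, threshold: float = VIF_THRESHOLD) -> VifReport:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from an intercept-included least-squares regression of
    covariate j on the remaining covariates. Exact collinearity is reported
    as an infinite, flagged VIF rather than raising.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise ValueError("VIF needs at least two covariates")
    if n < p + 1:
        raise ValueError(f"VIF needs at least p+1={p + 1} rows, got {n}")

    vals = []
    for j in range(p):
        y = M[:, j]
        others = sm.add_constant(np.delete(M, j, axis=1))
        res = sm.OLS(y, others).fit()
        r2 = min(res.rsquared, 1.0)
        vals.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    vals = np.array(vals)
    table = pd.DataFrame(
        {"covariate": names, "vif": vals, "flagged": vals > threshold}
    )
    return VifReport(table=table)


@dataclass(frozen=True)
class GlmFit:
    """Converged Poisson log-linear fit with offset log E."""

    params: pd.Series  # coefficients on the log scale (incl. intercept)
    bse: pd.Series
    conf_int: pd.DataFrame  # 95% CI, columns lo/hi
    fitted: np.ndarray  # mean mu per record, panel row order
    pearson_resid: np.ndarray
    deviance: float
    llf: float
    index: pd.DataFrame  # area_id, year per record


def fit_poisson_glm(
    panel: AreaYearPanel,
    covariates: list[str] | None = None,
    offset_log: np.ndarray | None = None,
    expected: np.ndarray | None = None,
) -> GlmFit:
    """Maximum-likelihood Poisson regression of deaths on covariates.

    The linear predictor is x'beta + offset with offset = log E (expected
    deaths from indirect standardization) unless ``offset_log`` overrides it.
    IRLS via statsmodels; convergence tolerance 1e-8 on the deviance.
    """
    s = panel.schema
    covariates = list(covariates if covariates is not None else s.covariate_cols)
    y = panel.data[s.deaths_col].to_numpy(dtype=float)

    if offset_log is None:
        if expected is None:
            raise ValueError("provide expected counts (or an explicit offset_log)")
        expected = np.asarray(expected, dtype=float).reshape(-1)
        if np.any(expected <= 0):
            raise ValueError("expected counts must be positive for a log offset")
        offset_log = np.log(expected)

    X = panel.data[covariates].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear or constant column)")

    model = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset_log)
    res = model.fit(tol=1e-8, maxiter=200)
    if not res.converged:
        raise RuntimeError(f"Poisson IRLS did not converge: {res.mle_retvals}")

    names = ["intercept", *covariates]
    ci = res.conf_int(alpha=0.05)
    return GlmFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        conf_int=pd.DataFrame(ci, index=names, columns=["lo", "hi"]),
        fitted=np.asarray(res.mu),
        pearson_resid=np.asarray(res.resid_pearson),
        deviance=float(res.deviance),
        llf=float(res.llf),
        index=panel.data[[s.area_col, s.year_col]].rename(
            columns={s.area_col: "area_id", s.year_col: "year"}
        ),
    )


def residuals_by_year(fit: GlmFit, kind: str = "pearson") -> dict[int, np.ndarray]:
    """Split residuals into one vector of length K per calendar year.

    Within each year, values are ordered by area_id (the panel's canonical
    ordering), matching the adjacency matrix built from sorted area ids.
    """
    if kind != "pearson":
        raise ValueError("only Pearson residuals are supported")
    df = fit.index.copy()
    df["resid"] = fit.pearson_resid
    out: dict[int, np.ndarray] = {}
    for year, grp in df.groupby("year"):
        out[int(year)] = grp.sort_values("area_id")["resid"].to_numpy()
    return out


@dataclass(frozen=True)
class MoranResult:
    I: float
    p_value: float
    expected_I: float
    n_perm: int


def _moran_statistic(z: np.ndarray, Wn: np.ndarray, S0: float) -> float:
    n = z.size
    return float(n / S0 * (z @ Wn @ z) / (z @ z))


def morans_i(
    x: np.ndarray,
    W: AdjacencyMatrix | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    row_standardize: bool = True,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation test.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 on the centred values z.
    The pseudo p-value is (#{|I_perm| >= |I_obs|} + 1) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    Wm = np.asarray(W.W if isinstance(W, AdjacencyMatrix) else W, dtype=float)
    n = x.size
    if Wm.shape != (n, n):
        raise ValueError(f"weights must be {n}x{n}, got {Wm.shape}")
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise ValueError("Moran's I undefined for a zero-variance vector")

    if row_standardize:
        rs = Wm.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        Wn = Wm / rs
    else:
        Wn = Wm
    S0 = Wn.sum()
    if S0 <= 0:
        raise ValueError("weights matrix has zero total weight")

    I_obs = _moran_statistic(z, Wn, S0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if abs(_moran_statistic(zp, Wn, S0)) >= abs(I_obs):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MoranResult(I=I_obs, p_value=p, expected_I=-1.0 / (n - 1), n_perm=n_perm)


def moran_by_year(
    values_by_year: dict[int, np.ndarray],
    W: AdjacencyMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Moran's I per year as a tidy (year, moran_i, p_value) table."""
    rows = []
    for k, (year, vec) in enumerate(sorted(values_by_year.items())):
        sub_seed = None if seed is None else seed + k
        res = morans_i(vec, W, n_perm=n_perm, seed=sub_seed)
        rows.append({"year": year, "moran_i": res.I, "p_value": res.p_value})
    return pd.DataFrame(rows)
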