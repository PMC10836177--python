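"""Hierarchical Poisson model with a Leroux CAR spatial prior and AR(1)
temporal evolution, fitted by Metropolis-within-Gibbs MCMC.

Model
-----
    Y_kt ~ Poisson(E_kt * theta_kt),     ln theta_kt = x_kt' beta + psi_kt
    psi_.1 ~ MVN(0, tau2 * Q(W, rho_S)^-1)
    psi_.t = rho_T * psi_.(t-1) + eps_t,  eps_t ~ MVN(0, tau2 * Q(W, rho_S)^-1)
    Q(W, rho_S) = rho_S * (diag(W 1) - W) + (1 - rho_S) * I

Priors: beta ~ N(0, 1e5 I); tau2 ~ Inverse-Gamma(1, 0.01); rho_S, rho_T ~ U(0, 1).

The joint prior precision of vec(psi) is (M(rho_T) kron Q(rho_S)) / tau2 with
M the tridiagonal AR(1) precision, so single-site full conditionals only
couple sites that are spatial neighbours (or identical) at time lags <= 1.
The sampler exploits this: random-walk Metropolis updates of psi are applied
simultaneously to colour classes of the space-time interaction graph (greedy
spatial colouring x time parity), which is exact and vectorises the update.
rho_S uses the eigenvalues of the graph Laplacian, cached once, so its
log-determinant term costs O(K) per proposal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.special import expit, gammaln, logit

from .geo_io import AdjacencyMatrix, AreaYearPanel

__all__ = [
    "save_samples",
    "load_samples",
    "PriorSpec",
    "StcarSpec",
    "McmcConfig",
    "PosteriorSamples",
    "ModelFit",
    "ConvergenceReport",
    "leroux_precision",
    "ar1_precision",
    "update_tau2",
    "sample_posterior",
    "run_mcmc",
    "gelman_rubin",
    "geweke",
    "convergence_report",
    "fit_criteria",
]


# ---------------------------------------------------------------------
# specification containers
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors, fixed to the conventional disease-mapping defaults."""

    beta_var: float = 1e5
    tau2_shape: float = 1.0
    tau2_scale: float = 0.01


@dataclass(frozen=True)
class StcarSpec:
    """Which covariates enter the linear predictor (intercept always added).

    With ``standardize`` (default) the sampler works on z-scored covariates —
    raw registry covariates differ by orders of magnitude in scale, which
    cripples random-walk mixing — and the retained draws are mapped back to
    the per-unit scale exactly (the transform is linear), so reported
    coefficients and RRs are always per original covariate unit.
    """

    covariates: tuple[str, ...]
    priors: PriorSpec = field(default_factory=PriorSpec)
    standardize: bool = True


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 220_000
    burn_in: int = 20_000
    thin: int = 100
    n_chains: int = 2
    seed: int = 0
    tune_interval: int = 100

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_keep(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, one entry per chain.

    beta has shape (n_keep, p) per chain (column 0 is the intercept),
    psi has shape (n_keep, K, T); tau2, rho_S, rho_T are (n_keep,).
    """

    beta: list[np.ndarray]
    psi: list[np.ndarray]
    tau2: list[np.ndarray]
    rho_S: list[np.ndarray]
    rho_T: list[np.ndarray]
    beta_names: tuple[str, ...]
    acceptance: list[dict[str, float]]

    @property
    def n_chains(self) -> int:
        return len(self.beta)

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains along the first axis."""
        return np.concatenate(getattr(self, name), axis=0)

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """Scalar parameters as (n_chains, n_keep) arrays, for diagnostics."""
        out: dict[str, np.ndarray] = {}
        for j, nm in enumerate(self.beta_names):
            out[f"beta[{nm}]"] = np.stack([b[:, j] for b in self.beta])
        out["tau2"] = np.stack(self.tau2)
        out["rho_S"] = np.stack(self.rho_S)
        out["rho_T"] = np.stack(self.rho_T)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Scalar draws as a tidy DataFrame (chain, iteration, parameter, value)."""
        rows = []
        for name, chains in self.scalar_chains().items():
            for c in range(chains.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(chains.shape[1]),
                            "parameter": name,
                            "value": chains[c],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def save_samples(samples: PosteriorSamples, path) -> None:
    """Persist retained draws to a .npz archive (one array set per chain)."""
    arrays: dict[str, np.ndarray] = {
        "beta_names": np.array(samples.beta_names),
        "n_chains": np.array(samples.n_chains),
    }
    for c in range(samples.n_chains):
        for name in ("beta", "psi", "tau2", "rho_S", "rho_T"):
            arrays[f"{name}_{c}"] = getattr(samples, name)[c]
        acc = samples.acceptance[c]
        arrays[f"acc_keys_{c}"] = np.array(list(acc.keys()))
        arrays[f"acc_vals_{c}"] = np.array(list(acc.values()))
    np.savez_compressed(path, **arrays)


def load_samples(path) -> PosteriorSamples:
    with np.load(path, allow_pickle=False) as z:
        n_chains = int(z["n_chains"])
        names = tuple(str(s) for s in z["beta_names"])
        kwargs: dict[str, list] = {k: [] for k in ("beta", "psi", "tau2", "rho_S", "rho_T")}
        acceptance = []
        for c in range(n_chains):
            for name in kwargs:
                kwargs[name].append(z[f"{name}_{c}"])
            acceptance.append(
                dict(zip((str(k) for k in z[f"acc_keys_{c}"]), z[f"acc_vals_{c}"].astype(float)))
            )
    return PosteriorSamples(beta_names=names, acceptance=acceptance, **kwargs)


# ---------------------------------------------------------------------
# precision matrices
# ---------------------------------------------------------------------

def leroux_precision(W: AdjacencyMatrix | np.ndarray, rho_S: float) -> np.ndarray:
    """Q = rho_S (diag(W 1) - W) + (1 - rho_S) I.

    Interpolates between independence (rho_S = 0, Q = I) and the intrinsic
    CAR (rho_S = 1, singular with zero row sums).
    """
    Wm = np.asarray(W.W if isinstance(W, AdjacencyMatrix) else W, dtype=float)
    if not 0.0 <= rho_S <= 1.0:
        raise ValueError("rho_S must lie in [0, 1]")
    L = np.diag(Wm.sum(axis=1)) - Wm
    return rho_S * L + (1.0 - rho_S) * np.eye(Wm.shape[0])


def ar1_precision(T: int, rho_T: float) -> np.ndarray:
    """Tridiagonal precision of the AR(1) chain with unit innovation precision.

    Corresponds to psi_1 ~ N(0, .) and psi_t | psi_{t-1} ~ N(rho psi_{t-1}, .);
    determinant 1 for every rho, so rho_T has no log-determinant term.
    """
    M = np.eye(T)
    if T > 1:
        M[np.arange(T - 1), np.arange(T - 1)] += rho_T**2
        M[np.arange(T - 1), np.arange(1, T)] = -rho_T
        M[np.arange(1, T), np.arange(T - 1)] = -rho_T
    return M


def _quadforms(psi: np.ndarray, Q: np.ndarray, rho_T: float) -> float:
    """SS = psi_.1' Q psi_.1 + sum_{t>=2} (psi_.t - rho psi_.(t-1))' Q (...)."""
    Qp = Q @ psi
    ss = float(psi[:, 0] @ Qp[:, 0])
    if psi.shape[1] > 1:
        d = psi[:, 1:] - rho_T * psi[:, :-1]
        Qd = Qp[:, 1:] - rho_T * Qp[:, :-1]
        ss += float(np.sum(d * Qd))
    return ss


def update_tau2(
    psi: np.ndarray,
    Q: np.ndarray,
    rho_T: float,
    a: float = 1.0,
    b: float = 0.01,
    rng: np.random.Generator | None = None,
) -> float:
    """Conjugate Gibbs draw: tau2 | . ~ IG(a + KT/2, b + SS/2)."""
    rng = rng or np.random.default_rng()
    K, T = psi.shape
    ss = _quadforms(psi, Q, rho_T)
    if ss < -1e-9:
        raise RuntimeError("negative CAR quadratic form: precision not PD?")
    shape = a + 0.5 * K * T
    scale = b + 0.5 * max(ss, 0.0)
    return float(scale / rng.gamma(shape, 1.0))


# ---------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------

def _colour_blocks(W: np.ndarray, T: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Colour classes of the space-time interaction graph.

    Two sites (k, t), (k', t') are conditionally dependent iff |t - t'| <= 1
    and k = k' or k ~ k'. Pairing a proper spatial colouring with time parity
    therefore yields classes whose members can be Metropolis-updated jointly.
    """
    G = nx.from_numpy_array(W)
    colours = nx.greedy_color(G, strategy="largest_first")
    n_col = max(colours.values()) + 1 if colours else 1
    blocks = []
    for c in range(n_col):
        rows = np.array([k for k, cc in colours.items() if cc == c], dtype=int)
        if rows.size == 0:
            continue
        for parity in (0, 1):
            cols = np.arange(parity, T, 2)
            if cols.size:
                blocks.append((rows, cols))
    return blocks


class _Adapter:
    """Multiplicative proposal-scale tuning toward 30-50% acceptance.

    Active during burn-in only; scales are frozen afterwards so the retained
    chain satisfies detailed balance.
    """

    def __init__(self, scale: float, target: float = 0.4):
        self.scale = scale
        self.target = target
        self.accepted = 0.0
        self.attempted = 0.0
        self.total_accepted = 0.0
        self.total_attempted = 0.0

    def record(self, accepted: float, attempted: float) -> None:
        self.accepted += accepted
        self.attempted += attempted
        self.total_accepted += accepted
        self.total_attempted += attempted

    def adapt(self) -> None:
        if self.attempted > 0:
            rate = self.accepted / self.attempted
            self.scale *= float(np.exp(1.2 * (rate - self.target)))
            self.scale = float(np.clip(self.scale, 1e-4, 50.0))
        self.accepted = self.attempted = 0.0

    @property
    def overall_rate(self) -> float:
        return self.total_accepted / max(self.total_attempted, 1.0)


def _run_chain(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    config: McmcConfig,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> dict:
    K, T = y.shape
    p = X.shape[2]
    logE = np.log(E)

    Wm = np.asarray(W, dtype=float)
    deg = Wm.sum(axis=1)
    L = np.diag(deg) - Wm
    lam = np.linalg.eigvalsh(L)  # cached: logdet Q(rho) = sum log(rho*lam + 1-rho)
    blocks = _colour_blocks(Wm, T)

    # initial state, jittered per chain so diagnostics are honest
    beta = rng.normal(0.0, 0.1, size=p)
    psi = rng.normal(0.0, 0.01, size=(K, T))
    tau2 = float(rng.uniform(0.05, 0.5))
    rho_S = float(rng.uniform(0.3, 0.7))
    rho_T = float(rng.uniform(0.3, 0.7))

    Q = leroux_precision(Wm, rho_S)
    Qdiag = rho_S * deg + (1.0 - rho_S)
    M = ar1_precision(T, rho_T)
    Mdiag = np.diag(M).copy()

    with np.errstate(over="ignore"):
        eta = X @ beta
        mu = E * np.exp(eta + psi)

    ad_beta = [_Adapter(0.05) for _ in range(p)]
    ad_shift = [_Adapter(0.1) for _ in range(p)]
    ad_psi = _Adapter(0.3)
    ad_rho_S = _Adapter(0.7)
    ad_rho_T = _Adapter(0.7)

    n_keep = config.n_keep
    out_beta = np.empty((n_keep, p))
    out_psi = np.empty((n_keep, K, T))
    out_tau2 = np.empty(n_keep)
    out_rho_S = np.empty(n_keep)
    out_rho_T = np.empty(n_keep)
    kept = 0

    inv_beta_var = 1.0 / priors.beta_var

    for it in range(config.n_iter):
        # --- beta: single-coefficient random-walk Metropolis ----------
        for j in range(p):
            d = ad_beta[j].scale * rng.standard_normal()
            dX = d * X[:, :, j]
            with np.errstate(over="ignore", invalid="ignore"):
                delta = float(np.sum(y * dX) - np.sum(mu * np.expm1(dX)))
                delta -= 0.5 * inv_beta_var * ((beta[j] + d) ** 2 - beta[j] ** 2)
                acc = np.log(rng.uniform()) < delta
                if acc:
                    beta[j] += d
                    mu = mu * np.exp(dX)
            ad_beta[j].record(acc, 1.0)

        # --- psi: simultaneous Metropolis over colour classes ---------
        for rows, cols in blocks:
            G = Q @ psi @ M  # prior gradient term; exact for this block
            sub = np.ix_(rows, cols)
            d = ad_psi.scale * rng.standard_normal((rows.size, cols.size))
            with np.errstate(over="ignore", invalid="ignore"):
                dlik = y[sub] * d - mu[sub] * np.expm1(d)
                dprior = -(0.5 / tau2) * (
                    2.0 * d * G[sub] + d * d * np.outer(Qdiag[rows], Mdiag[cols])
                )
                acc = np.log(rng.uniform(size=d.shape)) < dlik + dprior
                if acc.any():
                    psi[sub] += np.where(acc, d, 0.0)
                    mu[sub] *= np.exp(np.where(acc, d, 0.0))
            ad_psi.record(acc.sum(), acc.size)

        # --- beta/psi interweaving: slide along the confounding ridge --
        # beta_j -> beta_j + d, psi -> psi - d X_j leaves the likelihood
        # invariant (eta is unchanged), so acceptance depends only on the
        # priors; this move is what mixes coefficients of spatially smooth
        # covariates, which are near-collinear with the CAR surface
        for j in range(p):
            d = ad_shift[j].scale * rng.standard_normal()
            Z = X[:, :, j]
            G = Q @ psi @ M
            B = float(np.sum(Z * G))
            C = float(np.sum(Z * (Q @ Z @ M)))
            delta = -(-2.0 * d * B + d * d * C) / (2.0 * tau2)
            delta -= 0.5 * inv_beta_var * ((beta[j] + d) ** 2 - beta[j] ** 2)
            acc = np.log(rng.uniform()) < delta
            if acc:
                beta[j] += d
                psi -= d * Z
            ad_shift[j].record(acc, 1.0)

        # --- tau2: conjugate Gibbs ------------------------------------
        tau2 = update_tau2(psi, Q, rho_T, priors.tau2_shape, priors.tau2_scale, rng)

        # --- rho_S: logit-scale random walk ---------------------------
        dd = psi[:, 1:] - rho_T * psi[:, :-1] if T > 1 else np.zeros((K, 0))
        sL_1 = float(psi[:, 0] @ L @ psi[:, 0])
        sI_1 = float(psi[:, 0] @ psi[:, 0])
        sL = sL_1 + float(np.sum(dd * (L @ dd)))
        sI = sI_1 + float(np.sum(dd * dd))

        def rho_S_logpost(r: float) -> float:
            ldet = float(np.sum(np.log(r * lam + (1.0 - r))))
            ss = r * sL + (1.0 - r) * sI
            return 0.5 * T * ldet - 0.5 * ss / tau2 + np.log(r) + np.log1p(-r)

        u = logit(rho_S) + ad_rho_S.scale * rng.standard_normal()
        r_new = float(expit(u))
        if 0.0 < r_new < 1.0:
            delta = rho_S_logpost(r_new) - rho_S_logpost(rho_S)
            acc = np.log(rng.uniform()) < delta
        else:  # numerically saturated proposal
            acc = False
        if acc:
            rho_S = r_new
            Q = rho_S * L + (1.0 - rho_S) * np.eye(K)
            Qdiag = rho_S * deg + (1.0 - rho_S)
        ad_rho_S.record(acc, 1.0)

        # --- rho_T: logit-scale random walk ---------------------------
        if T > 1:
            Qp = Q @ psi
            A = float(np.sum(psi[:, 1:] * Qp[:, 1:]))
            B = float(np.sum(psi[:, :-1] * Qp[:, 1:]))
            C = float(np.sum(psi[:, :-1] * Qp[:, :-1]))

            def rho_T_logpost(r: float) -> float:
                ss = A - 2.0 * r * B + r * r * C
                return -0.5 * ss / tau2 + np.log(r) + np.log1p(-r)

            u = logit(rho_T) + ad_rho_T.scale * rng.standard_normal()
            r_new = float(expit(u))
            if 0.0 < r_new < 1.0:
                delta = rho_T_logpost(r_new) - rho_T_logpost(rho_T)
                acc = np.log(rng.uniform()) < delta
            else:
                acc = False
            if acc:
                rho_T = r_new
                M = ar1_precision(T, rho_T)
                Mdiag = np.diag(M).copy()
            ad_rho_T.record(acc, 1.0)

        # --- adaptation and bookkeeping -------------------------------
        if it < config.burn_in and (it + 1) % config.tune_interval == 0:
            for a in (*ad_beta, *ad_shift, ad_psi, ad_rho_S, ad_rho_T):
                a.adapt()
        if (it + 1) % 500 == 0:  # guard against multiplicative drift in mu
            with np.errstate(over="ignore"):
                mu = E * np.exp(X @ beta + psi)
        # divergence guard: non-finite parameters are fatal, and so is an
        # overflowed mean wherever deaths were observed (the chain could
        # never leave such a state); an overflowed mean with y = 0 is a
        # legitimate prior-dominated excursion when E ~ 0 and resolves itself
        if (
            not (np.isfinite(beta).all() and np.isfinite(psi).all() and np.isfinite(tau2))
            or bool(np.any(~np.isfinite(mu) & (y > 0)))
        ):
            raise RuntimeError(
                f"sampler diverged at iteration {it}: non-finite state "
                f"(beta={beta}, tau2={tau2}, rho_S={rho_S}, rho_T={rho_T})"
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < n_keep:
            out_beta[kept] = beta
            out_psi[kept] = psi
            out_tau2[kept] = tau2
            out_rho_S[kept] = rho_S
            out_rho_T[kept] = rho_T
            kept += 1

    return {
        "beta": out_beta[:kept],
        "psi": out_psi[:kept],
        "tau2": out_tau2[:kept],
        "rho_S": out_rho_S[:kept],
        "rho_T": out_rho_T[:kept],
        "acceptance": {
            "beta": float(np.mean([a.overall_rate for a in ad_beta])),
            "shift": float(np.mean([a.overall_rate for a in ad_shift])),
            "psi": ad_psi.overall_rate,
            "rho_S": ad_rho_S.overall_rate,
            "rho_T": ad_rho_T.overall_rate,
        },
    }


def sample_posterior(
    y: np.ndarray,
    E: np.ndarray,
    X: np.ndarray,
    W: AdjacencyMatrix | np.ndarray,
    config: McmcConfig,
    priors: PriorSpec | None = None,
    beta_names: tuple[str, ...] | None = None,
) -> PosteriorSamples:
    """Run ``config.n_chains`` independent chains on array inputs.

    y, E are (K, T); X is (K, T, p) and must already contain the intercept
    column if one is wanted. Chains get independent seeds spawned from
    ``config.seed`` and are exactly reproducible.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape != E.shape or X.shape[:2] != y.shape:
        raise ValueError("y, E, X have inconsistent shapes")
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")
    Wm = np.asarray(W.W if isinstance(W, AdjacencyMatrix) else W, dtype=float)
    if isinstance(W, AdjacencyMatrix):
        W.require_no_islands()
    priors = priors or PriorSpec()

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(y, E, X, Wm, config, priors, np.random.default_rng(s))
        for s in seeds
    ]
    names = beta_names or tuple(f"b{j}" for j in range(X.shape[2]))
    return PosteriorSamples(
        beta=[c["beta"] for c in chains],
        psi=[c["psi"] for c in chains],
        tau2=[c["tau2"] for c in chains],
        rho_S=[c["rho_S"] for c in chains],
        rho_T=[c["rho_T"] for c in chains],
        beta_names=names,
        acceptance=[c["acceptance"] for c in chains],
    )


def run_mcmc(
    spec: StcarSpec,
    panel: AreaYearPanel,
    expected: np.ndarray,
    W: AdjacencyMatrix,
    config: McmcConfig,
) -> PosteriorSamples:
    """Fit the model to a balanced panel.

    ``expected`` is the (K, T) expected-count surface from indirect
    standardization. An intercept is always included ahead of the named
    covariates.
    """
    y = panel.pivot(panel.schema.deaths_col)
    K, T = y.shape
    p = len(spec.covariates)
    X = np.empty((K, T, p + 1))
    X[:, :, 0] = 1.0
    for j, name in enumerate(spec.covariates):
        X[:, :, j + 1] = panel.pivot(name)
    names = ("intercept", *spec.covariates)

    means = np.zeros(p + 1)
    sds = np.ones(p + 1)
    if spec.standardize and p > 0:
        means[1:] = X[:, :, 1:].reshape(-1, p).mean(axis=0)
        sds[1:] = X[:, :, 1:].reshape(-1, p).std(axis=0)
        if np.any(sds[1:] == 0):
            flat = [spec.covariates[j] for j in range(p) if sds[j + 1] == 0]
            raise ValueError(f"constant covariates cannot be standardized: {flat}")
        X = X.copy()
        X[:, :, 1:] = (X[:, :, 1:] - means[1:]) / sds[1:]

    samples = sample_posterior(y, np.asarray(expected, dtype=float), X, W, config,
                               priors=spec.priors, beta_names=names)

    if spec.standardize and p > 0:
        # map draws back to the per-unit scale: eta = b0s + sum bjs (x-m)/s
        # = (b0s - sum bjs m/s) + sum (bjs/s) x
        for c in range(samples.n_chains):
            b = samples.beta[c]
            b_unit = b / sds
            b_unit[:, 0] = b[:, 0] - (b[:, 1:] * (means[1:] / sds[1:])).sum(axis=1)
            samples.beta[c] = b_unit
    return samples


# ---------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor from >= 2 equal-length chains.

    chains: (m, n) array. R-hat = sqrt(((n-1)/n W + B/n) / W) with W the mean
    within-chain variance and B/n the variance of chain means.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short")
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_plus / within))


def _long_run_variance(x: np.ndarray) -> float:
    """Newey-West (Bartlett kernel) estimate of the spectral density at zero."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    lags = max(int(n ** (1 / 3)), 1)
    s = gamma0
    for k in range(1, lags + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (lags + 1)) * gk
    return max(s, 1e-300)


def geweke(samples: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(s1/n1 + s2/n2) with s the long-run
    variance of each segment; |z| > 2 flags disagreement between the start
    and the end of the chain.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    n1 = int(first * n)
    n2 = int(last * n)
    if n1 < 10 or n2 < 10:
        raise ValueError(f"chain of length {n} too short for Geweke segments")
    a, b = x[:n1], x[n - n2:]
    s1 = _long_run_variance(a)
    s2 = _long_run_variance(b)
    return float((a.mean() - b.mean()) / np.sqrt(s1 / n1 + s2 / n2))


@dataclass(frozen=True)
class ConvergenceReport:
    table: pd.DataFrame  # parameter, rhat, geweke_z per chain, flags

    @property
    def all_converged(self) -> bool:
        return not bool(self.table["flagged"].any())


def convergence_report(samples: PosteriorSamples) -> ConvergenceReport:
    """R-hat (threshold 1.1) and Geweke z (threshold |z| <= 2) per scalar."""
    rows = []
    for name, chains in samples.scalar_chains().items():
        rhat = gelman_rubin(chains) if chains.shape[0] >= 2 else np.nan
        zs = [geweke(chains[c]) for c in range(chains.shape[0])]
        zmax = float(np.max(np.abs(zs)))
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "geweke_z_max": zmax,
                "flagged": (rhat >= 1.1 if np.isfinite(rhat) else False) or zmax > 2.0,
            }
        )
    return ConvergenceReport(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------
# fit criteria
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    dic: float
    p_d: float
    waic: float
    p_waic: float
    mean_loglik: float


def _pointwise_loglik(
    samples: PosteriorSamples, y: np.ndarray, E: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """(n_draws_total, K*T) Poisson log-likelihood per retained draw."""
    beta = samples.stacked("beta")
    psi = samples.stacked("psi")
    yf = y.ravel()
    logEf = np.log(E).ravel()
    const = gammaln(yf + 1.0)
    n = beta.shape[0]
    out = np.empty((n, yf.size))
    Xf = X.reshape(-1, X.shape[2])
    for i in range(n):
        eta = Xf @ beta[i] + psi[i].ravel()
        log_mu = logEf + eta
        out[i] = yf * log_mu - np.exp(log_mu) - const
    return out


def fit_criteria(
    samples: PosteriorSamples, y: np.ndarray, E: np.ndarray, X: np.ndarray
) -> ModelFit:
    """DIC (plug-in penalty) and WAIC (variance penalty) from retained draws.

    DIC = Dbar + p_D with p_D = Dbar - D(posterior-mean parameters);
    WAIC = -2 (lppd - p_WAIC) with p_WAIC the summed pointwise posterior
    variance of the log-likelihood.
    """
    ll = _pointwise_loglik(samples, y, E, X)
    dev_draws = -2.0 * ll.sum(axis=1)
    dbar = float(dev_draws.mean())

    beta_bar = samples.stacked("beta").mean(axis=0)
    psi_bar = samples.stacked("psi").mean(axis=0)
    Xf = X.reshape(-1, X.shape[2])
    log_mu = np.log(E).ravel() + Xf @ beta_bar + psi_bar.ravel()
    yf = y.ravel()
    d_hat = float(-2.0 * np.sum(yf * log_mu - np.exp(log_mu) - gammaln(yf + 1.0)))
    p_d = dbar - d_hat

    n = ll.shape[0]
    lppd = float(np.sum(_logmeanexp(ll, axis=0)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1))) if n > 1 else 0.0
    waic = -2.0 * (lppd - p_waic)
    return ModelFit(
        dic=dbar + p_d,
        p_d=p_d,
        waic=waic,
        p_waic=p_waic,
        mean_loglik=float(ll.sum(axis=1).mean()),
    )


def _logmeanexp(a: np.ndarray, axis: int) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(a, axis=axis) - np.log(a.shape[axis])


# ---------------------------------------------------------------------
# simulation support (used by synthetic_region)
# ---------------------------------------------------------------------

def sample_car_field(
    Q: np.ndarray, tau2: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw from MVN(0, tau2 * Q^-1) via the Cholesky factor of Q."""
    R = cholesky(Q, lower=False)  # Q = R' R
    z = rng.standard_normal(Q.shape[0])
    x = np.linalg.solve(R, z)  # cov(x) = Q^-1
    return np.sqrt(tau2) * x
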