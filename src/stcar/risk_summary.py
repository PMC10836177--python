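"""Posterior summaries: covariate relative risks, per-area-year risk surfaces,
exceedance probabilities, and the yearly trend curve.

Conventions: a covariate RR is exp(posterior mean coefficient) with an
equal-tailed 95% credible interval from the exponentiated 2.5/97.5% sample
quantiles; the per-cell exceedance probability (PEP) is the posterior
probability that the relative risk strictly exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stcar_model import PosteriorSamples

__all__ = [
    "RiskSurface",
    "TrendSeries",
    "covariate_rr",
    "covariate_rr_table",
    "risk_surface",
    "yearly_trend",
    "percent_change",
    "rr_percent_reduction",
]

MIN_DRAWS = 100


@dataclass(frozen=True)
class RiskSurface:
    """Per (area, year): posterior mean RR, 95% CrI, and PEP = Pr(RR > 1)."""

    table: pd.DataFrame  # area_id, year, rr_mean, rr_lo, rr_hi, pep


@dataclass(frozen=True)
class TrendSeries:
    """Posterior mean of the across-area average risk per year, with 95% band."""

    table: pd.DataFrame  # year, rr_mean, rr_lo, rr_hi


def _require_draws(n: int) -> None:
    if n < MIN_DRAWS:
        raise ValueError(f"need >= {MIN_DRAWS} retained draws, got {n}")


def covariate_rr(samples: PosteriorSamples, covariate: str | int) -> tuple[float, tuple[float, float]]:
    """RR = exp(mean beta_j) with equal-tailed 95% CrI exp(q2.5, q97.5)."""
    beta = samples.stacked("beta")
    _require_draws(beta.shape[0])
    if isinstance(covariate, str):
        try:
            j = samples.beta_names.index(covariate)
        except ValueError:
            raise KeyError(
                f"unknown covariate {covariate!r}; have {samples.beta_names}"
            ) from None
    else:
        j = int(covariate)
    draws = beta[:, j]
    rr = float(np.exp(draws.mean()))
    lo, hi = np.exp(np.quantile(draws, [0.025, 0.975]))
    return rr, (float(lo), float(hi))


def covariate_rr_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Table-2-style summary: one RR and CrI per linear-predictor term."""
    rows = []
    for name in samples.beta_names:
        rr, (lo, hi) = covariate_rr(samples, name)
        rows.append({"covariate": name, "rr": rr, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def _theta_draws(samples: PosteriorSamples, X: np.ndarray) -> np.ndarray:
    """(n_draws, K, T) relative-risk draws theta = exp(X beta + psi)."""
    beta = samples.stacked("beta")
    psi = samples.stacked("psi")
    _require_draws(beta.shape[0])
    if X.shape[2] != beta.shape[1]:
        raise ValueError(
            f"design has {X.shape[2]} columns but beta has {beta.shape[1]}"
        )
    eta = np.einsum("ktp,np->nkt", X, beta)
    return np.exp(eta + psi)


def risk_surface(
    samples: PosteriorSamples,
    X: np.ndarray,
    area_ids: list[str],
    years: list[int],
) -> RiskSurface:
    """Posterior RR surface over every (area, year) cell.

    X is the (K, T, p) design used in the fit, including the intercept.
    PEP counts draws with theta strictly above 1 (ties count as
    non-exceedance).
    """
    theta = _theta_draws(samples, X)
    rr_mean = theta.mean(axis=0)
    rr_lo, rr_hi = np.quantile(theta, [0.025, 0.975], axis=0)
    pep = (theta > 1.0).mean(axis=0)

    K, T = rr_mean.shape
    if len(area_ids) != K or len(years) != T:
        raise ValueError("area_ids/years do not match the design dimensions")
    idx = pd.MultiIndex.from_product([area_ids, years], names=["area_id", "year"])
    table = pd.DataFrame(
        {
            "rr_mean": rr_mean.ravel(),
            "rr_lo": rr_lo.ravel(),
            "rr_hi": rr_hi.ravel(),
            "pep": pep.ravel(),
        },
        index=idx,
    ).reset_index()
    return RiskSurface(table=table)


def yearly_trend(
    samples: PosteriorSamples,
    X: np.ndarray,
    years: list[int],
) -> TrendSeries:
    """Across-area average risk per year, summarised draw by draw."""
    theta = _theta_draws(samples, X)
    avg = theta.mean(axis=1)  # (n_draws, T)
    lo, hi = np.quantile(avg, [0.025, 0.975], axis=0)
    table = pd.DataFrame(
        {
            "year": list(years),
            "rr_mean": avg.mean(axis=0),
            "rr_lo": lo,
            "rr_hi": hi,
        }
    )
    return TrendSeries(table=table)


def percent_change(rr_start: float, rr_end: float) -> float:
    """Percent decline between two relative risks, 100 (start - end) / start,
    rounded to one decimal for reporting."""
    if rr_start <= 0:
        raise ValueError("starting relative risk must be positive")
    return round(100.0 * (rr_start - rr_end) / rr_start, 1)


def rr_percent_reduction(rr: float) -> float:
    """Protective-effect size of a covariate RR, 100 (1 - RR) percent."""
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return round(100.0 * (1.0 - rr), 1)
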