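"""Mortality rates, indirect standardization, and standardized mortality ratios.

Expected deaths for each area-year are built by applying whole-region
age-stratum death rates to that area-year's stratum populations (indirect
standardization). The SMR is observed/expected: values above one mean more
deaths than the region's age structure predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .geo_io import AreaYearPanel

__all__ = [
    "raw_mortality_rate",
    "service_rate",
    "expected_counts",
    "expected_from_stratum_counts",
    "smr",
    "ExpectedCounts",
    "SmrTable",
    "standardization_table",
]


def expected_from_stratum_counts(obs_strata, pop_strata) -> np.ndarray:
    """Indirect standardization from stratum-level observed counts.

    ``obs_strata`` and ``pop_strata`` are (units x strata) arrays. Reference
    rates are r_a = sum_k O_ka / sum_k n_ka; expected counts are
    E_k = sum_a n_ka * r_a. Satisfies sum(E) == sum(O) exactly.
    """
    O = np.asarray(obs_strata, dtype=float)
    n = np.asarray(pop_strata, dtype=float)
    if O.shape != n.shape:
        raise ValueError("observed and population arrays must have the same shape")
    tot_n = n.sum(axis=0)
    if np.any(tot_n <= 0):
        empty = np.flatnonzero(tot_n <= 0).tolist()
        raise ValueError(f"empty reference stratum populations at indices {empty}")
    rates = O.sum(axis=0) / tot_n
    return n @ rates


def raw_mortality_rate(deaths, pop):
    """Deaths per 100,000 population. Accepts scalars or arrays."""
    deaths = np.asarray(deaths, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be positive for a mortality rate")
    if np.any(deaths < 0):
        raise ValueError("death counts must be non-negative")
    out = deaths / pop * 100_000.0
    return float(out) if out.ndim == 0 else out


def service_rate(count, pop_15plus):
    """Procedures or practitioners per 1,000 population aged 15+."""
    count = np.asarray(count, dtype=float)
    pop = np.asarray(pop_15plus, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population aged 15+ must be positive")
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    out = count / pop * 1_000.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected deaths E_kt per (area, year), from indirect standardization."""

    table: pd.DataFrame  # columns: area_id, year, expected
    reference_rates: pd.DataFrame  # columns: stratum, rate (per person-year)

    def pivot(self) -> np.ndarray:
        wide = self.table.pivot(index="area_id", columns="year", values="expected")
        return wide.sort_index().sort_index(axis=1).to_numpy()


@dataclass(frozen=True)
class SmrTable:
    """Standardized mortality ratio O/E per (area, year)."""

    table: pd.DataFrame  # columns: area_id, year, observed, expected, smr

    def pivot(self) -> np.ndarray:
        wide = self.table.pivot(index="area_id", columns="year", values="smr")
        return wide.sort_index().sort_index(axis=1).to_numpy()


def _stratum_deaths(panel: AreaYearPanel) -> pd.DataFrame:
    """Apportion each area-year's deaths to age strata by population share.

    The panel carries one aggregate death count per (area, year); stratum-level
    observed deaths are imputed proportionally to stratum population, which
    keeps the whole-region reference rates internally consistent and makes the
    conservation identity exact.
    """
    s = panel.schema
    df = panel.data.copy()
    strata = list(s.strata_cols)
    share = df[strata].div(df[strata].sum(axis=1), axis=0)
    return share.mul(df[s.deaths_col], axis=0)


def expected_counts(
    panel: AreaYearPanel,
    scope: Literal["pooled", "per-year"] = "pooled",
) -> ExpectedCounts:
    """Indirectly standardized expected deaths per area-year.

    Reference rates are the whole-region stratum-specific death rates, pooled
    over the full study window by default (``scope="per-year"`` recomputes
    them within each calendar year). Under either scope the totals are
    conserved: summed over the scope, expected equals observed.
    """
    s = panel.schema
    df = panel.data
    strata = list(s.strata_cols)
    deaths_by_stratum = _stratum_deaths(panel)

    if scope == "pooled":
        tot_d = deaths_by_stratum.sum(axis=0)
        tot_n = df[strata].sum(axis=0)
        if (tot_n <= 0).any():
            empty = tot_n.index[tot_n <= 0].tolist()
            raise ValueError(f"empty reference stratum populations: {empty}")
        rates = tot_d / tot_n
        E = (df[strata] * rates.to_numpy()).sum(axis=1)
    elif scope == "per-year":
        E = pd.Series(0.0, index=df.index)
        for _, idx in df.groupby(s.year_col).groups.items():
            sub_d = deaths_by_stratum.loc[idx].sum(axis=0)
            sub_n = df.loc[idx, strata].sum(axis=0)
            if (sub_n <= 0).any():
                empty = sub_n.index[sub_n <= 0].tolist()
                raise ValueError(f"empty reference stratum populations: {empty}")
            rates = sub_d / sub_n
            E.loc[idx] = (df.loc[idx, strata] * rates.to_numpy()).sum(axis=1)
        tot_d = deaths_by_stratum.sum(axis=0)
        tot_n = df[strata].sum(axis=0)
        rates = tot_d / tot_n  # reported reference = pooled, for the record
    else:
        raise ValueError(f"unknown standardization scope {scope!r}")

    out = pd.DataFrame(
        {
            "area_id": df[s.area_col].to_numpy(),
            "year": df[s.year_col].to_numpy(),
            "expected": E.to_numpy(),
        }
    )
    ref = pd.DataFrame({"stratum": strata, "rate": rates.to_numpy()})
    return ExpectedCounts(table=out, reference_rates=ref)


def smr(observed, expected) -> SmrTable | np.ndarray:
    """Standardized mortality ratio, elementwise observed / expected.

    With array inputs returns the ratio array; with a panel-aligned
    DataFrame-backed ``ExpectedCounts`` use :func:`standardization_table`.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive to form an SMR")
    if np.any(O < 0):
        raise ValueError("observed counts must be non-negative")
    out = O / E
    return float(out) if out.ndim == 0 else out


def standardization_table(
    panel: AreaYearPanel,
    scope: Literal["pooled", "per-year"] = "pooled",
) -> SmrTable:
    """Tidy (area_id, year, observed, expected, smr, raw_rate) table."""
    s = panel.schema
    E = expected_counts(panel, scope=scope)
    df = panel.data
    obs = df[s.deaths_col].to_numpy(dtype=float)
    exp_ = E.table["expected"].to_numpy()
    out = pd.DataFrame(
        {
            "area_id": df[s.area_col].to_numpy(),
            "year": df[s.year_col].to_numpy(),
            "observed": obs,
            "expected": exp_,
            "smr": smr(obs, exp_),
            "raw_rate_per_100k": raw_mortality_rate(obs, df[s.pop_total_col].to_numpy()),
        }
    )
    return SmrTable(table=out)
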