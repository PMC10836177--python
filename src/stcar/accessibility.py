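"""Two-step floating catchment area (2SFCA) accessibility to cardiology centres.

Step 1 assigns each facility a supply-to-demand ratio: bed capacity divided by
the population living within the travel-time catchment (60 minutes by default,
the reperfusion-window radius used for ST-elevation infarction care). Step 2
sums, for each area, the ratios of every facility it can reach within the same
radius. Dichotomous weighting, no distance decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geo_io import AreaYearPanel

__all__ = [
    "FacilitySet",
    "TravelTimeMatrix",
    "facility_ratio",
    "facility_ratios",
    "accessibility_index",
    "two_step_fca",
    "attach_accessibility",
    "read_facilities_csv",
    "read_travel_times_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_MIN = 60.0
DEFAULT_CAPACITY_BEDS = 100.0


@dataclass(frozen=True)
class FacilitySet:
    """Hemodynamic/cardiology centres with bed capacities."""

    facility_ids: tuple[str, ...]
    capacity_beds: np.ndarray

    def __post_init__(self) -> None:
        caps = np.asarray(self.capacity_beds, dtype=float)
        if len(self.facility_ids) != len(set(self.facility_ids)):
            raise ValueError("facility ids are not unique")
        if caps.shape != (len(self.facility_ids),) or np.any(caps <= 0):
            raise ValueError("capacities must be positive, one per facility")


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Minutes of car travel from each area (rows) to each facility (columns)."""

    area_ids: tuple[str, ...]
    facility_ids: tuple[str, ...]
    minutes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.minutes, dtype=float)
        expected = (len(self.area_ids), len(self.facility_ids))
        if t.shape != expected:
            raise ValueError(f"travel matrix must be {expected}, got {t.shape}")
        if not np.isfinite(t).all() or np.any(t < 0):
            raise ValueError("travel times must be finite and non-negative")


def facility_ratio(
    capacity: float,
    travel_to_facility: np.ndarray,
    population: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> float:
    """Supply-to-demand ratio for one facility: S_j / sum of P_i within reach.

    The catchment test is closed (t <= threshold). An empty catchment yields
    ratio 0 with a warning rather than a division error.
    """
    if threshold <= 0:
        raise ValueError("catchment threshold must be positive")
    t = np.asarray(travel_to_facility, dtype=float)
    P = np.asarray(population, dtype=float)
    if np.any(P < 0):
        raise ValueError("populations must be non-negative")
    within = t <= threshold
    demand = P[within].sum()
    if demand <= 0:
        logger.warning("facility has an empty catchment (no population within %g min)", threshold)
        return 0.0
    return float(capacity) / float(demand)


def facility_ratios(
    facilities: FacilitySet,
    travel: TravelTimeMatrix,
    population: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> np.ndarray:
    caps = np.asarray(facilities.capacity_beds, dtype=float)
    return np.array(
        [
            facility_ratio(caps[j], travel.minutes[:, j], population, threshold)
            for j in range(len(caps))
        ]
    )


def accessibility_index(
    ratios: np.ndarray,
    travel: TravelTimeMatrix,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> np.ndarray:
    """A_i = sum of R_j over facilities j reachable from area i (t <= threshold)."""
    R = np.asarray(ratios, dtype=float)
    if R.shape != (len(travel.facility_ids),):
        raise ValueError(
            f"expected one ratio per facility ({len(travel.facility_ids)}), got {R.shape}"
        )
    reach = travel.minutes <= threshold
    return reach @ R


def two_step_fca(
    facilities: FacilitySet,
    travel: TravelTimeMatrix,
    population: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> pd.DataFrame:
    """Full 2SFCA: returns a tidy (area_id, accessibility) table."""
    R = facility_ratios(facilities, travel, population, threshold)
    A = accessibility_index(R, travel, threshold)
    return pd.DataFrame({"area_id": list(travel.area_ids), "accessibility": A})


def attach_accessibility(panel: AreaYearPanel, access: pd.DataFrame) -> AreaYearPanel:
    """Join the (time-invariant) accessibility index onto every panel year."""
    s = panel.schema
    amap = dict(zip(access["area_id"].astype(str), access["accessibility"].astype(float)))
    missing = [a for a in panel.area_ids if a not in amap]
    if missing:
        raise ValueError(f"accessibility missing for areas: {missing[:10]}")
    df = panel.data.copy()
    df["accessibility"] = df[s.area_col].map(amap)
    schema = s
    if "accessibility" not in s.covariate_cols:
        from dataclasses import replace

        schema = replace(s, covariate_cols=(*s.covariate_cols, "accessibility"))
    return AreaYearPanel(df, schema)


# ---------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------

def read_facilities_csv(path: str | Path) -> FacilitySet:
    df = pd.read_csv(path, dtype={"facility_id": str})
    return FacilitySet(
        facility_ids=tuple(df["facility_id"]),
        capacity_beds=df["capacity_beds"].to_numpy(dtype=float),
    )


def read_travel_times_csv(path: str | Path) -> TravelTimeMatrix:
    """Matrix CSV: first column area_id, remaining columns one per facility."""
    df = pd.read_csv(path, dtype={"area_id": str}).set_index("area_id")
    return TravelTimeMatrix(
        area_ids=tuple(df.index),
        facility_ids=tuple(df.columns),
        minutes=df.to_numpy(dtype=float),
    )
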