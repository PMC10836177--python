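"""Geometry and panel I/O for small-area mortality analysis.

Reads area polygons from GeoJSON, builds queen-contiguity spatial weights,
and loads/validates balanced area x year panels from CSV. All downstream
stages (standardization, accessibility, screening, the Bayesian model)
consume the containers defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "AreaGeometry",
    "AdjacencyMatrix",
    "AreaYearPanel",
    "PanelSchema",
    "build_queen_adjacency",
    "load_panel",
    "write_panel",
    "read_geojson",
    "write_geojson",
    "write_surface",
]

#: default 10-year age bands covering the 50-79 study population
DEFAULT_STRATA = ("pop_50_59", "pop_60_69", "pop_70_79")

#: covariates with hard range constraints (inclusive bounds; None = unbounded)
_COVARIATE_RANGES = {
    "phc_coverage": (0.0, 100.0),
    "ipdm": (0.0, 1.0),
    "stress_test_rate": (0.0, None),
    "echo_rate": (0.0, None),
    "scinti_rate": (0.0, None),
    "cath_rate": (0.0, None),
    "cardiologist_rate": (0.0, None),
    "accessibility": (0.0, None),
}

DEFAULT_COVARIATES = (
    "phc_coverage",
    "ipdm",
    "stress_test_rate",
    "echo_rate",
    "scinti_rate",
    "cath_rate",
    "cardiologist_rate",
)


@dataclass(frozen=True)
class AreaGeometry:
    """A study area: string identifier plus a planar polygon (metres)."""

    area_id: str
    polygon: BaseGeometry

    def validate(self) -> None:
        if self.polygon is None or self.polygon.is_empty:
            raise ValueError(f"area {self.area_id!r}: empty geometry")
        if not self.polygon.is_valid:
            raise ValueError(f"area {self.area_id!r}: invalid (self-intersecting?) geometry")


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric binary spatial weights over ``n`` areas.

    ``W[i, j] == 1`` iff areas ``i`` and ``j`` are neighbours. The diagonal
    is zero. ``area_ids`` records the row/column ordering.
    """

    n: int
    W: np.ndarray
    area_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        if W.shape != (self.n, self.n):
            raise ValueError(f"W must be {self.n}x{self.n}, got {W.shape}")
        if not np.array_equal(W, W.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("adjacency matrix must have a zero diagonal")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.W).sum(axis=1)

    def require_no_islands(self) -> None:
        """Reject areas with zero neighbours (the CAR prior needs degree >= 1)."""
        deg = self.degrees
        if (deg == 0).any():
            isolated = [
                self.area_ids[i] if self.area_ids else str(i)
                for i in np.flatnonzero(deg == 0)
            ]
            raise ValueError(
                "adjacency has island areas with no neighbours "
                f"(unusable under a CAR prior): {isolated}"
            )


@dataclass(frozen=True)
class PanelSchema:
    """Column layout of a panel CSV."""

    area_col: str = "area_id"
    year_col: str = "year"
    deaths_col: str = "deaths"
    pop_total_col: str = "pop_total"
    pop_15plus_col: str = "pop_15plus"
    strata_cols: tuple[str, ...] = DEFAULT_STRATA
    covariate_cols: tuple[str, ...] = DEFAULT_COVARIATES

    @property
    def required(self) -> tuple[str, ...]:
        return (
            self.area_col,
            self.year_col,
            self.deaths_col,
            self.pop_total_col,
            self.pop_15plus_col,
            *self.strata_cols,
            *self.covariate_cols,
        )


@dataclass
class AreaYearPanel:
    """Balanced long-format panel of area x year records.

    Holds one row per (area, year) with a death count, population totals,
    age-stratum populations, and named covariates, sorted by (area_id, year).
    """

    data: pd.DataFrame
    schema: PanelSchema = field(default_factory=PanelSchema)

    def __post_init__(self) -> None:
        self.data = self.data.sort_values(
            [self.schema.area_col, self.schema.year_col], kind="mergesort"
        ).reset_index(drop=True)
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def area_ids(self) -> list[str]:
        return sorted(self.data[self.schema.area_col].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data[self.schema.year_col].unique())

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def pivot(self, column: str) -> np.ndarray:
        """Return ``column`` as a (K areas x T years) array, rows/cols sorted."""
        wide = self.data.pivot(
            index=self.schema.area_col, columns=self.schema.year_col, values=column
        )
        wide = wide.sort_index().sort_index(axis=1)
        return wide.to_numpy()

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stacked covariate design (K*T rows in (area, year) order, p columns)."""
        names = list(names if names is not None else self.schema.covariate_cols)
        return self.data[names].to_numpy(dtype=float)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        s = self.schema
        df = self.data
        missing = [c for c in s.required if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing required columns: {missing}")

        dup = df.duplicated([s.area_col, s.year_col])
        if dup.any():
            pairs = df.loc[dup, [s.area_col, s.year_col]].to_records(index=False)
            raise ValueError(f"duplicated (area, year) cells: {list(pairs)[:5]}")

        areas, years = self.area_ids, self.years
        expected = len(areas) * len(years)
        if len(df) != expected:
            have = set(zip(df[s.area_col], df[s.year_col].astype(int)))
            gaps = [(a, y) for a in areas for y in years if (a, y) not in have]
            raise ValueError(
                f"unbalanced panel: {len(df)} rows for {len(areas)} areas x "
                f"{len(years)} years; missing cells {gaps[:10]}"
            )
        if years != list(range(years[0], years[0] + len(years))):
            raise ValueError(f"years are not contiguous: {years}")

        if (df[s.deaths_col] < 0).any():
            bad = df.index[df[s.deaths_col] < 0].tolist()
            raise ValueError(f"negative death counts at rows {bad[:5]}")
        for col in (s.pop_total_col, s.pop_15plus_col, *s.strata_cols):
            if (df[col] <= 0).any():
                bad = df.index[df[col] <= 0].tolist()
                raise ValueError(f"non-positive population in {col!r} at rows {bad[:5]}")
        if (df[s.deaths_col] > df[s.pop_total_col]).any():
            raise ValueError("death counts exceed total population in some cells")

        for col in s.covariate_cols:
            lo, hi = _COVARIATE_RANGES.get(col, (None, None))
            if lo is not None and (df[col] < lo).any():
                raise ValueError(f"covariate {col!r} below {lo}")
            if hi is not None and (df[col] > hi).any():
                raise ValueError(f"covariate {col!r} above {hi}")


# ---------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------

def build_queen_adjacency(geometries: Sequence[AreaGeometry]) -> AdjacencyMatrix:
    """Queen-contiguity weights: areas sharing >= 1 boundary point are neighbours.

    Uses an STRtree so the construction is O(n log n) on typical lattices.
    Raises if any polygon is invalid, naming the offending area_id.
    """
    if len(geometries) == 0:
        raise ValueError("need at least one area geometry")
    ids = [g.area_id for g in geometries]
    if len(set(ids)) != len(ids):
        raise ValueError("area_ids are not unique")
    for g in geometries:
        g.validate()

    polys = [g.polygon for g in geometries]
    tree = STRtree(polys)
    n = len(polys)
    W = np.zeros((n, n), dtype=int)
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j != i:
                W[i, j] = W[j, i] = 1
    return AdjacencyMatrix(n=n, W=W, area_ids=tuple(ids))


# ---------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------

def load_panel(panel_csv: str | Path, schema: PanelSchema | None = None) -> AreaYearPanel:
    """Read and validate a balanced panel from a comma-separated UTF-8 CSV."""
    schema = schema or PanelSchema()
    df = pd.read_csv(panel_csv, dtype={schema.area_col: str})
    df[schema.year_col] = df[schema.year_col].astype(int)
    return AreaYearPanel(df, schema)


def write_panel(panel: AreaYearPanel, out_csv: str | Path) -> Path:
    out_csv = Path(out_csv)
    panel.data.to_csv(out_csv, index=False)
    return out_csv


# ---------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------

def read_geojson(path: str | Path, id_property: str = "area_id") -> list[AreaGeometry]:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for k, feat in enumerate(gj["features"]):
        props = feat.get("properties") or {}
        area_id = str(props.get(id_property, feat.get("id", k)))
        out.append(AreaGeometry(area_id=area_id, polygon=shape(feat["geometry"])))
    return out


def write_geojson(
    geometries: Sequence[AreaGeometry],
    path: str | Path,
    properties: dict[str, dict] | None = None,
) -> Path:
    """Write areas as a FeatureCollection; ``properties`` maps area_id -> dict."""
    feats = []
    for g in geometries:
        props = {"area_id": g.area_id}
        if properties is not None:
            props.update(properties.get(g.area_id, {}))
        feats.append(
            {"type": "Feature", "geometry": mapping(g.polygon), "properties": props}
        )
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    return path


def write_surface(surface, geometries: Sequence[AreaGeometry], out_path: str | Path) -> tuple[Path, Path]:
    """Export a posterior risk surface as GeoJSON (one feature per area, one
    set of RR/CrI/PEP attributes per year) plus a tidy CSV.

    ``surface`` is any object with a ``table`` DataFrame holding columns
    area_id, year, rr_mean, rr_lo, rr_hi, pep (see risk_summary.RiskSurface).
    Round-tripping the GeoJSON recovers every value to 1e-9.
    """
    table = surface.table if hasattr(surface, "table") else surface
    if len(table) == 0:
        raise ValueError("refusing to write an empty risk surface")
    geo_ids = {g.area_id for g in geometries}
    surf_ids = set(table["area_id"].astype(str))
    if geo_ids != surf_ids:
        raise ValueError(
            "surface/geometry area_id mismatch: "
            f"only in surface {sorted(surf_ids - geo_ids)[:5]}, "
            f"only in geometry {sorted(geo_ids - surf_ids)[:5]}"
        )

    props: dict[str, dict] = {}
    for (aid,), grp in table.groupby(["area_id"]):
        d: dict[str, float] = {}
        for _, row in grp.iterrows():
            y = int(row["year"])
            d[f"rr_{y}"] = float(row["rr_mean"])
            d[f"rr_lo_{y}"] = float(row["rr_lo"])
            d[f"rr_hi_{y}"] = float(row["rr_hi"])
            d[f"pep_{y}"] = float(row["pep"])
        props[str(aid)] = d

    out_path = Path(out_path)
    gj_path = out_path if out_path.suffix == ".geojson" else out_path.with_suffix(".geojson")
    csv_path = gj_path.with_suffix(".csv")
    write_geojson(geometries, gj_path, properties=props)
    table.to_csv(csv_path, index=False)
    return gj_path, csv_path
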