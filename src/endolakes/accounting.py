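"""Surface-water area accounting and human-use series construction.

Fraction maps are summarized inside digitized, functionally classified
polygons. A pixel counts as inundated (at its full footprint) when its water
fraction is at or above the 10% threshold; pixels below the threshold
contribute nothing. Excluded-class polygons (reservoirs, salt evaporation
ponds, livestock ponds) override every other class so extraneous water bodies
never enter the series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import CubicSpline
from shapely.geometry import shape as geojson_shape, mapping as geojson_mapping
from shapely.geometry.base import BaseGeometry

from .core import GridGeometry, SpectralImage, anchors_from_mapping
from .endmembers import IndexGrid, compute_index
from .unmix import FractionMap

log = logging.getLogger(__name__)

#: Functional polygon classes. ``excluded`` filters extraneous water bodies.
POLYGON_CLASSES = ("lake", "wetland", "peripheral_wetland", "field", "excluded")

#: Integer label codes; 0 is unlabeled background.
LABEL_CODES: dict[str, int] = {cls: i + 1 for i, cls in enumerate(POLYGON_CLASSES)}
CODE_LABELS: dict[int, str] = {v: k for k, v in LABEL_CODES.items()}
UNLABELED = 0

#: Classes whose inundated area is reported.
WATER_CLASSES = ("lake", "wetland", "peripheral_wetland")

M2_PER_HA = 10_000.0

#: Inclusive water-fraction threshold: pixels below 10% water are omitted.
WATER_FRACTION_THRESHOLD = 0.10

#: Strict NDVI threshold above which a field pixel counts as irrigated.
IRRIGATION_NDVI_THRESHOLD = 0.4

#: Annual max-NDVI window (month, day) bounds: 1 February - 30 November.
NDVI_WINDOW = ((2, 1), (11, 30))


@dataclass
class ClassedPolygon:
    """A polygon with its functional class and optional subtype note."""

    geom: BaseGeometry
    cls: str
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in POLYGON_CLASSES:
            raise ValueError(
                f"class {self.cls!r} not in vocabulary {POLYGON_CLASSES}"
            )
        if not self.geom.is_valid:
            raise ValueError(f"invalid (self-intersecting?) {self.cls} polygon")


@dataclass
class PolygonSet:
    """Digitized lake / wetland / field / excluded polygons for a watershed."""

    polygons: list[ClassedPolygon] = field(default_factory=list)

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def of_class(self, cls: str) -> list[ClassedPolygon]:
        return [p for p in self.polygons if p.cls == cls]

    def geoms(self, cls: str) -> list[BaseGeometry]:
        return [p.geom for p in self.of_class(cls)]

    # ----- GeoJSON persistence -----

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": geojson_mapping(p.geom),
                "properties": {"class": p.cls, "subtype": p.subtype},
            }
            for p in self.polygons
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PolygonSet":
        data = json.loads(Path(path).read_text())
        polys = [
            ClassedPolygon(
                geom=geojson_shape(feat["geometry"]),
                cls=feat["properties"]["class"],
                subtype=feat["properties"].get("subtype"),
            )
            for feat in data["features"]
        ]
        return cls(polygons=polys)


def rasterize(
    polygons: PolygonSet,
    geometry: GridGeometry,
    shape: tuple[int, int],
) -> np.ndarray:
    """Label grid by pixel-center containment (boundary-inclusive, even-odd).

    Precedence: ``excluded`` polygons win any overlap; among the remaining
    classes the first polygon in list order wins.
    """
    xs, ys = geometry.pixel_centers(shape)
    points = shapely.points(xs, ys)
    labels = np.full(shape, UNLABELED, dtype=np.int8)
    for poly in polygons:
        if poly.cls == "excluded":
            continue
        inside = shapely.covers(poly.geom, points)
        labels[inside & (labels == UNLABELED)] = LABEL_CODES[poly.cls]
    for poly in polygons.of_class("excluded"):
        labels[shapely.covers(poly.geom, points)] = LABEL_CODES["excluded"]
    return labels


def water_area(
    fractions: FractionMap,
    labels: np.ndarray,
    threshold: float = WATER_FRACTION_THRESHOLD,
    pixel_area: float | None = None,
) -> dict[str, float]:
    """Inundated hectares per water class.

    A valid pixel contributes its full footprint when its water fraction is
    >= ``threshold`` (inclusive); excluded and unlabeled pixels contribute
    nothing.
    """
    if labels.shape != fractions.shape:
        raise ValueError(
            f"label grid {labels.shape} does not align with fractions {fractions.shape}"
        )
    if pixel_area is None:
        pixel_area = fractions.geometry.pixel_area
    water = fractions.band("water")
    inundated = fractions.valid & (water >= threshold)
    areas = {}
    for cls in WATER_CLASSES:
        n = int(np.count_nonzero(inundated & (labels == LABEL_CODES[cls])))
        areas[cls] = n * pixel_area / M2_PER_HA
    return areas


def max_ndvi_composite(
    images: Sequence[SpectralImage],
    window: tuple[tuple[int, int], tuple[int, int]] = NDVI_WINDOW,
) -> IndexGrid:
    """Per-pixel maximum NDVI over unmasked observations dated in the window."""
    if not images:
        raise ValueError("empty image list")
    (m0, d0), (m1, d1) = window
    selected = [
        im
        for im in images
        if im.date is not None and (m0, d0) <= (im.date.month, im.date.day) <= (m1, d1)
    ]
    if not selected:
        raise ValueError("no images dated within the NDVI window")
    best = np.full(selected[0].shape, -np.inf)
    any_valid = np.zeros(selected[0].shape, dtype=bool)
    for im in selected:
        grid = compute_index(im, "ndvi")
        update = grid.valid & (grid.values > best)
        best[update] = grid.values[update]
        any_valid |= grid.valid
    values = np.where(any_valid, best, np.nan)
    return IndexGrid(values=values, kind="ndvi", valid=any_valid)


def irrigated_area(
    max_ndvi: IndexGrid,
    labels: np.ndarray,
    threshold: float = IRRIGATION_NDVI_THRESHOLD,
    pixel_area: float = 900.0,
) -> float:
    """Hectares of field-labeled pixels with max NDVI strictly above threshold."""
    if labels.shape != max_ndvi.shape:
        raise ValueError("label grid does not align with NDVI grid")
    fields = labels == LABEL_CODES["field"]
    irrigated = fields & max_ndvi.valid & (max_ndvi.values > threshold)
    return float(np.count_nonzero(irrigated)) * pixel_area / M2_PER_HA


def population_series(
    anchors: Mapping[int, float],
    years: Iterable[int],
    watershed_area_km2: float,
) -> pd.DataFrame:
    """Natural cubic spline through sparse population anchors.

    Evaluated at integer years; beyond the last anchor the terminal cubic is
    continued. Density is persons per km^2.
    """
    if watershed_area_km2 <= 0:
        raise ValueError("watershed area must be positive")
    ax, ay = anchors_from_mapping(anchors)
    if len(ax) < 4:
        raise ValueError("population interpolation needs at least 4 anchors")
    spline = CubicSpline(ax, ay, bc_type="natural", extrapolate=True)
    yrs = np.array(sorted(set(int(y) for y in years)))
    pop = spline(yrs)
    return pd.DataFrame(
        {
            "year": yrs,
            "population": pop,
            "density_km2": pop / watershed_area_km2,
        }
    )


def build_series(
    watershed: str,
    region: str,
    water_by_year: Mapping[int, Mapping[str, float]],
    irrigated_by_year: Mapping[int, float],
    population: pd.DataFrame,
    watershed_area_ha: float,
    years: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble aligned annual surface-water and human-use tables.

    Years absent from the inputs (e.g. the 2012 satellite gap) appear as rows
    with NaN areas rather than being dropped. Returns
    ``(surface_water, human_use)`` data frames.
    """
    if region not in ("snowmelt", "monsoonal"):
        raise ValueError(f"region must be snowmelt or monsoonal, got {region!r}")
    obs_years = sorted(water_by_year)
    if len(obs_years) != len(set(obs_years)):
        raise ValueError("duplicate year entries")
    if years is None:
        years = range(min(obs_years), max(obs_years) + 1)
    years = sorted(set(int(y) for y in years))

    water_rows = []
    for year in years:
        areas = water_by_year.get(year)
        for cls in WATER_CLASSES:
            water_rows.append(
                {
                    "watershed": watershed,
                    "region": region,
                    "year": year,
                    "class": cls,
                    "area_ha": float(areas[cls]) if areas is not None else np.nan,
                }
            )
    water_df = pd.DataFrame(water_rows)

    pop = population.set_index("year")
    human_rows = []
    for year in years:
        irr = irrigated_by_year.get(year, np.nan)
        human_rows.append(
            {
                "watershed": watershed,
                "year": year,
                "irrigated_ha": irr,
                "irrigated_frac": irr / watershed_area_ha,
                "population": pop["population"].get(year, np.nan),
                "density_km2": pop["density_km2"].get(year, np.nan),
            }
        )
    human_df = pd.DataFrame(human_rows)
    n_missing = int(water_df["area_ha"].isna().sum() // len(WATER_CLASSES))
    if n_missing:
        log.info("%s: %d year(s) missing from surface-water series", watershed, n_missing)
    return water_df, human_df
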