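"""Synthetic endorheic-watershed generator.

Builds a desk-scale stand-in for a 35-year annual satellite record: per-year
multispectral scenes rendered from known ("truth") endmember-fraction grids,
functional polygons, truth area tables, climate series, and human water-use
series, all coupled the way the downstream analysis assumes.

Two hydrologic regimes are emulated:

* ``snowmelt`` — lake proportion follows a strong linear decline with modest
  interannual variance; ET drifts upward; SWE is substantial.
* ``monsoonal`` — lake proportion has no trend but high interannual variance;
  SWE is essentially zero.

Wetland inundation is linearly coupled (with noise) to configurable
predictors — by default the irrigated fraction — so attribution has a
recoverable dominant driver. The rendered scene for a fixed seed is
byte-identical across runs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .accounting import (
    ClassedPolygon,
    PolygonSet,
    population_series,
    rasterize,
    water_area,
)
from .core import (
    DEFAULT_BANDS,
    ENDMEMBER_NAMES,
    EndmemberLibrary,
    GridGeometry,
    SpectralImage,
    QA_CLOUD,
    QA_VALID,
)
from .unmix import FractionMap

REGIMES = ("snowmelt", "monsoonal")

# Reference spectra (6 bands) jittered per seed by make_library.
_BASE_SPECTRA = np.array(
    [
        [0.06, 0.09, 0.05, 0.03, 0.02, 0.01],  # water: dark, falls off in NIR/SWIR
        [0.04, 0.08, 0.05, 0.50, 0.25, 0.12],  # wetland vegetation: NIR plateau
        [0.12, 0.16, 0.20, 0.28, 0.32, 0.30],  # upland shrub/soil
        [0.35, 0.42, 0.48, 0.52, 0.55, 0.50],  # alkali soil: bright across bands
    ]
)

# Pure-surface fraction vectors (water, vegetation, upland, alkali).
_SURFACES = {
    "upland": (0.0, 0.0, 1.0, 0.0),
    "alkali": (0.0, 0.0, 0.0, 1.0),
    "water": (1.0, 0.0, 0.0, 0.0),
    "veg": (0.0, 1.0, 0.0, 0.0),
    "wet_wetland": (0.6, 0.4, 0.0, 0.0),
    "dry_wetland": (0.0, 0.5, 0.5, 0.0),
    "periph_wet": (0.6, 0.4, 0.0, 0.0),
    "periph_dry": (0.0, 0.4, 0.6, 0.0),
    "field_irr": (0.0, 0.85, 0.15, 0.0),
    "field_dry": (0.0, 0.1, 0.9, 0.0),
}

POPULATION_ANCHOR_YEARS = (1975, 1990, 2000, 2015)


def make_library(seed: int, n_bands: int = 6) -> EndmemberLibrary:
    """Seeded endmember library with plausible spectral shapes in [0, 1].

    Bands beyond the 6 reference bands are linearly interpolated; jitter is
    +/-0.02 uniform per element so different seeds give distinct spectra.
    """
    if n_bands < 4:
        raise ValueError("need at least 4 bands")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE17)))
    if n_bands == 6:
        base = _BASE_SPECTRA
        band_names = DEFAULT_BANDS
    else:
        pos = np.linspace(0, 5, n_bands)
        base = np.stack([np.interp(pos, np.arange(6), row) for row in _BASE_SPECTRA])
        band_names = tuple(
            DEFAULT_BANDS[i] if i < 6 else f"b{i + 1}" for i in range(n_bands)
        )
    spectra = np.clip(base + rng.uniform(-0.02, 0.02, base.shape), 0.0, 1.0)
    return EndmemberLibrary(
        spectra=spectra,
        band_names=band_names,
        names=ENDMEMBER_NAMES,
        provenance={name: f"synthetic seed={seed}" for name in ENDMEMBER_NAMES},
    )


def render_scene(
    truth_fractions: np.ndarray,
    library: EndmemberLibrary,
    noise_sd: float = 0.0,
    cloud_fraction: float = 0.0,
    seed: int | None = None,
    date: dt.date | None = None,
    geometry: GridGeometry | None = None,
) -> SpectralImage:
    """Render a scene by the linear mixing model plus Gaussian band noise.

    Per pixel: reflectance = fractions . endmember spectra + N(0, noise_sd),
    clipped at zero. Cloud pixels are drawn i.i.d. Bernoulli(cloud_fraction)
    and flagged in the QA mask.
    """
    truth = np.asarray(truth_fractions, dtype=float)
    if truth.ndim != 3 or truth.shape[2] != library.n_endmembers:
        raise ValueError(
            f"truth grid must be (H, W, {library.n_endmembers}), got {truth.shape}"
        )
    if (truth < -1e-12).any():
        raise ValueError("fraction vectors must be nonnegative")
    sums = truth.sum(axis=2)
    if np.abs(sums - 1).max() > 1e-9:
        raise ValueError("fraction vectors must sum to 1 (simplex constraint)")
    if not 0 <= cloud_fraction < 1:
        raise ValueError("cloud_fraction must be in [0, 1); all-cloud scenes carry no data")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    cube = truth @ library.spectra  # (H, W, B)
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, cube.shape)
    cube = np.clip(cube, 0.0, None)
    qa = np.where(
        rng.random(truth.shape[:2]) < cloud_fraction, QA_CLOUD, QA_VALID
    ).astype(np.uint8)
    bands = {name: np.ascontiguousarray(cube[..., i]) for i, name in enumerate(library.band_names)}
    return SpectralImage(
        bands=bands, qa=qa, date=date, geometry=geometry or GridGeometry()
    )


def render_all_cloud_scene(
    truth_fractions: np.ndarray,
    library: EndmemberLibrary,
    date: dt.date | None = None,
    geometry: GridGeometry | None = None,
) -> SpectralImage:
    """Boundary case: a scene whose every pixel is QA-masked."""
    truth = np.asarray(truth_fractions, dtype=float)
    cube = np.clip(truth @ library.spectra, 0.0, None)
    bands = {name: np.ascontiguousarray(cube[..., i]) for i, name in enumerate(library.band_names)}
    qa = np.full(truth.shape[:2], QA_CLOUD, dtype=np.uint8)
    return SpectralImage(bands=bands, qa=qa, date=date, geometry=geometry or GridGeometry())


@dataclass(frozen=True)
class RegimeParams:
    """Configuration of a synthetic watershed series."""

    regime: str
    seed: int
    n_years: int = 35
    start_year: int = 1984
    missing_years: tuple[int, ...] = (2012,)
    shape: tuple[int, int] = (64, 64)
    pixel_size: float = 30.0
    n_bands: int = 6
    p0: float = 0.75
    lake_trend: float = 0.0
    interannual_sd: float = 0.05
    ar1: float = 0.0
    cloud_fraction: float = 0.0
    noise_sd: float = 0.0
    coupling: Mapping[str, float] = field(default_factory=dict)
    wetland_base: float = 0.5
    wetland_sd: float = 0.04

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_years < 4:
            raise ValueError("need at least 4 years")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must lie in (-1, 1)")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_years))

    @property
    def scene_years(self) -> tuple[int, ...]:
        return tuple(y for y in self.years if y not in self.missing_years)


def snowmelt_params(seed: int, **overrides) -> RegimeParams:
    """Snowmelt regime: strong linear lake decline, modest variance."""
    defaults = dict(
        regime="snowmelt",
        seed=seed,
        p0=0.78,
        lake_trend=-0.016,
        interannual_sd=0.03,
        coupling={"irrigated_frac": 0.25},
        wetland_base=0.55,
        wetland_sd=0.04,
    )
    defaults.update(overrides)
    return RegimeParams(**defaults)


def monsoonal_params(seed: int, **overrides) -> RegimeParams:
    """Monsoonal regime: stable mean, high interannual variance."""
    defaults = dict(
        regime="monsoonal",
        seed=seed,
        p0=0.45,
        lake_trend=0.0,
        interannual_sd=0.22,
        coupling={"irrigated_frac": 0.25},
        wetland_base=0.40,
        wetland_sd=0.10,
    )
    defaults.update(overrides)
    return RegimeParams(**defaults)


@dataclass
class _Layout:
    """Pixel-space layout of synthetic surface features."""

    lake_center: tuple[float, float]
    basin_radius: float
    water_max_radius: float
    wetland: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    peripheral: tuple[int, int, int, int]
    fields: tuple[int, int, int, int]
    reservoir: tuple[int, int, int, int]
    upland_plot: tuple[int, int, int, int]
    alkali_plot: tuple[int, int, int, int]


def _make_layout(shape: tuple[int, int]) -> _Layout:
    h, w = shape
    if min(h, w) < 32:
        raise ValueError("synthetic grids need at least 32x32 pixels")
    cx, cy = 0.32 * w, 0.35 * h
    basin_r = 0.25 * min(h, w)
    water_r = 0.75 * basin_r

    def _box(r0, r1, c0, c1):
        return (round(r0 * h), round(r1 * h), round(c0 * w), round(c1 * w))

    ac = round(cx + 0.875 * basin_r)
    ar = round(cy)
    return _Layout(
        lake_center=(cx, cy),
        basin_radius=basin_r,
        water_max_radius=water_r,
        wetland=_box(0.06, 0.44, 0.66, 0.94),
        peripheral=_box(0.62, 0.81, 0.03, 0.22),
        fields=_box(0.84, 0.97, 0.06, 0.94),
        reservoir=_box(0.66, 0.78, 0.56, 0.70),
        upland_plot=(round(0.63 * h), round(0.63 * h) + 3, round(0.38 * w), round(0.38 * w) + 3),
        alkali_plot=(ar - 1, ar + 2, ac - 1, ac + 2),
    )


def _zone_mask(shape: tuple[int, int], zone: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = zone
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


def _zone_polygon(zone: tuple[int, int, int, int], ps: float):
    r0, r1, c0, c1 = zone
    return box(c0 * ps, r0 * ps, c1 * ps, r1 * ps)


@dataclass
class WatershedBundle:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    params: RegimeParams
    watershed_id: str
    geometry: GridGeometry
    library: EndmemberLibrary
    polygons: PolygonSet
    upland_plot: object
    alkali_plot: object
    labels: np.ndarray
    scenes: dict[int, SpectralImage]
    truth_fractions: dict[int, np.ndarray]
    truth_areas: pd.DataFrame
    climate: pd.DataFrame
    human: pd.DataFrame
    population_anchors: dict[int, float]

    @property
    def watershed_area_ha(self) -> float:
        h, w = self.params.shape
        return h * w * self.geometry.pixel_area / 10_000.0

    @property
    def watershed_area_km2(self) -> float:
        return self.watershed_area_ha / 100.0

    def truth_fraction_map(self, year: int) -> FractionMap:
        truth = self.truth_fractions[year]
        h, w, _ = truth.shape
        return FractionMap(
            fractions=truth.copy(),
            rmse=np.zeros((h, w)),
            valid=np.ones((h, w), dtype=bool),
            names=self.library.names,
            geometry=self.geometry,
        )


def _climate_tables(params: RegimeParams, rng: np.random.Generator) -> pd.DataFrame:
    t = np.arange(params.n_years, dtype=float)
    if params.regime == "snowmelt":
        et = 1100 + 2.2 * t + rng.normal(0, 45, params.n_years)
        pr = np.clip(380 - 1.5 * t + rng.normal(0, 95, params.n_years), 5, None)
        ro = np.clip(100 - 0.7 * t + rng.normal(0, 55, params.n_years), 0, None)
        swe = np.clip(310 - 1.4 * t + rng.normal(0, 130, params.n_years), 0, None)
    else:
        et = 1615 + 0.6 * t + rng.normal(0, 45, params.n_years)
        pr = np.clip(420 + rng.normal(0, 95, params.n_years), 5, None)
        ro = np.clip(25 + rng.normal(0, 13, params.n_years), 0, None)
        swe = np.clip(rng.normal(0, 0.12, params.n_years), 0, None)
    return pd.DataFrame(
        {"year": params.years, "ET": et, "PR": pr, "RO": ro, "SWE": swe}
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_series(params: RegimeParams, render_scenes: bool = True) -> WatershedBundle:
    """Generate a complete synthetic watershed bundle.

    ``render_scenes=False`` skips the (relatively costly) scene rendering and
    leaves ``scenes`` empty — useful for statistics-only experiments that work
    from the truth tables.
    """
    h, w = params.shape
    geometry = GridGeometry(pixel_size=params.pixel_size)
    layout = _make_layout(params.shape)
    ss = np.random.SeedSequence((params.seed, 0x5EED))
    (
        lib_seed, lake_seed, wet_seed, periph_seed, irr_seed,
        clim_seed, pop_seed, perm_seed, scene_seed,
    ) = ss.spawn(9)

    library = make_library(params.seed, params.n_bands)
    n_years = params.n_years
    years = np.array(params.years)
    t = np.arange(n_years, dtype=float)

    # --- lake proportion: trend + (optionally AR(1)) noise, clamped ---
    rng_lake = np.random.default_rng(lake_seed)
    innov = rng_lake.normal(0.0, params.interannual_sd, n_years)
    eps = np.empty(n_years)
    if params.ar1 != 0.0:
        scale = np.sqrt(1.0 - params.ar1**2)
        eps[0] = innov[0]
        for i in range(1, n_years):
            eps[i] = params.ar1 * eps[i - 1] + scale * innov[i]
    else:
        eps = innov
    p_lake = np.clip(params.p0 + params.lake_trend * t + eps, 0.02, 0.80)

    # --- climate ---
    climate = _climate_tables(params, np.random.default_rng(clim_seed))

    # --- irrigation (fraction of the field zone actually irrigated) ---
    rng_irr = np.random.default_rng(irr_seed)
    if params.regime == "snowmelt":
        irr_field = 0.55 + 0.002 * t + rng_irr.normal(0, 0.06, n_years)
    else:
        irr_field = 0.40 + 0.006 * t + rng_irr.normal(0, 0.06, n_years)
    irr_field = np.clip(irr_field, 0.02, 0.98)

    # --- population anchors and interpolated series ---
    rng_pop = np.random.default_rng(pop_seed)
    base = 3000.0 * (1.0 + 0.5 * rng_pop.random())
    growth = 0.015 + 0.01 * rng_pop.random()
    anchors = {
        y: float(round(base * np.exp(growth * (y - POPULATION_ANCHOR_YEARS[0]))))
        for y in POPULATION_ANCHOR_YEARS
    }
    area_km2 = h * w * geometry.pixel_area / 1e6
    pop_years = range(POPULATION_ANCHOR_YEARS[0], params.years[-1] + 1)
    population = population_series(anchors, pop_years, area_km2)

    # --- zone bookkeeping (fixed across years) ---
    rng_perm = np.random.default_rng(perm_seed)
    wet_mask = _zone_mask(params.shape, layout.wetland)
    wet_idx = np.flatnonzero(wet_mask.ravel())
    wet_idx = rng_perm.permutation(wet_idx)
    n_core = int(round(0.11 * len(wet_idx)))
    veg_core_idx = wet_idx[:n_core]
    wet_dyn_idx = wet_idx[n_core:]

    periph_mask = _zone_mask(params.shape, layout.peripheral)
    periph_idx = rng_perm.permutation(np.flatnonzero(periph_mask.ravel()))

    field_mask = _zone_mask(params.shape, layout.fields)
    field_idx = rng_perm.permutation(np.flatnonzero(field_mask.ravel()))

    reservoir_mask = _zone_mask(params.shape, layout.reservoir)

    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    dist = np.hypot(gx - layout.lake_center[0], gy - layout.lake_center[1])
    lakebed = dist <= layout.basin_radius

    # --- wetland / peripheral wetted proportions ---
    irrigated_ha = np.round(irr_field * len(field_idx)) * geometry.pixel_area / 10_000.0
    irr_frac = irrigated_ha / (h * w * geometry.pixel_area / 10_000.0)
    density = (
        population.set_index("year")["density_km2"].reindex(years).to_numpy()
    )
    predictor_series = {
        "ET": climate["ET"].to_numpy(),
        "PR": climate["PR"].to_numpy(),
        "RO": climate["RO"].to_numpy(),
        "SWE": climate["SWE"].to_numpy(),
        "irrigated_frac": irr_frac,
        "density_km2": density,
    }
    rng_wet = np.random.default_rng(wet_seed)
    q_wet = np.full(n_years, params.wetland_base)
    for name, effect in params.coupling.items():
        if name not in predictor_series:
            raise ValueError(f"unknown coupling predictor {name!r}")
        q_wet = q_wet + effect * _zscore(predictor_series[name])
    q_wet = np.clip(q_wet + rng_wet.normal(0, params.wetland_sd, n_years), 0.02, 0.98)

    rng_periph = np.random.default_rng(periph_seed)
    q_periph = np.clip(
        0.15 + 0.8 * p_lake + rng_periph.normal(0, 0.04, n_years), 0.02, 0.98
    )
    has_peripheral = params.regime == "snowmelt"

    # --- polygons and labels ---
    ps = params.pixel_size
    lake_poly = Point(
        layout.lake_center[0] * ps, layout.lake_center[1] * ps
    ).buffer((layout.basin_radius + 0.25) * ps, quad_segs=128)
    polys = [ClassedPolygon(lake_poly, "lake")]
    polys.append(ClassedPolygon(_zone_polygon(layout.wetland, ps), "wetland"))
    if has_peripheral:
        polys.append(
            ClassedPolygon(_zone_polygon(layout.peripheral, ps), "peripheral_wetland")
        )
    polys.append(ClassedPolygon(_zone_polygon(layout.fields, ps), "field"))
    polys.append(
        ClassedPolygon(_zone_polygon(layout.reservoir, ps), "excluded", subtype="reservoir")
    )
    polygons = PolygonSet(polys)
    upland_plot = _zone_polygon(layout.upland_plot, ps)
    alkali_plot = _zone_polygon(layout.alkali_plot, ps)
    labels = rasterize(polygons, geometry, params.shape)

    # --- per-year truth fraction grids ---
    surfaces = {k: np.array(v) for k, v in _SURFACES.items()}
    truth_fractions: dict[int, np.ndarray] = {}
    for i, year in enumerate(params.years):
        truth = np.empty((h, w, 4))
        truth[:] = surfaces["upland"]
        truth[lakebed] = surfaces["alkali"]
        truth[dist <= layout.water_max_radius * np.sqrt(p_lake[i])] = surfaces["water"]

        flat = truth.reshape(-1, 4)
        flat[veg_core_idx] = surfaces["veg"]
        n_wet = int(round(q_wet[i] * len(wet_dyn_idx)))
        flat[wet_dyn_idx[:n_wet]] = surfaces["wet_wetland"]
        flat[wet_dyn_idx[n_wet:]] = surfaces["dry_wetland"]
        if has_peripheral:
            n_p = int(round(q_periph[i] * len(periph_idx)))
            flat[periph_idx[:n_p]] = surfaces["periph_wet"]
            flat[periph_idx[n_p:]] = surfaces["periph_dry"]
        n_irr = int(round(irr_field[i] * len(field_idx)))
        flat[field_idx[:n_irr]] = surfaces["field_irr"]
        flat[field_idx[n_irr:]] = surfaces["field_dry"]
        truth = flat.reshape(h, w, 4)
        truth[reservoir_mask] = surfaces["water"]
        truth_fractions[year] = truth

    # --- truth area table (thresholded truth-fraction pixel counts) ---
    area_rows = []
    dummy_rmse = np.zeros((h, w))
    all_valid = np.ones((h, w), dtype=bool)
    for year in params.years:
        fm = FractionMap(
            fractions=truth_fractions[year],
            rmse=dummy_rmse,
            valid=all_valid,
            names=library.names,
            geometry=geometry,
        )
        areas = water_area(fm, labels)
        for cls, ha in areas.items():
            area_rows.append(
                {
                    "watershed": f"synthetic-{params.regime}",
                    "year": year,
                    "class": cls,
                    "area_ha": ha,
                    "scene_available": year not in params.missing_years,
                }
            )
    truth_areas = pd.DataFrame(area_rows)

    # --- human-use table ---
    human = pd.DataFrame(
        {
            "watershed": f"synthetic-{params.regime}",
            "year": years,
            "irrigated_ha": irrigated_ha,
            "irrigated_frac": irr_frac,
            "population": population.set_index("year")["population"].reindex(years).to_numpy(),
            "density_km2": density,
        }
    )
    climate = climate.assign(watershed=f"synthetic-{params.regime}")

    # --- rendered scenes (2012 and any other missing years absent) ---
    scenes: dict[int, SpectralImage] = {}
    if render_scenes:
        scene_children = scene_seed.spawn(len(params.scene_years))
        for child, year in zip(scene_children, params.scene_years):
            if params.regime == "snowmelt":
                date = dt.date(year, 7, 1)
            else:
                # mid-March sits inside both the Oct-Mar seasonal window and
                # the Feb-Nov annual max-NDVI window
                date = dt.date(year, 3, 15)
            scenes[year] = render_scene(
                truth_fractions[year],
                library,
                noise_sd=params.noise_sd,
                cloud_fraction=params.cloud_fraction,
                seed=child,
                date=date,
                geometry=geometry,
            )

    return WatershedBundle(
        params=params,
        watershed_id=f"synthetic-{params.regime}",
        geometry=geometry,
        library=library,
        polygons=polygons,
        upland_plot=upland_plot,
        alkali_plot=alkali_plot,
        labels=labels,
        scenes=scenes,
        truth_fractions=truth_fractions,
        truth_areas=truth_areas,
        climate=climate,
        human=human,
        population_anchors=anchors,
    )
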