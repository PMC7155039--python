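"""End-to-end pipeline: scenes -> composites -> endmembers -> fractions -> series."""

from __future__ import annotations

import pandas as pd

from .accounting import (
    build_series,
    irrigated_area,
    max_ndvi_composite,
    population_series,
    water_area,
)
from .endmembers import extract_library
from .synth import WatershedBundle
from .unmix import seasonal_composite, unmix_image


def run_bundle(
    bundle: WatershedBundle,
    use_true_library: bool = False,
    water_constraint: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full surface-water pipeline over a synthetic bundle.

    For each year with a scene: composite the (single-scene) seasonal window,
    derive an endmember library from the composite (or reuse the bundle's true
    library), unmix, and account areas inside the bundle polygons. Returns
    ``(surface_water, human_use)`` annual tables with missing years flagged.
    """
    params = bundle.params
    window = params.regime
    wetland_geoms = bundle.polygons.geoms("wetland")
    constraint = None
    if water_constraint:
        lakes = bundle.polygons.geoms("lake")
        constraint = lakes[0] if lakes else None

    water_by_year: dict[int, dict[str, float]] = {}
    irrigated_by_year: dict[int, float] = {}
    for year, scene in sorted(bundle.scenes.items()):
        composite = seasonal_composite([scene], window)
        if use_true_library:
            library = bundle.library
        else:
            library = extract_library(
                composite,
                wetland_polygons=wetland_geoms,
                upland_plot=bundle.upland_plot,
                alkali_plot=bundle.alkali_plot,
                water_constraint=constraint,
            )
        fractions = unmix_image(composite, library)
        water_by_year[year] = water_area(fractions, bundle.labels)
        ndvi = max_ndvi_composite([scene])
        irrigated_by_year[year] = irrigated_area(
            ndvi, bundle.labels, pixel_area=bundle.geometry.pixel_area
        )

    population = population_series(
        bundle.population_anchors,
        range(min(bundle.population_anchors), params.years[-1] + 1),
        bundle.watershed_area_km2,
    )
    return build_series(
        watershed=bundle.watershed_id,
        region=params.regime,
        water_by_year=water_by_year,
        irrigated_by_year=irrigated_by_year,
        population=population,
        watershed_area_ha=bundle.watershed_area_ha,
        years=params.years,
    )
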