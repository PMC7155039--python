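"""Training-endmember derivation from spectral-index percentile masks and plots.

Water endmembers come from top-percentile NDWI pixels (optionally constrained
to a lake polygon), wetland-vegetation endmembers from top-percentile NDVI
pixels inside wetland polygons, and upland / alkali-soil endmembers from small
static homogeneous plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

from .core import (
    DEFAULT_BANDS,
    EndmemberLibrary,
    SpectralImage,
    polygon_mask,
)

INDEX_KINDS = ("ndwi", "ndvi")


@dataclass
class IndexGrid:
    """A normalized-difference index grid with validity mask.

    ``values`` is NaN wherever ``valid`` is False (QA-masked source pixels or
    zero denominators).
    """

    values: np.ndarray
    kind: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in INDEX_KINDS:
            raise ValueError(f"kind must be one of {INDEX_KINDS}, got {self.kind!r}")
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        vals = self.values[self.valid]
        if vals.size and (np.abs(vals) > 1 + 1e-12).any():
            raise ValueError("normalized-difference values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_index(image: SpectralImage, kind: str) -> IndexGrid:
    """Per-pixel NDWI ((green-nir)/(green+nir)) or NDVI ((nir-red)/(nir+red)).

    Pixels that are QA-masked or have a zero denominator are invalid.
    """
    if kind == "ndwi":
        a, b = image.band("green"), image.band("nir")
    elif kind == "ndvi":
        a, b = image.band("nir"), image.band("red")
    else:
        raise ValueError(f"kind must be one of {INDEX_KINDS}, got {kind!r}")
    denom = a + b
    valid = image.valid_mask & (denom != 0)
    values = np.full(image.shape, np.nan)
    np.divide(a - b, denom, out=values, where=valid)
    return IndexGrid(values=values, kind=kind, valid=valid)


def percentile_mask(index: IndexGrid, q: float) -> np.ndarray:
    """Boolean grid selecting valid pixels at/above the q-th percentile of
    valid index values (linear interpolation of order statistics)."""
    if not 0 < q < 100:
        raise ValueError(f"q must be in (0, 100), got {q}")
    vals = index.values[index.valid]
    if vals.size == 0:
        raise ValueError("index grid has no valid pixels")
    threshold = np.percentile(vals, q)
    mask = np.zeros(index.shape, dtype=bool)
    mask[index.valid] = index.values[index.valid] >= threshold
    return mask


def extract_endmember(
    image: SpectralImage,
    mask: np.ndarray,
    band_names: Sequence[str] | None = None,
    agg: str = "mean",
) -> np.ndarray:
    """Band-wise mean (or median) reflectance over selected unmasked pixels."""
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    select = mask & image.valid_mask
    if not select.any():
        raise ValueError("mask selects no unmasked pixels")
    cube = image.stack(band_names)
    reducer = {"mean": np.mean, "median": np.median}[agg]
    return reducer(cube[select], axis=0)


def plot_endmember(
    image: SpectralImage,
    plot: BaseGeometry,
    band_names: Sequence[str] | None = None,
    agg: str = "mean",
) -> np.ndarray:
    """Band-wise mean over pixels whose centers fall inside a static plot."""
    mask = polygon_mask([plot], image.geometry, image.shape)
    if not mask.any():
        raise ValueError("no pixel centers fall inside the plot polygon")
    return extract_endmember(image, mask, band_names=band_names, agg=agg)


def extract_library(
    composite: SpectralImage,
    wetland_polygons: Iterable[BaseGeometry],
    upland_plot: BaseGeometry,
    alkali_plot: BaseGeometry,
    water_constraint: BaseGeometry | None = None,
    water_percentile: float = 99.0,
    vegetation_percentile: float = 95.0,
    agg: str = "mean",
) -> EndmemberLibrary:
    """Assemble a 4-endmember library from one seasonal composite.

    Water: pixels at/above ``water_percentile`` of NDWI, optionally restricted
    to a deep-lake constraint polygon. Wetland vegetation: pixels inside the
    supplied wetland polygons at/above ``vegetation_percentile`` of NDVI.
    Upland and alkali soil: static plot means.
    """
    band_names = composite.band_names

    ndwi = compute_index(composite, "ndwi")
    if water_constraint is not None:
        inside = polygon_mask([water_constraint], composite.geometry, composite.shape)
        ndwi = IndexGrid(
            values=np.where(inside, ndwi.values, np.nan),
            kind="ndwi",
            valid=ndwi.valid & inside,
        )
    water = extract_endmember(
        composite, percentile_mask(ndwi, water_percentile), band_names, agg
    )

    wet_mask = polygon_mask(wetland_polygons, composite.geometry, composite.shape)
    ndvi = compute_index(composite, "ndvi")
    ndvi_wet = IndexGrid(
        values=np.where(wet_mask, ndvi.values, np.nan),
        kind="ndvi",
        valid=ndvi.valid & wet_mask,
    )
    vegetation = extract_endmember(
        composite, percentile_mask(ndvi_wet, vegetation_percentile), band_names, agg
    )

    upland = plot_endmember(composite, upland_plot, band_names, agg)
    alkali = plot_endmember(composite, alkali_plot, band_names, agg)

    return EndmemberLibrary(
        spectra=np.stack([water, vegetation, upland, alkali]),
        band_names=band_names if band_names else DEFAULT_BANDS,
        provenance={
            "water": f"ndwi>=p{water_percentile:g}"
            + (" within constraint polygon" if water_constraint is not None else ""),
            "wetland_vegetation": f"ndvi>=p{vegetation_percentile:g} within wetland polygons",
            "upland": "static plot mean",
            "alkali_soil": "static plot mean",
        },
    )
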