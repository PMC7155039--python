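"""Core raster and spectral data structures shared across the pipeline.

Grids are plain numpy arrays in row-major (row, col) order. Geographic
placement is a simple planar affine: the center of pixel (row, col) sits at
``(origin_x + (col + 0.5) * pixel_size, origin_y + (row + 0.5) * pixel_size)``.
All reflectance values are surface-reflectance fractions in [0, 1]-ish range
(values may exceed 1 after noise; they are only required to be finite and
nonnegative).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

#: Default Landsat-like band ordering used throughout.
DEFAULT_BANDS: tuple[str, ...] = ("blue", "green", "red", "nir", "swir1", "swir2")

#: Canonical endmember ordering: water, wetland vegetation, upland, alkali soil.
ENDMEMBER_NAMES: tuple[str, ...] = ("water", "wetland_vegetation", "upland", "alkali_soil")

# QA codes; everything nonzero is excluded from analysis.
QA_VALID = 0
QA_CLOUD = 1
QA_SHADOW = 2
QA_SNOW_ICE = 3


@dataclass(frozen=True)
class GridGeometry:
    """Planar placement of a raster grid: origin and square pixel size (m)."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 30.0

    @property
    def pixel_area(self) -> float:
        """Pixel footprint in square meters."""
        return self.pixel_size * self.pixel_size

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate grids for a raster of ``shape``."""
        rows, cols = shape
        xs = self.origin_x + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.origin_y + (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.pixel_size == other.pixel_size
        )

    def __hash__(self) -> int:
        return hash((self.origin_x, self.origin_y, self.pixel_size))


@dataclass
class SpectralImage:
    """A multi-band surface-reflectance grid with a per-pixel QA mask.

    Parameters
    ----------
    bands:
        Mapping band name -> 2-D float array. All bands must share a shape.
    qa:
        Integer QA grid aligned with the bands; ``QA_VALID`` (0) marks usable
        pixels, any other code (cloud / shadow / snow-ice) is excluded.
    date:
        Acquisition (or composite) date; needed for seasonal windowing.
    geometry:
        Planar grid placement. Defaults to a 30 m grid at the origin.
    """

    bands: dict[str, np.ndarray]
    qa: np.ndarray
    date: dt.date | None = None
    geometry: GridGeometry = field(default_factory=GridGeometry)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("SpectralImage requires at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands have inconsistent shapes: {shapes}")
        (shape,) = shapes
        if self.qa.shape != shape:
            raise ValueError(f"qa shape {self.qa.shape} != band shape {shape}")
        for name, band in self.bands.items():
            finite = np.isfinite(band)
            if not finite.all():
                raise ValueError(f"band {name!r} contains non-finite values")
            if (band < 0).any():
                raise ValueError(f"band {name!r} contains negative reflectance")

    @property
    def shape(self) -> tuple[int, int]:
        return self.qa.shape

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid of pixels usable for analysis (QA == valid)."""
        return self.qa == QA_VALID

    @property
    def pixel_area(self) -> float:
        return self.geometry.pixel_area

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(
                f"image has no band {name!r}; available: {sorted(self.bands)}"
            ) from None

    def stack(self, band_names: Sequence[str] | None = None) -> np.ndarray:
        """Return an (H, W, B) cube in the requested band order."""
        names = tuple(band_names) if band_names is not None else self.band_names
        return np.stack([self.band(n) for n in names], axis=-1)


class RankDeficientLibraryError(ValueError):
    """Raised when an endmember set cannot support unmixing."""


@dataclass
class EndmemberLibrary:
    """Ordered named endmember spectra (rows) over named bands (columns)."""

    spectra: np.ndarray
    band_names: tuple[str, ...] = DEFAULT_BANDS
    names: tuple[str, ...] = ENDMEMBER_NAMES
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.band_names = tuple(self.band_names)
        self.names = tuple(self.names)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (endmember, band) array")
        n_end, n_bands = self.spectra.shape
        if n_end != len(self.names):
            raise ValueError(f"{n_end} spectra but {len(self.names)} names")
        if n_bands != len(self.band_names):
            raise ValueError(f"{n_bands} bands but {len(self.band_names)} band names")
        if not np.isfinite(self.spectra).all():
            raise ValueError("endmember spectra must be finite")
        if (self.spectra < 0).any():
            raise ValueError("endmember spectra must be nonnegative")
        for i in range(n_end):
            for j in range(i + 1, n_end):
                if np.array_equal(self.spectra[i], self.spectra[j]):
                    raise ValueError(
                        f"endmembers {self.names[i]!r} and {self.names[j]!r} are identical"
                    )
        if np.linalg.matrix_rank(self.spectra.T) < n_end:
            raise RankDeficientLibraryError(
                "mixing matrix is rank deficient; endmembers are not linearly independent"
            )

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    @property
    def mixing_matrix(self) -> np.ndarray:
        """(bands, endmembers) matrix M so that a mixed spectrum is M @ f."""
        return self.spectra.T

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[self.names.index(name)]

    def reordered(self, order: Sequence[int]) -> "EndmemberLibrary":
        order = list(order)
        return EndmemberLibrary(
            spectra=self.spectra[order],
            band_names=self.band_names,
            names=tuple(self.names[i] for i in order),
            provenance=dict(self.provenance),
        )

    # ----- persistence: CSV table + JSON sidecar for provenance -----

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = "endmember," + ",".join(self.band_names)
        lines = [header]
        for name, spec in zip(self.names, self.spectra):
            lines.append(name + "," + ",".join(f"{v:.10g}" for v in spec))
        path.write_text("\n".join(lines) + "\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"provenance": self.provenance}, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EndmemberLibrary":
        path = Path(path)
        lines = path.read_text().strip().splitlines()
        band_names = tuple(lines[0].split(",")[1:])
        names, rows = [], []
        for line in lines[1:]:
            parts = line.split(",")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        provenance: dict[str, str] = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            provenance = json.loads(sidecar.read_text()).get("provenance", {})
        return cls(
            spectra=np.array(rows),
            band_names=band_names,
            names=tuple(names),
            provenance=provenance,
        )


def polygon_mask(
    geoms: Iterable[BaseGeometry],
    geometry: GridGeometry,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean grid: True where the pixel center falls inside (or on the
    boundary of) any of ``geoms``."""
    xs, ys = geometry.pixel_centers(shape)
    mask = np.zeros(shape, dtype=bool)
    for geom in geoms:
        if geom.is_empty:
            continue
        mask |= shapely.covers(geom, shapely.points(xs, ys))
    return mask


def anchors_from_mapping(anchors: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    """Validate and sort year -> value anchors; reject duplicate years."""
    years = np.array(sorted(anchors), dtype=float)
    if len(years) != len(set(anchors)):
        raise ValueError("duplicate anchor years")
    values = np.array([anchors[int(y)] for y in years], dtype=float)
    return years, values
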