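"""Seasonal compositing and fully constrained least-squares (FCLS) unmixing.

Imagery inside a 6-month seasonal window is averaged per pixel/band (ignoring
QA-masked observations) into a single composite, which is then decomposed
per pixel into endmember fractions that are nonnegative and sum to one.

The FCLS solver uses the standard construction: nonnegative least squares on
the mixing matrix augmented with a sum-to-one row scaled by a large weight
delta = 1e3 * max|M|, followed by an exact renormalization of the fraction
vector (the residual sum-to-one error before renormalization is O(delta^-1)).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .core import EndmemberLibrary, GridGeometry, SpectralImage, QA_CLOUD, QA_VALID

#: Months composing each 6-month seasonal window.
SEASONAL_WINDOWS: dict[str, tuple[int, ...]] = {
    "snowmelt": (4, 5, 6, 7, 8, 9),  # April-September
    "monsoonal": (10, 11, 12, 1, 2, 3),  # October-March
}

#: Sum-to-one weight multiplier for the augmented NNLS system.
DELTA_SCALE = 1e3


def composite_year(date: dt.date, window: str) -> int:
    """Series-year label for an acquisition date.

    Monsoonal windows span the new year: October-December observations are
    labeled with the following calendar year, so the window labeled Y covers
    Oct Y-1 through Mar Y.
    """
    if window not in SEASONAL_WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    if window == "monsoonal" and date.month >= 10:
        return date.year + 1
    return date.year


def in_window(date: dt.date, window: str) -> bool:
    return date.month in SEASONAL_WINDOWS[window]


def seasonal_composite(
    images: Sequence[SpectralImage], window: str
) -> SpectralImage:
    """Average imagery dated within a seasonal window into one composite.

    Per pixel and band, the composite is the plain mean over observations not
    QA-masked; pixels masked in every observation are invalid (QA cloud) in
    the composite.
    """
    if window not in SEASONAL_WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    if not images:
        raise ValueError("empty image list")
    selected = [im for im in images if im.date is not None and in_window(im.date, window)]
    if not selected:
        raise ValueError(f"no images dated within the {window!r} window")

    first = selected[0]
    band_names = first.band_names
    for im in selected[1:]:
        if im.band_names != band_names:
            raise ValueError("images have inconsistent band sets")
        if im.shape != first.shape:
            raise ValueError("images have inconsistent shapes")
        if im.geometry != first.geometry:
            raise ValueError("images have inconsistent grid geometry")

    counts = np.zeros(first.shape)
    sums = {name: np.zeros(first.shape) for name in band_names}
    for im in selected:
        valid = im.valid_mask
        counts += valid
        for name in band_names:
            sums[name] += np.where(valid, im.band(name), 0.0)

    observed = counts > 0
    bands = {}
    for name in band_names:
        out = np.zeros(first.shape)
        np.divide(sums[name], counts, out=out, where=observed)
        bands[name] = out
    qa = np.where(observed, QA_VALID, QA_CLOUD).astype(np.uint8)
    date = max(im.date for im in selected)
    return SpectralImage(bands=bands, qa=qa, date=date, geometry=first.geometry)


@dataclass
class FractionMap:
    """Per-pixel endmember fraction vectors with residual RMSE.

    ``fractions`` has shape (H, W, n_endmembers) ordered as the library;
    invalid pixels carry NaN fractions and RMSE.
    """

    fractions: np.ndarray
    rmse: np.ndarray
    valid: np.ndarray
    names: tuple[str, ...]
    geometry: GridGeometry = field(default_factory=GridGeometry)

    def __post_init__(self) -> None:
        if self.fractions.shape[:2] != self.valid.shape or self.rmse.shape != self.valid.shape:
            raise ValueError("fraction/rmse/valid shapes are inconsistent")
        f = self.fractions[self.valid]
        if f.size:
            if (f < -1e-6).any() or (f > 1 + 1e-6).any():
                raise ValueError("valid fractions must lie in [0, 1]")
            if np.abs(f.sum(axis=-1) - 1).max() > 1e-6:
                raise ValueError("valid fraction vectors must sum to 1 within 1e-6")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def band(self, name: str) -> np.ndarray:
        """Fraction grid for one endmember (NaN where invalid)."""
        return self.fractions[..., self.names.index(name)]


def unmix_pixel(
    spectrum: np.ndarray, library: EndmemberLibrary
) -> tuple[np.ndarray, float]:
    """Fully constrained least-squares fractions for one spectrum.

    Minimizes ||spectrum - M f||_2 subject to f >= 0 and sum(f) = 1, and
    returns (fractions, residual RMSE over bands).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    M = library.mixing_matrix
    if spectrum.shape != (M.shape[0],):
        raise ValueError(
            f"spectrum length {spectrum.shape} does not match library bands {M.shape[0]}"
        )
    f = _fcls_solve(spectrum[None, :], M)[0]
    resid = spectrum - M @ f
    return f, float(np.sqrt(np.mean(resid**2)))


def _fcls_solve(spectra: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Vectorized-over-rows FCLS via sum-to-one-augmented NNLS."""
    delta = DELTA_SCALE * np.abs(M).max()
    n_end = M.shape[1]
    A = np.vstack([M, delta * np.ones((1, n_end))])
    out = np.empty((spectra.shape[0], n_end))
    b = np.empty(M.shape[0] + 1)
    b[-1] = delta
    for i, s in enumerate(spectra):
        b[:-1] = s
        f, _ = nnls(A, b)
        total = f.sum()
        if total > 0:
            f = f / total
        out[i] = f
    return out


def unmix_image(
    composite: SpectralImage,
    library: EndmemberLibrary,
    deduplicate: bool = True,
) -> FractionMap:
    """Apply FCLS to every valid pixel of a composite.

    Identical spectra are solved once when ``deduplicate`` is set — a large
    saving on noiseless synthetic scenes with few distinct surface states.
    """
    missing = set(library.band_names) - set(composite.band_names)
    if missing:
        raise ValueError(f"composite lacks library bands: {sorted(missing)}")

    valid = composite.valid_mask
    cube = composite.stack(library.band_names)
    h, w, _ = cube.shape
    fractions = np.full((h, w, library.n_endmembers), np.nan)
    rmse = np.full((h, w), np.nan)
    if valid.any():
        pixels = cube[valid]
        M = library.mixing_matrix
        if deduplicate:
            uniq, inverse = np.unique(pixels, axis=0, return_inverse=True)
            sols = _fcls_solve(uniq, M)[inverse]
        else:
            sols = _fcls_solve(pixels, M)
        resid = pixels - sols @ M.T
        fractions[valid] = sols
        rmse[valid] = np.sqrt(np.mean(resid**2, axis=1))
    return FractionMap(
        fractions=fractions,
        rmse=rmse,
        valid=valid.copy(),
        names=library.names,
        geometry=composite.geometry,
    )
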