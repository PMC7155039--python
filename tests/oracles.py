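"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the unmixing oracle is a
hierarchical exhaustive grid search over the probability simplex refined to a
final step of 1e-3 (the coarse 0.05 argmin of the strictly convex objective
lies within 0.10 of the optimum, so the +/-0.12 first refinement window
brackets it).
"""

from __future__ import annotations

import numpy as np


def simplex_grid(step: float) -> np.ndarray:
    """All 4-vectors on the probability simplex with coordinates k*step."""
    k = int(round(1 / step))
    pts = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            for l in range(k + 1 - i - j):
                pts.append((i * step, j * step, l * step, 1 - (i + j + l) * step))
    return np.array(pts)


_COARSE = None
_LEVELS = ((0.12, 0.01), (0.025, 0.0025), (0.006, 0.001))


def grid_fcls(spectrum: np.ndarray, mixing_matrix: np.ndarray) -> np.ndarray:
    """Simplex-grid minimizer of ||spectrum - M f||^2, final step 1e-3."""
    global _COARSE
    if _COARSE is None:
        _COARSE = simplex_grid(0.05)
    MT = mixing_matrix.T
    best = _COARSE[np.argmin(((_COARSE @ MT - spectrum) ** 2).sum(axis=1))]
    for window, step in _LEVELS:
        g = np.arange(-window, window + step / 2, step)
        cand = best[None, :3] + np.stack(np.meshgrid(g, g, g), axis=-1).reshape(-1, 3)
        f4 = 1 - cand.sum(axis=1)
        ok = (cand >= -1e-12).all(axis=1) & (f4 >= -1e-12)
        cand = np.column_stack([cand[ok], f4[ok]])
        best = cand[np.argmin(((cand @ MT - spectrum) ** 2).sum(axis=1))]
    return np.clip(best, 0.0, None)
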