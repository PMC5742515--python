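"""Synthetic stand-in reference EMD used only as a cross-check oracle.

No established third-party EMD implementation is available in this
environment, so the cross-check in the test suite compares against this
independently written textbook sifter instead.  It deliberately shares no
code with the package implementation: extrema come from
``scipy.signal.argrelextrema``, envelope knots are mirrored by separate
array arithmetic, and sifting runs a fixed number of iterations instead of
a convergence criterion.  EMD is convention-sensitive, so agreement is
asserted as high correlation of the leading IMFs, not equality.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


def _envelope(h: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    v = h[idx]
    ext_i = np.concatenate([-idx[:2][::-1], idx, 2 * (n - 1) - idx[-2:][::-1]])
    ext_v = np.concatenate([v[:2][::-1], v, v[-2:][::-1]])
    keep = np.concatenate([[True], np.diff(ext_i) > 0])
    return CubicSpline(ext_i[keep], ext_v[keep])(np.arange(n))


def reference_decompose(x: np.ndarray, max_imfs: int = 3,
                        n_sift: int = 4) -> list[np.ndarray]:
    """Fixed-iteration textbook EMD; returns the list of IMFs."""
    x = np.asarray(x, dtype=float)
    n = x.size
    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        h = residue.copy()
        ok = True
        for _ in range(n_sift):
            maxima = argrelextrema(h, np.greater)[0]
            minima = argrelextrema(h, np.less)[0]
            if len(maxima) < 2 or len(minima) < 2:
                ok = False
                break
            mean = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
            h = h - mean
        if not ok:
            break
        imfs.append(h)
        residue = residue - h
    return imfs
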