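"""Independent brute-force oracles used to cross-check production metrics."""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_gamma(
    ref: np.ndarray,
    ev: np.ndarray,
    dose_pct: float,
    dta_mm: float,
    threshold_pct: float,
    spacing,
    search_factor: float = 3.0,
    step_fraction: float = 1.0 / 3.0,
) -> np.ndarray:
    """Exhaustive per-voxel minimisation over a dense candidate lattice.

    Independent of the production path: plain voxel loop, manual trilinear
    interpolation, no early exit.  Candidates falling outside the grid are
    skipped.
    """
    norm = float(ref.max())
    dd = dose_pct / 100.0 * norm
    thr = threshold_pct / 100.0 * norm
    radius = search_factor * dta_mm
    step = dta_mm * step_fraction
    n = int(np.floor(radius / step))
    ax = step * np.arange(-n, n + 1)
    offs = np.array(list(itertools.product(ax, ax, ax)))
    offs = offs[(offs**2).sum(1) <= radius**2 + 1e-9]
    sp = np.asarray(spacing, float)
    dist2 = (offs**2).sum(1) / dta_mm**2
    shp = np.asarray(ref.shape)
    out = np.full(ref.shape, np.nan)
    for idx in np.ndindex(ref.shape):
        if ref[idx] < thr:
            continue
        ci = np.asarray(idx) + offs / sp
        ok = np.all((ci >= 0) & (ci <= shp - 1), axis=1)
        ci = ci[ok]
        b = np.floor(ci).astype(int)
        f = ci - b
        b1 = np.minimum(b + 1, shp - 1)
        de = np.zeros(len(ci))
        for cz in (0, 1):
            for cy in (0, 1):
                for cx in (0, 1):
                    w = (
                        (f[:, 0] if cz else 1 - f[:, 0])
                        * (f[:, 1] if cy else 1 - f[:, 1])
                        * (f[:, 2] if cx else 1 - f[:, 2])
                    )
                    zi = b1[:, 0] if cz else b[:, 0]
                    yi = b1[:, 1] if cy else b[:, 1]
                    xi = b1[:, 2] if cx else b[:, 2]
                    de += w * ev[zi, yi, xi]
        g2 = (de - ref[idx]) ** 2 / dd**2 + dist2[ok]
        out[idx] = np.sqrt(g2.min())
    return out
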