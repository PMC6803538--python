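"""Neurovascular coupling: lagged ERP-HbO cross-correlation surface.

For every EEG window length X (100-600 ms, 1 ms steps) the Pearson
correlation is computed between the grand-averaged ERP over [0, X] ms and an
equal-length HbO segment lagged Y ms behind it (Y on the fNIRS sampling grid,
0-3000 ms in 27 ms steps), per condition.  The high-correlation region is
where the minimum correlation over conditions exceeds a threshold (0.8); its
peak locates the neurovascular lag.

HbO is linearly interpolated onto the 1 ms grid before windowing; both
waveforms are single summary traces per condition (cross-channel mean by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_X_GRID_MS = np.arange(100, 601, 1)
DEFAULT_Y_GRID_MS = np.arange(0, 3001, 27)


def summary_waveform(grand_avg: np.ndarray) -> np.ndarray:
    """Reduce (conditions, channels, time) to (conditions, time) by channel mean."""
    grand_avg = np.asarray(grand_avg, dtype=float)
    if grand_avg.size == 0:
        raise ValueError("empty grand average")
    return grand_avg.mean(axis=-2)


def pearson_rows(windows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``windows`` and ``ref``; NaN if degenerate."""
    ref = np.asarray(ref, dtype=float)
    windows = np.asarray(windows, dtype=float)
    refc = ref - ref.mean()
    wc = windows - windows.mean(axis=1, keepdims=True)
    denom = np.sqrt((wc**2).sum(axis=1) * (refc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (wc @ refc) / denom
    scale = np.sqrt((windows**2).mean(axis=1).max() + (ref**2).mean() + 1e-300)
    tiny = 1e-12 * scale
    r[np.sqrt((wc**2).sum(axis=1)) < tiny] = np.nan
    if np.sqrt((refc**2).sum()) < tiny:
        r[:] = np.nan
    return r


@dataclass
class CorrelationSurface:
    x_ms: np.ndarray  # EEG window lengths
    y_ms: np.ndarray  # fNIRS lags
    r: np.ndarray  # (n_conditions, n_x, n_y)
    conditions: list[str]

    @property
    def r_min(self) -> np.ndarray:
        """Minimum over conditions (NaN wherever any condition is NaN)."""
        return np.min(self.r, axis=0)


def lag_surface(
    erp: np.ndarray,
    erp_times_s: np.ndarray,
    hbo: np.ndarray,
    hbo_times_s: np.ndarray,
    conditions: list[str] | None = None,
    x_grid_ms: np.ndarray = DEFAULT_X_GRID_MS,
    y_grid_ms: np.ndarray = DEFAULT_Y_GRID_MS,
) -> CorrelationSurface:
    """Compute the (condition, X, Y) Pearson surface.

    ``erp`` and ``hbo`` are (conditions, time) summary waveforms with their
    time axes in seconds relative to observation onset.  HbO must cover
    [0, max(Y) + max(X)] ms.
    """
    erp = np.atleast_2d(np.asarray(erp, dtype=float))
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    n_cond = erp.shape[0]
    if hbo.shape[0] != n_cond:
        raise ValueError("ERP and HbO must have the same number of conditions")
    conditions = conditions or [f"C{i}" for i in range(n_cond)]
    x_grid_ms = np.asarray(x_grid_ms, dtype=int)
    y_grid_ms = np.asarray(y_grid_ms, dtype=int)
    max_x, max_y = int(x_grid_ms.max()), int(y_grid_ms.max())

    need_ms = (max_x + max_y) / 1000.0
    if hbo_times_s[-1] + 1e-9 < need_ms:
        raise ValueError(
            f"HbO must extend to {need_ms} s after onset, has {hbo_times_s[-1]} s"
        )
    if erp_times_s[-1] + 1e-9 < max_x / 1000.0:
        raise ValueError("ERP does not cover the largest window length")

    # resample both to the 1 ms grid from onset
    t_erp_ms = np.arange(0, max_x)
    t_hbo_ms = np.arange(0, max_x + max_y + 1)
    erp_ms = np.stack(
        [np.interp(t_erp_ms / 1000.0, erp_times_s, erp[c]) for c in range(n_cond)]
    )
    hbo_ms = np.stack(
        [np.interp(t_hbo_ms / 1000.0, hbo_times_s, hbo[c]) for c in range(n_cond)]
    )

    r = np.full((n_cond, len(x_grid_ms), len(y_grid_ms)), np.nan)
    for ix, x in enumerate(x_grid_ms):
        idx = y_grid_ms[:, None] + np.arange(x)[None, :]
        for c in range(n_cond):
            r[c, ix] = pearson_rows(hbo_ms[c][idx], erp_ms[c][:x])
    if np.isnan(r).any():
        warnings.warn(
            "constant segments produced undefined correlations; entries set "
            "to NaN and excluded from region extraction",
            stacklevel=2,
        )
    return CorrelationSurface(x_grid_ms, y_grid_ms, r, list(conditions))


@dataclass
class HighCorrRegion:
    mask: np.ndarray  # (n_x, n_y), True where r_min > threshold
    peak_x_ms: int | None
    peak_y_ms: int | None
    peak_r: float | None
    threshold: float

    @property
    def empty(self) -> bool:
        return not self.mask.any()


def high_corr_region(
    surface: CorrelationSurface, threshold: float = 0.8
) -> HighCorrRegion:
    """Threshold the min-over-conditions surface and locate its peak.

    Peak is the argmax of r_min; ties broken by smallest Y, then smallest X.
    An all-NaN surface yields an empty region with a warning (not an error).
    """
    rmin = surface.r_min
    with np.errstate(invalid="ignore"):
        mask = rmin > threshold
    if np.all(np.isnan(rmin)):
        warnings.warn("correlation surface is entirely undefined", stacklevel=2)
        return HighCorrRegion(mask, None, None, None, threshold)
    best = np.nanmax(rmin)
    ties = np.argwhere(rmin == best)  # rows: (ix, iy)
    order = np.lexsort((ties[:, 0], ties[:, 1]))  # smallest Y, then X
    ix, iy = ties[order[0]]
    if not mask.any():
        warnings.warn(
            f"no region exceeds threshold {threshold}; peak still reported",
            stacklevel=2,
        )
    return HighCorrRegion(
        mask=mask,
        peak_x_ms=int(surface.x_ms[ix]),
        peak_y_ms=int(surface.y_ms[iy]),
        peak_r=float(best),
        threshold=threshold,
    )
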