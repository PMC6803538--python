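"""Sensor-level statistics: grand averages, channelwise ANOVA with
Bonferroni post hocs, HbO observation-vs-baseline t-tests, topographic maps.

Window-mean amplitudes are the unit of analysis: for each trial and channel
the signal is averaged over the analysis window (350-400 ms for the ERP,
0-3.5 s for HbO) and the per-trial means are compared across the three
conditions with a one-way ANOVA; pairwise post hoc t-tests are
Bonferroni-corrected over the three comparisons.  The HbO block t-test
contrasts the mean around each probe time (1-5 s) against the mean of the
pre-observation baseline block, paired over trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import interpolate, spatial, stats

from .preprocessing import EpochSet


class DegenerateDataError(ValueError):
    """Raised when inputs have no variance where a test requires some."""


@dataclass
class ChannelStatResult:
    """Per-channel one-way ANOVA (or t-test) results."""

    statistic: np.ndarray  # (n_channels,)
    p: np.ndarray
    df: tuple[float, float]
    posthoc_p: np.ndarray | None  # (n_channels, n_pairs), Bonferroni-corrected
    pairs: list[tuple[str, str]] | None
    significant: np.ndarray
    alpha: float


@dataclass
class TopoMap:
    grid: np.ndarray  # (grid_n, grid_n), NaN outside the channel hull
    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    channel_xy: np.ndarray
    values_at_channels: np.ndarray


def grand_average(epochs: EpochSet) -> tuple[list[str], np.ndarray]:
    """Mean over trials within condition -> (conditions, cond x ch x time)."""
    conds = epochs.conditions()
    if not conds:
        raise DegenerateDataError("no trials to average")
    out = np.stack(
        [epochs.data[epochs.labels == c].mean(axis=0) for c in conds], axis=0
    )
    return conds, out


def bonferroni(p_raw: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_corr = min(1, m * p_raw)."""
    p_raw = np.asarray(p_raw, dtype=float)
    m = m if m is not None else p_raw.shape[-1]
    return np.minimum(1.0, m * p_raw)


def channel_anova(
    epochs: EpochSet,
    window_s: tuple[float, float],
    alpha: float = 0.001,
) -> ChannelStatResult:
    """One-way ANOVA of per-trial window means across conditions, per channel."""
    conds = epochs.conditions()
    if len(conds) < 2:
        raise DegenerateDataError("ANOVA needs at least two conditions")
    mask = epochs.time_mask(*window_s)
    if not mask.any():
        raise DegenerateDataError(f"window {window_s} contains no samples")
    means = epochs.data[:, :, mask].mean(axis=2)  # (trials, channels)
    groups = [means[epochs.labels == c] for c in conds]
    for g, c in zip(groups, conds):
        if len(g) < 2:
            raise DegenerateDataError(f"condition {c} has fewer than 2 trials")
    if all(np.allclose(g.var(axis=0), 0.0) for g in groups):
        raise DegenerateDataError("zero within-group variance in all groups")

    f, p = stats.f_oneway(*groups, axis=0)
    n_total = sum(len(g) for g in groups)
    df = (len(conds) - 1, n_total - len(conds))

    pairs = list(combinations(conds, 2))
    raw = np.empty((means.shape[1], len(pairs)))
    for j, (a, b) in enumerate(pairs):
        ga, gb = means[epochs.labels == a], means[epochs.labels == b]
        raw[:, j] = stats.ttest_ind(ga, gb, axis=0).pvalue
    posthoc = bonferroni(raw, len(pairs))
    return ChannelStatResult(
        statistic=np.asarray(f),
        p=np.asarray(p),
        df=df,
        posthoc_p=posthoc,
        pairs=pairs,
        significant=np.asarray(p) < alpha,
        alpha=alpha,
    )


def hbo_block_ttest(
    epochs: EpochSet,
    times_s: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
    window_halfwidth_s: float = 0.5,
    baseline_window_s: tuple[float, float] | None = None,
    alpha: float = 0.05,
) -> dict[float, ChannelStatResult]:
    """Paired t-test of observation-window vs baseline-block trial means.

    The observation value at probe time t is the trial mean over
    [t - halfwidth, t + halfwidth]; the baseline is the trial mean over the
    epoch's baseline block.  Returns one per-channel result per probe time.
    """
    if epochs.n_trials < 2:
        raise DegenerateDataError("paired t-test needs at least 2 trials")
    base_win = baseline_window_s or epochs.baseline_window_s
    if base_win is None:
        raise DegenerateDataError("no baseline window available")
    bmask = epochs.time_mask(*base_win)
    baseline = epochs.data[:, :, bmask].mean(axis=2)
    out: dict[float, ChannelStatResult] = {}
    for t in times_s:
        omask = epochs.time_mask(t - window_halfwidth_s, t + window_halfwidth_s)
        if not omask.any():
            raise DegenerateDataError(f"probe window at {t} s has no samples")
        obs = epochs.data[:, :, omask].mean(axis=2)
        res = stats.ttest_rel(obs, baseline, axis=0)
        out[float(t)] = ChannelStatResult(
            statistic=np.asarray(res.statistic),
            p=np.asarray(res.pvalue),
            df=(1.0, float(epochs.n_trials - 1)),
            posthoc_p=None,
            pairs=None,
            significant=np.asarray(res.pvalue) < alpha,
            alpha=alpha,
        )
    return out


def topo_interpolate(
    values: np.ndarray, channel_xy: np.ndarray, grid_n: int = 64
) -> TopoMap:
    """Scattered linear interpolation of per-channel values onto a grid.

    The grid spans the channel bounding box; points outside the channel
    convex hull are NaN (mask False).  Linear barycentric interpolation is
    exact at the channel sites and reproduces linear fields exactly.
    """
    values = np.asarray(values, dtype=float)
    channel_xy = np.asarray(channel_xy, dtype=float)
    if channel_xy.shape[0] < 3:
        raise DegenerateDataError("need at least 3 channels")
    try:
        spatial.ConvexHull(channel_xy)
    except spatial.QhullError as err:
        raise DegenerateDataError("channel layout is collinear") from err

    x = np.linspace(channel_xy[:, 0].min(), channel_xy[:, 0].max(), grid_n)
    y = np.linspace(channel_xy[:, 1].min(), channel_xy[:, 1].max(), grid_n)
    xx, yy = np.meshgrid(x, y)
    interp = interpolate.LinearNDInterpolator(channel_xy, values)
    grid = interp(xx, yy)
    at_sites = interp(channel_xy[:, 0], channel_xy[:, 1])
    return TopoMap(
        grid=grid,
        x=x,
        y=y,
        mask=~np.isnan(grid),
        channel_xy=channel_xy,
        values_at_channels=at_sites,
    )


def save_topomap_png(topo: TopoMap, path: str, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(topo.x, topo.y, topo.grid, shading="auto")
    ax.scatter(topo.channel_xy[:, 0], topo.channel_xy[:, 1], s=4, c="k")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=100)
    plt.close(fig)
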