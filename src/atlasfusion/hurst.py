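"""Rescaled-range (R/S) Hurst-exponent estimation for BOLD voxel series.

The Hurst exponent h quantifies long-range temporal dependence of a series:
h = 0.5 for memoryless (white) noise, h > 0.5 for persistent (positively
correlated) fluctuations, h < 0.5 for anti-persistent ones.  The classical
R/S estimator partitions the series into non-overlapping blocks of length n,
computes per block the range R of the mean-adjusted cumulative-sum profile
and the block standard deviation S, and regresses log(mean R/S) on log(n):
the slope is the estimate.  The estimator carries a positive small-sample
bias near h = 0.5 which shrinks with series length; tests and documentation
quote empirical tolerances rather than pretending it away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, PipelineError
from .timeseries import VoxelSeriesSet

logger = logging.getLogger(__name__)

__all__ = ["HurstEstimate", "default_window_sizes", "rs_hurst", "rs_hurst_batch", "hurst_map"]

MIN_SERIES_LENGTH = 32


@dataclass
class HurstEstimate:
    """R/S estimate with its log-log regression diagnostics."""

    h: float
    window_sizes: np.ndarray
    log_rs: np.ndarray
    fit_r2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.h < 2.0):
            logger.warning("Hurst estimate %.3f outside the nominal (0, 2) range", self.h)


def default_window_sizes(n_timepoints: int) -> np.ndarray:
    """Dyadic block-length ladder: powers of 2 from 8 up to n/2.

    E.g. 229 time points -> (8, 16, 32, 64); 1024 -> (8, ..., 512).
    """
    if n_timepoints < MIN_SERIES_LENGTH:
        raise ValueError(f"series too short for R/S: {n_timepoints} < {MIN_SERIES_LENGTH}")
    sizes = []
    w = 8
    while w <= n_timepoints // 2:
        sizes.append(w)
        w *= 2
    return np.asarray(sizes, dtype=int)


def _validate_windows(window_sizes, n: int) -> np.ndarray:
    sizes = np.asarray(window_sizes, dtype=int)
    if sizes.size < 2:
        raise ValueError("need at least two window sizes for the log-log fit")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("window sizes must be strictly increasing")
    if sizes[0] < 8 or sizes[-1] > n // 2:
        raise ValueError("window sizes must lie in [8, n_timepoints/2]")
    return sizes


def _mean_rs_per_window(data: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Mean R/S over non-overlapping blocks, per series (rows) and window.

    Blocks with zero standard deviation are skipped; a (series, window) cell
    with no valid block becomes NaN.  Trailing partial blocks are discarded.
    Block standard deviation uses the population (divide-by-n) convention.
    """
    n_series, n_time = data.shape
    out = np.full((n_series, sizes.size), np.nan)
    for j, w in enumerate(sizes):
        m = n_time // w
        blocks = data[:, : m * w].reshape(n_series, m, w)
        dev = blocks - blocks.mean(axis=2, keepdims=True)
        profile = np.cumsum(dev, axis=2)
        rng = profile.max(axis=2) - profile.min(axis=2)
        std = blocks.std(axis=2)
        valid = std > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            rs = np.where(valid, rng / np.where(valid, std, 1.0), np.nan)
        counts = valid.sum(axis=1)
        sums = np.where(valid, rs, 0.0).sum(axis=1)
        out[:, j] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def rs_hurst_batch(
    data: np.ndarray, window_sizes=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized R/S over many series at once.

    Parameters
    ----------
    data : (n_series, n_timepoints) array

    Returns
    -------
    h : (n_series,) slopes; NaN for degenerate (constant) series
    log_rs : (n_series, n_windows) mean log rescaled range
    fit_r2 : (n_series,) goodness of the log-log fit
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_time = data.shape[1]
    if n_time < MIN_SERIES_LENGTH:
        raise ValueError(f"series too short for R/S: {n_time} < {MIN_SERIES_LENGTH}")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in input series")
    sizes = (
        default_window_sizes(n_time)
        if window_sizes is None
        else _validate_windows(window_sizes, n_time)
    )
    mean_rs = _mean_rs_per_window(data, sizes)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rs = np.log(mean_rs)
    log_n = np.log(sizes.astype(float))
    h = np.full(data.shape[0], np.nan)
    r2 = np.full(data.shape[0], np.nan)
    complete = np.all(np.isfinite(log_rs), axis=1)
    if np.any(complete):
        y = log_rs[complete]
        xc = log_n - log_n.mean()
        slope = (y @ xc) / (xc @ xc)
        intercept = y.mean(axis=1)
        resid = y - (intercept[:, None] + np.outer(slope, xc))
        ss_tot = ((y - intercept[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_c = 1.0 - (resid**2).sum(axis=1) / ss_tot
        h[complete] = slope
        r2[complete] = r2_c
    # series with some S=0 blocks in every replicate of a window: fit on the
    # windows that survived, if at least two did
    partial = ~complete & (np.isfinite(log_rs).sum(axis=1) >= 2)
    for i in np.where(partial)[0]:
        ok = np.isfinite(log_rs[i])
        logger.warning("series %d: %d window size(s) skipped (zero-variance blocks)", i, (~ok).sum())
        coef = np.polyfit(log_n[ok], log_rs[i, ok], 1)
        h[i] = coef[0]
        fitted = np.polyval(coef, log_n[ok])
        ss_tot = ((log_rs[i, ok] - log_rs[i, ok].mean()) ** 2).sum()
        r2[i] = 1.0 - ((log_rs[i, ok] - fitted) ** 2).sum() / ss_tot if ss_tot > 0 else np.nan
    return h, log_rs, r2


def rs_hurst(series: np.ndarray, window_sizes=None) -> HurstEstimate:
    """Estimate the Hurst exponent of one series with the R/S method.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (every block has zero standard deviation).
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size and np.all(np.isfinite(series)) and series.max() == series.min():
        raise DegenerateSeriesError("constant series has no rescaled range")
    h, log_rs, r2 = rs_hurst_batch(series[None, :], window_sizes)
    if not np.isfinite(h[0]):
        raise DegenerateSeriesError("too few non-degenerate blocks for the log-log fit")
    sizes = (
        default_window_sizes(series.size)
        if window_sizes is None
        else np.asarray(window_sizes, dtype=int)
    )
    return HurstEstimate(h=float(h[0]), window_sizes=sizes, log_rs=log_rs[0], fit_r2=float(r2[0]))


def hurst_map(
    ts: VoxelSeriesSet, window_sizes=None, chunk_size: int = 4096
) -> np.ndarray:
    """Voxel-wise Hurst map on the mask grid.

    Degenerate voxels (constant series) become NaN and are counted in the
    log; if every voxel is degenerate the whole stage fails.
    """
    out = np.full(ts.grid_shape, np.nan)
    n_degenerate = 0
    n_total = ts.n_voxels
    for start in range(0, n_total, chunk_size):
        stop = min(start + chunk_size, n_total)
        h, _, _ = rs_hurst_batch(ts.data[start:stop], window_sizes)
        bad = ~np.isfinite(h)
        n_degenerate += int(bad.sum())
        idx = ts.mask_indices[start:stop]
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = h
    if n_degenerate == n_total:
        raise PipelineError("all voxels degenerate: no Hurst map produced")
    if n_degenerate:
        logger.warning("hurst_map: %d of %d voxels degenerate (set to NaN)", n_degenerate, n_total)
    return out
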