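"""Post-processing of already-normalized resting-state 4D fMRI.

The heavy spatial preprocessing (slice timing, realignment, normalization,
smoothing) is assumed done upstream; this module covers the light temporal
steps that precede Hurst-exponent estimation: discarding leading volumes,
nuisance regression, band-pass filtering, and voxel-series extraction under
a brain mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import GridMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelSeriesSet",
    "drop_initial_volumes",
    "regress_confounds",
    "bandpass",
    "linear_drift",
    "load_confounds",
]

#: Minimum series length: the R/S window ladder needs at least two window
#: sizes (8 and 16), hence 32 time points.
MIN_TIMEPOINTS = 32


@dataclass
class VoxelSeriesSet:
    """Masked voxel x time matrix with acquisition metadata.

    ``data`` holds one row per in-mask voxel; ``mask_indices`` maps rows back
    to (i, j, k) grid coordinates of a grid of shape ``grid_shape``.
    """

    data: np.ndarray
    mask_indices: np.ndarray
    tr_seconds: float
    grid_shape: tuple
    affine: np.ndarray | None = None
    n_dropped_initial: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.mask_indices = np.atleast_2d(np.asarray(self.mask_indices, dtype=int))
        if self.data.shape[0] != self.mask_indices.shape[0]:
            raise ValueError("one coordinate row per voxel row required")
        if self.n_timepoints < MIN_TIMEPOINTS:
            raise ValueError(
                f"need >= {MIN_TIMEPOINTS} time points, got {self.n_timepoints}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in voxel series")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    @classmethod
    def from_4d(
        cls,
        img,
        mask: np.ndarray,
        tr_seconds: float,
        *,
        drop_initial: int = 0,
    ) -> "VoxelSeriesSet":
        """Extract in-mask voxel series from a 4D image or array."""
        if isinstance(img, (str, Path)):
            img = nib.load(str(img))
        if hasattr(img, "dataobj"):
            data4d = np.asarray(img.dataobj, dtype=float)
            affine = np.asarray(img.affine, dtype=float)
        else:
            data4d = np.asarray(img, dtype=float)
            affine = None
        if data4d.ndim != 4:
            raise ValueError("expected a 4D (x, y, z, t) input")
        if drop_initial:
            data4d = drop_initial_volumes(data4d, drop_initial)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data4d.shape[:3]:
            raise GridMismatchError("mask shape does not match image grid")
        idx = np.argwhere(mask)
        return cls(
            data=data4d[mask],
            mask_indices=idx,
            tr_seconds=tr_seconds,
            grid_shape=data4d.shape[:3],
            affine=affine,
            n_dropped_initial=drop_initial,
        )


def drop_initial_volumes(series4d: np.ndarray, n: int) -> np.ndarray:
    """Discard the first ``n`` volumes (magnetization-equilibration scans)."""
    series4d = np.asarray(series4d)
    n_volumes = series4d.shape[-1]
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= n_volumes:
        raise ValueError(f"cannot drop {n} of {n_volumes} volumes")
    return series4d[..., n:]


def linear_drift(n_timepoints: int) -> np.ndarray:
    """Demeaned unit ramp used as the linear-drift nuisance regressor."""
    ramp = np.linspace(0.0, 1.0, n_timepoints)
    return ramp - ramp.mean()


def load_confounds(path: str | Path) -> np.ndarray:
    """Read a headered TSV of confound regressors (timepoints x k)."""
    frame = pd.read_csv(path, sep="\t")
    return frame.to_numpy(dtype=float)


def regress_confounds(ts: VoxelSeriesSet, confounds: np.ndarray) -> VoxelSeriesSet:
    """Replace each voxel series by its OLS residual against the confounds.

    The design matrix is ``[intercept, confounds]``; residuals are orthogonal
    to every confound column.  A rank-deficient design triggers a warning and
    a pseudo-inverse (minimum-norm) solve, which leaves the residuals
    unchanged relative to any other least-squares solution.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"confounds have {confounds.shape[0]} rows, series has "
            f"{ts.n_timepoints} time points"
        )
    design = np.column_stack([np.ones(ts.n_timepoints), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "confound matrix is rank deficient (rank %d of %d); using a "
            "pseudo-inverse solution",
            rank,
            design.shape[1],
        )
    beta = np.linalg.pinv(design) @ ts.data.T
    residuals = ts.data - (design @ beta).T
    return replace(ts, data=residuals)


def _fft_bandpass(data: np.ndarray, tr: float, low: float, high: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(data.shape[1], d=tr)
    keep = (freqs >= low) & (freqs <= high)
    spectrum = np.fft.rfft(data, axis=1)
    spectrum[:, ~keep] = 0.0
    return np.fft.irfft(spectrum, n=data.shape[1], axis=1)


def _butterworth_bandpass(
    data: np.ndarray, tr: float, low: float, high: float, order: int = 5
) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    nyq = 1.0 / (2.0 * tr)
    low_n = max(low / nyq, 1e-6)
    sos = butter(order, [low_n, high / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, data, axis=1)


def bandpass(
    ts: VoxelSeriesSet,
    low_hz: float = 0.01,
    high_hz: float = 0.10,
    method: str = "fft",
) -> VoxelSeriesSet:
    """Band-pass filter every voxel series.

    The default is a discrete-Fourier ideal (brick-wall) filter that zeroes
    all frequency bins outside ``[low_hz, high_hz]``, including the DC bin
    when ``low_hz > 0``; applying it twice is a no-op.  ``method="butterworth"``
    selects an order-5 zero-phase Butterworth alternative.
    """
    if not 0.0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > ts.nyquist_hz + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds Nyquist {ts.nyquist_hz:.4f} Hz at "
            f"TR={ts.tr_seconds} s"
        )
    if method == "fft":
        filtered = _fft_bandpass(ts.data, ts.tr_seconds, low_hz, high_hz)
    elif method == "butterworth":
        filtered = _butterworth_bandpass(ts.data, ts.tr_seconds, low_hz, high_hz)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return replace(ts, data=filtered)
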