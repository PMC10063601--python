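"""Voxelwise intrinsic neural timescale (INT) estimation.

The estimator follows the positive-autocorrelation-sum definition: compute
the sample autocorrelation function (ACF) of each voxel's BOLD time series
on a lag grid of TR multiples up to a maximum lag window (20 s by default),
sum the coefficients from lag 1 while they remain strictly positive, stop
at the first non-positive coefficient, and multiply the sum by the TR.  The
result is an index in seconds of how long signal fluctuations persist.

Lag spacing is in multiples of the repetition time rather than 1-second
bins: the index is ultimately scaled by the TR, so the natural lag grid is
the sampling grid itself.  Lag 0 is excluded from the sum by default (its
coefficient is identically 1 and carries no dynamics); an
``include_lag_zero`` flag is provided for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

__all__ = [
    "AcfProfile",
    "DegenerateSeriesError",
    "IntMap",
    "TimeSeries",
    "Volume4D",
    "int_from_acf",
    "int_map",
    "int_map_from_series",
    "load_volume",
    "sample_acf",
    "save_int_map",
]


class DegenerateSeriesError(ValueError):
    """Raised when a time series has zero variance (ACF undefined)."""


@dataclass(frozen=True)
class TimeSeries:
    """A single regularly sampled signal with its sampling interval.

    Parameters
    ----------
    values : array-like
        Signal samples, arbitrary units. Length must be at least 3.
    tr : float
        Sampling interval (repetition time) in seconds, strictly positive.
    """

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 3:
            raise ValueError("time series must be 1-D with length >= 3")
        if not np.isfinite(self.tr) or self.tr <= 0:
            raise ValueError(f"tr must be finite and positive, got {self.tr!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AcfProfile:
    """Sample autocorrelation coefficients on an integer lag grid.

    ``lags`` starts at 0 (where the coefficient is exactly 1) and increases
    in steps of one sample; coefficients lie in [-1, 1].
    """

    lags: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        coefficients = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "coefficients", coefficients)
        if lags.shape != coefficients.shape:
            raise ValueError("lags and coefficients must have equal length")
        if lags.size == 0:
            raise ValueError("ACF profile must be nonempty")
        if lags[0] != 0:
            raise ValueError("lag grid must start at 0")
        if not np.isclose(coefficients[0], 1.0):
            raise ValueError("coefficient at lag 0 must be 1")
        if np.any(np.abs(coefficients) > 1.0 + 1e-9):
            raise ValueError("autocorrelation coefficients must lie in [-1, 1]")


@dataclass
class Volume4D:
    """A 4D BOLD image: ``data[x, y, z, t]``, voxel-to-mm affine, and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("expected a 4-D array (x, y, z, t)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.isfinite(self.tr) or self.tr <= 0:
            raise ValueError(f"tr must be finite and positive, got {self.tr!r}")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class IntMap:
    """3-D map of INT values (seconds) on the grid of its source volume.

    Out-of-mask or unestimable voxels hold NaN. ``qc`` counts degenerate
    voxels (constant or non-finite series) and window-capped voxels (no
    non-positive ACF coefficient inside the lag window, so the positive sum
    was truncated by the window itself).
    """

    grid: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("INT grid must be 3-D")
        if self.grid.shape != self.mask.shape:
            raise ValueError("mask shape must match grid shape")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


def sample_acf(series: TimeSeries, max_lag_samples: int) -> AcfProfile:
    """Sample autocorrelation of ``series`` at lags 0..``max_lag_samples``.

    The estimator is the standard biased ("1/N") sample ACF with a single
    global mean removal:

        r_k = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2

    which guarantees |r_k| <= 1 and r_0 = 1.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (zero variance).
    ValueError
        If ``max_lag_samples`` is not in [1, len(series) - 1].
    """
    x = series.values
    if not np.all(np.isfinite(x)):
        raise DegenerateSeriesError("series contains non-finite samples")
    max_lag_samples = int(max_lag_samples)
    if max_lag_samples < 1 or max_lag_samples >= len(x):
        raise ValueError(
            f"max_lag_samples must be in [1, {len(x) - 1}], got {max_lag_samples}"
        )
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise DegenerateSeriesError("constant series has undefined ACF")
    coeffs = np.empty(max_lag_samples + 1)
    coeffs[0] = 1.0
    for k in range(1, max_lag_samples + 1):
        coeffs[k] = float(d[:-k] @ d[k:]) / denom
    return AcfProfile(lags=np.arange(max_lag_samples + 1), coefficients=coeffs)


def int_from_acf(
    acf: AcfProfile, tr: float, include_lag_zero: bool = False
) -> float:
    """Positive-ACF-sum timescale: walk lags upward from 1 (or 0 if
    ``include_lag_zero``), accumulate coefficients while strictly positive,
    stop at the first coefficient <= 0 or at the window end, and return the
    accumulated sum times ``tr`` (seconds).

    Returns 0.0 when the first inspected coefficient is already
    non-positive.
    """
    start = 0 if include_lag_zero else 1
    coeffs = acf.coefficients[start:]
    total = 0.0
    for c in coeffs:
        if c <= 0.0:
            break
        total += c
    return total * tr


def _acf_positive_sum_matrix(
    series_matrix: np.ndarray, max_lag: int
) -> tuple:
    """Vectorized positive-ACF sum for columns of a (T, V) matrix.

    Returns (sums, constant_mask, capped_mask): ``sums`` is the positive-run
    sum of ACF coefficients from lag 1 per column (NaN where degenerate);
    ``capped_mask`` marks columns whose run reached the window end without
    meeting a non-positive coefficient.
    """
    T, V = series_matrix.shape
    finite = np.all(np.isfinite(series_matrix), axis=0)
    x = np.where(finite[None, :], series_matrix, 0.0)
    d = x - x.mean(axis=0, keepdims=True)
    denom = np.einsum("tv,tv->v", d, d)
    degenerate = ~finite | (denom == 0.0)
    safe_denom = np.where(degenerate, 1.0, denom)
    coeffs = np.empty((max_lag, V))
    for k in range(1, max_lag + 1):
        coeffs[k - 1] = np.einsum("tv,tv->v", d[:-k], d[k:]) / safe_denom
    positive = coeffs > 0.0
    run = np.cumprod(positive, axis=0).astype(bool)  # True while run alive
    sums = np.where(run, coeffs, 0.0).sum(axis=0)
    capped = run[-1] & ~degenerate
    sums = np.where(degenerate, np.nan, sums)
    return sums, degenerate, capped


def int_map_from_series(
    series_matrix: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    tr: float,
    max_lag_seconds: float = 20.0,
    include_lag_zero: bool = False,
) -> IntMap:
    """Build an INT map from the in-mask voxel series directly.

    ``series_matrix`` is (T, V) with one column per in-mask voxel in
    C-order; this is the memory-lean entry point used both by
    :func:`int_map` and by simulators that never materialize a full 4-D
    array.
    """
    mask = np.asarray(mask, dtype=bool)
    tr = float(tr)
    max_lag = int(np.floor(max_lag_seconds / tr))
    if max_lag < 1:
        raise ValueError("max_lag_seconds must cover at least one TR")
    T = series_matrix.shape[0]
    if max_lag >= T:
        raise ValueError(
            f"lag window ({max_lag} samples) must be shorter than the series "
            f"({T} volumes)"
        )
    n_in_mask = int(mask.sum())
    if series_matrix.shape[1] != n_in_mask:
        raise ValueError("one series column per in-mask voxel required")
    grid = np.full(mask.shape, np.nan)
    qc = {
        "n_in_mask": n_in_mask,
        "n_degenerate": 0,
        "n_window_capped": 0,
        "max_lag_samples": max_lag,
    }
    if n_in_mask:
        sums, degenerate, capped = _acf_positive_sum_matrix(
            np.asarray(series_matrix, dtype=float), max_lag
        )
        if include_lag_zero:
            sums = sums + 1.0
        grid[mask] = sums * tr
        qc["n_degenerate"] = int(degenerate.sum())
        qc["n_window_capped"] = int(capped.sum())
    return IntMap(grid=grid, affine=np.asarray(affine, dtype=float), mask=mask, qc=qc)


def int_map(
    volume: Volume4D,
    mask: np.ndarray,
    max_lag_seconds: float = 20.0,
    include_lag_zero: bool = False,
) -> IntMap:
    """Estimate the INT of every in-mask voxel of a 4D volume.

    The lag window holds ``floor(max_lag_seconds / tr)`` lags in TR steps
    (42 lags for the default 20 s window at TR = 0.475 s).  Voxels whose
    series is constant or non-finite are recorded as NaN and counted in the
    QC log rather than raising.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume spatial shape "
            f"{volume.spatial_shape}"
        )
    return int_map_from_series(
        volume.data[mask].T, mask, volume.affine, volume.tr,
        max_lag_seconds=max_lag_seconds, include_lag_zero=include_lag_zero,
    )


def load_volume(
    path: Union[str, Path], tr_override: float | None = None
) -> Volume4D:
    """Load a 4D NIfTI-1 image. TR is taken from the header ``pixdim[4]``
    unless ``tr_override`` is given (headers are unreliable in the wild)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got shape {data.shape}")
    tr = float(tr_override) if tr_override is not None else float(img.header.get_zooms()[3])
    return Volume4D(data=data, affine=np.asarray(img.affine), tr=tr)


def save_int_map(imap: IntMap, path: Union[str, Path]) -> None:
    """Write an INT map as 3-D NIfTI-1; missing voxels encoded as NaN."""
    img = nib.Nifti1Image(imap.grid.astype(np.float32), imap.affine)
    nib.save(img, str(path))
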