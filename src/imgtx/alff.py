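"""Amplitude of low-frequency fluctuations (ALFF) and nuisance handling.

Per-voxel ALFF is the mean of the square-root power spectrum over a low
frequency band (default 0.01-0.08 Hz), standardized by its global mean over
the analysis mask.  Also provides Power-convention framewise displacement and
voxelwise nuisance regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesImage",
    "AlffConfig",
    "AlffMap",
    "mean_fd",
    "regress_nuisance",
    "compute_alff",
]

#: Sphere radius (mm) used to convert rotations to displacements (Power et al.).
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class TimeSeriesImage:
    """4D BOLD series with geometry.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, n_volumes)``.
    affine
        4x4 voxel-index -> mm affine.
    tr
        Repetition time in seconds.
    mask
        Boolean analysis mask, shape ``(nx, ny, nz)``.  ``None`` means all
        voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match data grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class AlffConfig:
    """Band and volume-handling settings for ALFF."""

    band_low: float = 0.01
    band_high: float = 0.08
    tr: float = 2.0
    drop_initial_volumes: int = 10

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0.0 <= self.band_low < self.band_high <= nyquist):
            raise ValueError(
                f"band [{self.band_low}, {self.band_high}] must satisfy "
                f"0 <= low < high <= Nyquist ({nyquist:g} Hz)"
            )
        if self.drop_initial_volumes < 0:
            raise ValueError("drop_initial_volumes must be >= 0")


@dataclass
class AlffMap:
    """Raw and globally standardized ALFF volumes."""

    raw: np.ndarray
    standardized: np.ndarray
    mask: np.ndarray
    config: AlffConfig = field(repr=False, default_factory=AlffConfig)


def mean_fd(motion_params: np.ndarray) -> float:
    """Mean framewise displacement (mm) from 6 rigid-body parameters.

    ``motion_params`` is ``(n_volumes, 6)``: three translations in mm followed
    by three rotations in radians.  FD at volume t is the sum of absolute
    backward differences, with rotations converted to arc length on a
    50 mm sphere; the mean is taken over the ``n_volumes - 1`` differences.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError(f"motion_params must be (n_volumes, 6), got {p.shape}")
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)
    return float(fd.mean())


def _design_matrix(n_volumes: int, confounds: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n_volumes), np.linspace(-1.0, 1.0, n_volumes)]
    if confounds is not None:
        c = np.atleast_2d(np.asarray(confounds, dtype=float))
        if c.shape[0] != n_volumes:
            if c.shape[1] == n_volumes:
                c = c.T
            else:
                raise ValueError(
                    f"confounds have {c.shape[0]} rows for {n_volumes} volumes"
                )
        cols.extend(c.T)
    return np.column_stack(cols)


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Greedily keep a maximal set of linearly independent columns."""
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    if len(keep) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        warnings.warn(
            f"design matrix rank-deficient; dropping columns {dropped}",
            RuntimeWarning,
            stacklevel=3,
        )
    return X[:, keep]


def regress_nuisance(
    series: TimeSeriesImage, confounds: np.ndarray | None = None
) -> TimeSeriesImage:
    """Residualize every voxel series against intercept, linear trend and
    the supplied per-volume confound columns.

    Rank-deficient designs are repaired by dropping collinear columns with a
    warning.  Returns a new :class:`TimeSeriesImage` of residuals.
    """
    n = series.n_volumes
    X = _design_matrix(n, confounds)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = _drop_collinear(X)
    Y = series.data.reshape(-1, n).T  # volumes x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(series.data.shape)
    return TimeSeriesImage(out, series.affine, series.tr, series.mask)


def amplitude_spectrum(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum ``sqrt(|DFT|^2 * 2 / N^2)``.

    DC and (for even N) the Nyquist bin are excluded.  Returns
    ``(frequencies_in_cycles_per_sample, amplitudes)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    spec = np.fft.rfft(x, axis=axis)
    amp = np.abs(spec) * np.sqrt(2.0) / n
    freqs = np.fft.rfftfreq(n)
    lo = 1  # drop DC
    hi = amp.shape[axis] - 1 if n % 2 == 0 else amp.shape[axis]  # drop Nyquist
    sl = [slice(None)] * amp.ndim
    sl[axis] = slice(lo, hi)
    return freqs[lo:hi], amp[tuple(sl)]


def compute_alff(
    series: TimeSeriesImage,
    cfg: AlffConfig | None = None,
    mask: np.ndarray | None = None,
) -> AlffMap:
    """Compute raw and standardized ALFF maps.

    The first ``cfg.drop_initial_volumes`` volumes are discarded; each voxel's
    amplitude spectrum is averaged over DFT bins ``f`` with
    ``band_low <= f <= band_high`` (inclusive, grid ``f_k = k/(N*TR)``); the
    raw map is divided by its mean over the mask to give the standardized map.
    """
    if cfg is None:
        cfg = AlffConfig(tr=series.tr)
    if mask is None:
        mask = series.mask
    if mask is None:
        mask = np.ones(series.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask shape does not match series grid")
    if not mask.any():
        raise ValueError("empty mask")

    data = series.data[..., cfg.drop_initial_volumes :]
    n = data.shape[-1]
    if n < 32:
        raise ValueError(f"need >= 32 volumes after dropping, got {n}")

    freqs_cyc, amp = amplitude_spectrum(data, axis=-1)
    freqs_hz = freqs_cyc / cfg.tr
    in_band = (freqs_hz >= cfg.band_low) & (freqs_hz <= cfg.band_high)
    if not in_band.any():
        raise ValueError("no DFT bins fall inside the requested band")
    raw = amp[..., in_band].mean(axis=-1)
    raw = np.where(mask, raw, 0.0)

    gmean = raw[mask].mean()
    if gmean <= 0:
        logger.warning("global mean ALFF is zero; standardized map set to zeros")
        standardized = np.zeros_like(raw)
    else:
        standardized = np.where(mask, raw / gmean, 0.0)
    return AlffMap(raw=raw, standardized=standardized, mask=mask, config=cfg)
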