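"""Variogram-matched spatially autocorrelated surrogate maps.

Surrogates randomize a spatial map while preserving its autocorrelation
fingerprint (the empirical variogram) and, optionally, its exact value
distribution.  They serve as the null for spatial correlations between maps
and for gene-map association permutation tests.

The construction: permute the map, smooth the permutation with an
exponentially decaying kernel over each point's k nearest neighbors, and fit
non-negative scalars (beta, alpha) so the variogram of
``sqrt(beta) * smoothed + sqrt(alpha) * white noise`` matches the target
variogram; the kernel size k is selected per surrogate by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Variogram",
    "SurrogateEnsemble",
    "empirical_variogram",
    "SurrogateMaps",
    "make_surrogates",
]

DEFAULT_KERNEL_FRACTIONS = (0.1, 0.2, 0.3, 0.4)


@dataclass
class Variogram:
    """Binned, kernel-smoothed semivariance vs. pairwise distance."""

    bin_centers: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if np.any(self.gamma < -1e-12):
            raise ValueError("gamma must be non-negative")


@dataclass
class SurrogateEnsemble:
    """A stack of surrogate maps plus per-surrogate diagnostics."""

    values: np.ndarray  # (n_surrogates, n_points)
    kernel_k: np.ndarray  # chosen neighborhood size per surrogate
    resampled: bool


def _bin_gamma(
    sq_diffs: np.ndarray, bin_idx: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sums = np.bincount(bin_idx, weights=sq_diffs, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = 0.5 * sums / counts
    return gamma, counts


def _smooth_bins(
    gamma: np.ndarray, counts: np.ndarray, centers: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian-kernel smoothing across distance bins, weighted by pair counts."""
    w = np.exp(-0.5 * ((centers[:, None] - centers[None, :]) / bandwidth) ** 2)
    w = w * counts[None, :]
    g = np.where(counts > 0, gamma, 0.0)
    num = w @ g
    den = w.sum(axis=1)
    return num / np.where(den > 0, den, 1.0)


class _VariogramWorkspace:
    """Precomputed pair distances and bin assignment for repeated variograms."""

    def __init__(
        self,
        coords: np.ndarray,
        n_bins: int,
        max_dist_fraction: float,
        bandwidth: float | None,
    ):
        n = coords.shape[0]
        d = pdist(coords)
        dmax = d.max()
        if dmax <= 0:
            raise ValueError("all points are coincident")
        cutoff = max_dist_fraction * dmax
        self.pair_mask = d <= cutoff
        d_used = d[self.pair_mask]
        edges = np.linspace(0.0, cutoff, n_bins + 1)
        self.bin_idx = np.clip(np.searchsorted(edges, d_used, side="right") - 1, 0, n_bins - 1)
        self.centers = 0.5 * (edges[:-1] + edges[1:])
        self.n_bins = n_bins
        self.bin_width = edges[1] - edges[0]
        self.bandwidth = bandwidth if bandwidth is not None else self.bin_width
        # index pairs aligned with pdist ordering, restricted to used pairs
        iu, ju = np.triu_indices(n, k=1)
        self.i = iu[self.pair_mask]
        self.j = ju[self.pair_mask]

    def gamma(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sq = (values[self.i] - values[self.j]) ** 2
        gamma, counts = _bin_gamma(sq, self.bin_idx, self.n_bins)
        return _smooth_bins(gamma, counts, self.centers, self.bandwidth), counts


def empirical_variogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 25,
    max_dist_fraction: float = 0.5,
    bandwidth: float | None = None,
) -> Variogram:
    """Smoothed empirical variogram: ``gamma(h) = 0.5 * mean{(x_i - x_j)^2}``
    over pairs whose distance falls in bin ``h``.

    Bins span ``[0, max_dist_fraction * max pairwise distance]`` and are
    Gaussian-smoothed with the given bandwidth (default: one bin width).
    """
    values = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] != values.size:
        raise ValueError("coords must be (n_points, ndim) matching values")
    if values.size < 10:
        raise ValueError("need at least 10 points")
    ws = _VariogramWorkspace(coords, n_bins, max_dist_fraction, bandwidth)
    gamma, counts = ws.gamma(values)
    return Variogram(ws.centers.copy(), gamma, counts, ws.bandwidth)


class SurrogateMaps:
    """Reusable surrogate generator for a fixed map + coordinate set.

    Precomputes the distance structure once so large ensembles are cheap.

    Parameters
    ----------
    values, coords
        The map to randomize and its point coordinates in mm.
    kernel_grid
        Candidate neighborhood sizes k (points).  Default: fractions
        ``{0.1, 0.2, 0.3, 0.4}`` of the point count.
    resample
        If True (default), each surrogate's values are replaced by the
        original values via rank mapping, so value multisets match exactly.
    """

    def __init__(
        self,
        values: np.ndarray,
        coords: np.ndarray,
        kernel_grid: list[int] | None = None,
        n_bins: int = 25,
        max_dist_fraction: float = 0.5,
        bandwidth: float | None = None,
        resample: bool = True,
    ):
        self.values = np.asarray(values, dtype=float).ravel()
        self.coords = np.asarray(coords, dtype=float)
        n = self.values.size
        if self.coords.shape[0] != n:
            raise ValueError("coords/values length mismatch")
        if n < 10:
            raise ValueError("need at least 10 points")
        self.resample = resample
        self._constant = np.ptp(self.values) == 0

        if kernel_grid is None:
            kernel_grid = sorted({max(1, int(round(f * n))) for f in DEFAULT_KERNEL_FRACTIONS})
        if len(kernel_grid) == 0:
            raise ValueError("kernel_grid must not be empty")
        clamped = []
        for k in kernel_grid:
            if k >= n:
                warnings.warn(
                    f"kernel size k={k} >= n_points={n}; clamping to {n - 1}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                k = n - 1
            clamped.append(max(1, int(k)))
        self.kernel_grid = sorted(set(clamped))

        if self._constant:
            return
        self._ws = _VariogramWorkspace(self.coords, n_bins, max_dist_fraction, bandwidth)
        self.target_gamma, _ = self._ws.gamma(self.values)

        dmat = squareform(pdist(self.coords))
        order = np.argsort(dmat, axis=1)
        kmax = max(self.kernel_grid)
        self._nbr_idx = order[:, : kmax + 1]  # includes self at column 0
        self._nbr_d = np.take_along_axis(dmat, self._nbr_idx, axis=1)
        self._kernels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in self.kernel_grid:
            idx = self._nbr_idx[:, : k + 1]
            d = self._nbr_d[:, : k + 1]
            dk = d[:, [-1]]
            dk = np.where(dk > 0, dk, 1.0)
            w = np.exp(-d / dk)
            w /= w.sum(axis=1, keepdims=True)
            self._kernels[k] = (idx, w)
        self._sorted_values = np.sort(self.values)

    def _one(self, rng: np.random.Generator) -> tuple[np.ndarray, int]:
        perm = rng.permutation(self.values)
        noise = rng.standard_normal(self.values.size)
        best = None
        for k in self.kernel_grid:
            idx, w = self._kernels[k]
            sm = (w * perm[idx]).sum(axis=1)
            sd = sm.std()
            if sd == 0:
                continue
            sm = (sm - sm.mean()) / sd
            gamma_sm, _ = self._ws.gamma(sm)
            # target ~= beta * gamma_smoothed + alpha  (white noise adds a
            # constant alpha to the semivariance at all lags)
            A = np.column_stack([gamma_sm, np.ones_like(gamma_sm)])
            coef, *_ = np.linalg.lstsq(A, self.target_gamma, rcond=None)
            beta, alpha = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
            sse = float(((A @ [beta, alpha] - self.target_gamma) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, k, sm, beta, alpha)
        if best is None:  # degenerate permutation; fall back to the permutation
            return perm, self.kernel_grid[0]
        _, k, sm, beta, alpha = best
        surr = np.sqrt(beta) * sm + np.sqrt(alpha) * noise
        if self.resample:
            ranks = np.argsort(np.argsort(surr))
            surr = self._sorted_values[ranks]
        else:
            surr = surr - surr.mean() + self.values.mean()
        return surr, k

    def generate(self, n_surrogates: int, seed: int | np.random.Generator = 0) -> SurrogateEnsemble:
        """Generate ``n_surrogates`` maps; deterministic given seed."""
        if n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        n = self.values.size
        if self._constant:
            vals = np.tile(self.values, (n_surrogates, 1))
            return SurrogateEnsemble(vals, np.zeros(n_surrogates, dtype=int), self.resample)
        out = np.empty((n_surrogates, n))
        ks = np.empty(n_surrogates, dtype=int)
        for s in range(n_surrogates):
            out[s], ks[s] = self._one(rng)
        return SurrogateEnsemble(out, ks, self.resample)


def make_surrogates(
    values: np.ndarray,
    coords: np.ndarray,
    n_surrogates: int,
    seed: int = 0,
    kernel_grid: list[int] | None = None,
    resample: bool = True,
    **kwargs,
) -> SurrogateEnsemble:
    """One-shot convenience wrapper around :class:`SurrogateMaps`."""
    gen = SurrogateMaps(values, coords, kernel_grid=kernel_grid, resample=resample, **kwargs)
    return gen.generate(n_surrogates, seed)


def mask_coords(mask: np.ndarray, affine: np.ndarray, cap: int | None = 5000,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """In-mask voxel center coordinates in mm, optionally uniformly subsampled.

    Returns ``(coords, flat_indices)`` where ``flat_indices`` index into
    ``mask.ravel()`` restricted to in-mask voxels.
    """
    ijk = np.column_stack(np.nonzero(mask))
    xyz = ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    idx = np.arange(ijk.shape[0])
    if cap is not None and ijk.shape[0] > cap:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(ijk.shape[0], size=cap, replace=False))
        xyz = xyz[idx]
        warnings.warn(
            f"subsampled {cap} of {ijk.shape[0]} in-mask voxels for surrogates",
            RuntimeWarning,
            stacklevel=2,
        )
    return xyz, idx
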