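"""Voxel-wise covariate-adjusted permutation inference and demographic tests.

The group comparison is a voxelwise linear model ``y ~ intercept + group +
covariates`` with a Freedman-Lane residual-permutation null and max-statistic
family-wise error correction.  Also provides the between-dataset overlap /
spatial-correlation comparisons and the Table-1-style demographic tests
(Pearson chi-square, Mann-Whitney z, Monte-Carlo Lilliefors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .surrogates import SurrogateMaps

logger = logging.getLogger(__name__)

__all__ = [
    "TStatMap",
    "OverlapReport",
    "permutation_group_test",
    "threshold_overlap",
    "map_spatial_correlation",
    "sex_chi_square",
    "mann_whitney_z",
    "lilliefors",
]


@dataclass
class TStatMap:
    """Voxel-wise group-difference statistics (patients - controls)."""

    t: np.ndarray
    df: int
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    n_permutations: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = self.mask
        if np.any(self.p_fwe[m] + 1e-12 < self.p_uncorrected[m]):
            raise ValueError("p_fwe must dominate p_uncorrected voxelwise")


@dataclass
class OverlapReport:
    threshold: str
    n_overlap: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_overlap / self.n_total if self.n_total else float("nan")


def _group_tstats(X: np.ndarray, Y: np.ndarray, col: int, pinv: np.ndarray,
                  inv_diag: float) -> np.ndarray:
    """t statistic of ``X[:, col]`` for every column of ``Y`` (n x V)."""
    n, p = X.shape
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * inv_diag)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[col] / se
    return np.where(se > 0, t, 0.0)


def permutation_group_test(
    alff_maps: np.ndarray | list[np.ndarray],
    groups: np.ndarray,
    covariates: np.ndarray | None,
    mask: np.ndarray,
    B: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TStatMap:
    """Two-sided Freedman-Lane permutation test of a group effect per voxel.

    Parameters
    ----------
    alff_maps
        Per-subject 3D maps (list or stacked array, subjects first).
    groups
        Binary labels; 1 = patient, 0 = control.  ``t > 0`` means
        patients > controls.
    covariates
        ``(n_subjects, n_covariates)`` nuisance matrix (e.g. age, sex,
        mean FD), or None.
    B
        Number of permutations; p-values use the add-one rule so they are
        never zero.
    """
    maps = np.asarray(alff_maps, dtype=float)
    groups = np.asarray(groups, dtype=float).ravel()
    n = maps.shape[0]
    if groups.size != n:
        raise ValueError("groups length does not match number of maps")
    if (groups == 1).sum() < 2 or (groups == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    mask = np.asarray(mask, dtype=bool)
    Y = maps.reshape(n, -1)[:, mask.ravel()]

    cols = [np.ones(n), groups]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows do not match subjects")
        cols.extend(C.T)
    X = np.column_stack(cols)
    p = X.shape[1]
    df = n - p
    pinv = np.linalg.pinv(X)
    inv_diag = float(np.linalg.inv(X.T @ X)[1, 1])

    const = Y.std(axis=0) == 0
    if const.any():
        logger.warning("%d constant voxels: t=0, p=1", int(const.sum()))

    t_obs = _group_tstats(X, Y, 1, pinv, inv_diag)
    t_obs[const] = 0.0

    # Freedman-Lane: permute residuals of the reduced (covariates-only) model
    Z = np.delete(X, 1, axis=1)
    Hz = Z @ np.linalg.pinv(Z)
    Rz_Y = Y - Hz @ Y
    fit_Y = Hz @ Y

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs)
    exceed = np.zeros(Y.shape[1])
    exceed_max = np.zeros(Y.shape[1])
    for _ in range(B):
        perm = rng.permutation(n)
        Y_star = fit_Y + Rz_Y[perm]
        t_star = _group_tstats(X, Y_star, 1, pinv, inv_diag)
        abs_star = np.abs(t_star)
        exceed += abs_star >= abs_obs
        exceed_max += abs_star.max() >= abs_obs

    p_unc = (1.0 + exceed) / (B + 1.0)
    p_fwe = (1.0 + exceed_max) / (B + 1.0)
    p_unc[const] = 1.0
    p_fwe[const] = 1.0

    def to_vol(v: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape, dtype=float)
        out[mask] = v
        return out

    pvol = to_vol(p_unc)
    fvol = to_vol(p_fwe)
    pvol[~mask] = 1.0
    fvol[~mask] = 1.0
    return TStatMap(
        t=to_vol(t_obs), df=df, p_uncorrected=pvol, p_fwe=fvol,
        n_permutations=B, mask=mask,
    )


def threshold_overlap(
    tmap1: TStatMap, tmap2: TStatMap,
    thresholds: list[str | tuple[str, float]] | None = None,
) -> list[OverlapReport]:
    """Count voxels where both maps agree in effect direction, at a ladder of
    thresholds.

    Thresholds: ``("fwe", a)`` uses the FWE p-map, ``("unc", a)`` the
    uncorrected p-map, and ``"unthresholded"`` requires only matching nonzero
    sign.
    """
    if not np.array_equal(tmap1.mask, tmap2.mask):
        raise ValueError("masks differ")
    if thresholds is None:
        thresholds = [("fwe", 0.05), ("unc", 0.001), ("unc", 0.01), ("unc", 0.05),
                      "unthresholded"]
    m = tmap1.mask
    s1, s2 = np.sign(tmap1.t[m]), np.sign(tmap2.t[m])
    same_sign = (s1 == s2) & (s1 != 0)
    out = []
    for th in thresholds:
        if th == "unthresholded":
            sel = same_sign
            label = "unthresholded"
        else:
            kind, a = th
            pm1 = tmap1.p_fwe if kind == "fwe" else tmap1.p_uncorrected
            pm2 = tmap2.p_fwe if kind == "fwe" else tmap2.p_uncorrected
            sel = same_sign & (pm1[m] < a) & (pm2[m] < a)
            label = f"{kind} {a:g}"
        out.append(OverlapReport(label, int(sel.sum()), int(m.sum())))
    return out


def map_spatial_correlation(
    map1: np.ndarray,
    map2: np.ndarray,
    coords: np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
    surrogate_factory=None,
) -> tuple[float, float]:
    """Pearson correlation of two spatial maps with a surrogate-based
    permutation p-value.

    The null pools correlations of surrogates of map1 with the real map2 and
    surrogates of map2 with the real map1 (``2 * n_surrogates`` draws).
    """
    v1 = np.asarray(map1, dtype=float).ravel()
    v2 = np.asarray(map2, dtype=float).ravel()
    if v1.size != v2.size or v1.size < 3:
        raise ValueError("maps must share >= 3 points")
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero-variance map")
    factory = surrogate_factory or (lambda v, c: SurrogateMaps(v, c))
    r = float(np.corrcoef(v1, v2)[0, 1])

    z1 = (v1 - v1.mean()) / v1.std()
    z2 = (v2 - v2.mean()) / v2.std()
    null = []
    for vals, other in ((v1, z2), (v2, z1)):
        ens = factory(vals, coords).generate(n_surrogates, seed)
        S = ens.values
        Sz = (S - S.mean(axis=1, keepdims=True))
        sd = Sz.std(axis=1)
        sd[sd == 0] = np.inf
        null.append((Sz / sd[:, None]) @ other / v1.size)
    null = np.concatenate(null)
    p = (1.0 + np.sum(np.abs(null) >= abs(r))) / (null.size + 1.0)
    return r, float(p)


def sex_chi_square(counts) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("counts must be 2x2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin")
    n = tab.sum()
    expected = np.outer(rows, cols) / n
    chi2 = float(((tab - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def mann_whitney_z(x, y) -> tuple[float, float]:
    """Mann-Whitney test, normal approximation with tie correction.

    z is signed positive when ``x`` is stochastically larger than ``y``.
    Returns ``(z, two_sided_p)``; all-tied data gives ``(0, 1)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 observations per sample")
    nx, ny = x.size, y.size
    allv = np.concatenate([x, y])
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(allv)
    u = ranks[:nx].sum() - nx * (nx + 1) / 2.0  # U for x
    mu = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(nx * ny / 12.0 * (n + 1 - tie_term))
    if sigma == 0:
        return 0.0, 1.0
    z = float((u - mu) / sigma)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


_LILLIEFORS_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance between the empirical CDF and a normal fit to the sample."""
    x = np.sort(x)
    n = x.size
    z = stats.norm.cdf((x - x.mean()) / x.std(ddof=1))
    i = np.arange(1, n + 1)
    return float(max((i / n - z).max(), (z - (i - 1) / n).max()))


def lilliefors(values, n_sims: int = 10000, seed: int = 12345) -> float:
    """Lilliefors normality test p-value via a cached Monte-Carlo null table.

    The null distribution of the KS statistic with estimated mean/sd is
    simulated once per sample size (``n_sims`` standard-normal samples) and
    cached for the process lifetime.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("Lilliefors test needs >= 4 observations")
    if np.ptp(x) == 0:
        return 0.0  # a point mass is maximally non-normal
    d = _lilliefors_stat(x)
    key = (x.size, n_sims)
    if key not in _LILLIEFORS_CACHE:
        rng = np.random.default_rng(seed)
        sims = rng.standard_normal((n_sims, x.size))
        _LILLIEFORS_CACHE[key] = np.array([_lilliefors_stat(s) for s in sims])
    null = _LILLIEFORS_CACHE[key]
    return float((1.0 + np.sum(null >= d)) / (null.size + 1.0))
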