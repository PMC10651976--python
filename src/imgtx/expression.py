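"""Microarray expression preprocessing for transcriptome-map association.

Implements the standard atlas-style steps: intensity-based probe filtering,
RNA-seq-guided probe selection, coordinate-based sample assignment, scaled
robust sigmoid (SRS) normalization per donor, and differential stability (DS)
scoring across donors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMatrix",
    "ExpressionDataset",
    "intensity_filter",
    "select_probes",
    "assign_samples",
    "srs_normalize",
    "differential_stability",
    "build_dataset",
]


@dataclass
class ProbeMatrix:
    """Probe-level expression with annotations.

    Attributes
    ----------
    expr
        DataFrame, probes x samples.
    probe2gene
        Series mapping probe id -> gene symbol (exactly one gene per probe).
    above_background
        Boolean DataFrame, probes x samples (detection calls).
    samples
        DataFrame indexed by sample id with columns
        ``donor, region, x, y, z``.
    """

    expr: pd.DataFrame
    probe2gene: pd.Series
    above_background: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.above_background.index):
            raise ValueError("expr and above_background probe indices differ")
        if not self.expr.columns.equals(self.above_background.columns):
            raise ValueError("expr and above_background sample columns differ")
        missing = self.expr.index.difference(self.probe2gene.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack a gene mapping")
        coords = self.samples[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("sample coordinates must be finite")


@dataclass
class ExpressionDataset:
    """Gene-level normalized expression with per-gene DS scores."""

    expr: pd.DataFrame  # genes x samples, values in [0, 1]
    ds: pd.Series  # per-gene differential stability
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.expr.isna().any().any():
            raise ValueError("normalized expression contains missing values")
        vals = self.expr.to_numpy()
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("normalized expression must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def coords(self) -> np.ndarray:
        return self.samples.loc[self.expr.columns, ["x", "y", "z"]].to_numpy(dtype=float)


def intensity_filter(pm: ProbeMatrix, min_fraction: float = 0.5) -> pd.Index:
    """Probes detected above background in at least ``min_fraction`` of
    samples (inclusive boundary)."""
    frac = pm.above_background.mean(axis=1)
    kept = pm.expr.index[frac >= min_fraction]
    if len(kept) == 0:
        logger.warning("intensity filter removed every probe")
    return kept


def select_probes(
    pm: ProbeMatrix,
    rnaseq: pd.DataFrame,
    r_thresh: float = 0.2,
    probes: pd.Index | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pick one probe per gene by agreement with an RNA-seq reference.

    Per gene, each probe is correlated with the gene's RNA-seq profile over
    the shared samples; probes with ``r <= r_thresh`` (strict >) are dropped
    and the surviving probe with maximal r represents the gene.  Genes with no
    surviving probe (or absent from the reference) are dropped with a warning.

    Returns the gene x sample matrix over all of ``pm``'s samples.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    probes = pm.expr.index if probes is None else probes
    shared = pm.expr.columns.intersection(rnaseq.columns)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between probes and RNA-seq")

    rows: dict[str, str] = {}
    dropped: list[str] = []
    for gene, gene_probes in pm.probe2gene.loc[probes].groupby(pm.probe2gene.loc[probes]):
        if gene not in rnaseq.index:
            dropped.append(gene)
            continue
        ref = rnaseq.loc[gene, shared].to_numpy(dtype=float)
        best_probe, best_r = None, r_thresh
        for probe in gene_probes.index:
            x = pm.expr.loc[probe, shared].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(ref) == 0:
                continue
            if method == "pearson":
                r = float(np.corrcoef(x, ref)[0, 1])
            else:
                r = float(stats.spearmanr(x, ref).statistic)
            if r > best_r:
                best_probe, best_r = probe, r
        if best_probe is None:
            dropped.append(gene)
        else:
            rows[gene] = best_probe
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes dropped in probe selection "
            f"(missing from RNA-seq or no probe with r > {r_thresh})",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pm.expr.loc[list(rows.values())].copy()
    out.index = pd.Index(list(rows.keys()), name="gene")
    return out.sort_index()


def assign_samples(
    sample_coords: pd.DataFrame,
    region_centroids: pd.DataFrame,
    max_dist: float = 2.0,
) -> pd.Series:
    """Assign each sample to its nearest region centroid within ``max_dist``
    mm (Euclidean); unassigned samples are omitted from the result.

    Both frames must carry ``x, y, z`` columns in the same (MNI mm) space.
    """
    s = sample_coords[["x", "y", "z"]].to_numpy(dtype=float)
    c = region_centroids[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(s[:, None, :] - c[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    dist = d[np.arange(len(s)), nearest]
    keep = dist <= max_dist
    return pd.Series(
        region_centroids.index.to_numpy()[nearest[keep]],
        index=sample_coords.index[keep],
        name="region",
    )


def _srs_vector(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid of one vector: sigmoid((x - median)/(IQR/1.35)),
    then min-max rescaled to [0, 1]."""
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        # degenerate spread: fall back to a rank-based sigmoid
        warnings.warn("IQR = 0; using rank-based sigmoid", RuntimeWarning, stacklevel=3)
        r = stats.rankdata(x)
        s = 1.0 / (1.0 + np.exp(-(r - np.median(r))))
    else:
        s = special.expit((x - med) / (iqr / 1.35))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(s, 0.5)
    return (s - lo) / (hi - lo)


def srs_normalize(matrix: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Scaled robust sigmoid normalization along ``axis`` (1 = per row).

    Each unit needs >= 3 values.  Output lies in [0, 1].
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    n_per_unit = matrix.shape[1] if axis == 1 else matrix.shape[0]
    if n_per_unit < 3:
        raise ValueError("need >= 3 values per normalized unit")
    vals = matrix.to_numpy(dtype=float)
    if axis == 0:
        vals = vals.T
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        out[i] = _srs_vector(vals[i])
    if axis == 0:
        out = out.T
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def differential_stability(donor_profiles: dict[str, pd.DataFrame]) -> pd.Series:
    """Differential stability per gene: mean over donor pairs of the Spearman
    correlation between the pair's regional expression profiles.

    ``donor_profiles`` maps donor -> (genes x regions) matrix; each donor pair
    must share >= 3 regions.  Genes are the union intersection across donors.
    """
    donors = sorted(donor_profiles)
    if len(donors) < 2:
        raise ValueError("need >= 2 donors for differential stability")
    genes = donor_profiles[donors[0]].index
    for d in donors[1:]:
        genes = genes.intersection(donor_profiles[d].index)
    acc = pd.Series(0.0, index=genes)
    n_pairs = 0
    for a in range(len(donors)):
        for b in range(a + 1, len(donors)):
            pa, pb = donor_profiles[donors[a]], donor_profiles[donors[b]]
            common = pa.columns.intersection(pb.columns)
            if len(common) < 3:
                raise ValueError(
                    f"donors {donors[a]}/{donors[b]} share only {len(common)} regions"
                )
            xa = pa.loc[genes, common].to_numpy(dtype=float)
            xb = pb.loc[genes, common].to_numpy(dtype=float)
            ra = stats.rankdata(xa, axis=1)
            rb = stats.rankdata(xb, axis=1)
            ra = ra - ra.mean(axis=1, keepdims=True)
            rb = rb - rb.mean(axis=1, keepdims=True)
            denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = (ra * rb).sum(axis=1) / denom
            acc += pd.Series(np.where(denom > 0, rho, 0.0), index=genes)
            n_pairs += 1
    return (acc / n_pairs).rename("ds")


def build_dataset(
    pm: ProbeMatrix,
    rnaseq: pd.DataFrame,
    min_fraction: float = 0.5,
    r_thresh: float = 0.2,
    region_centroids: pd.DataFrame | None = None,
    max_dist: float = 2.0,
    probe_corr_method: str = "pearson",
) -> ExpressionDataset:
    """Full preprocessing chain: intensity filter -> probe selection ->
    (optional) sample assignment -> per-donor SRS normalization -> DS."""
    kept = intensity_filter(pm, min_fraction)
    gene_expr = select_probes(pm, rnaseq, r_thresh, probes=kept,
                              method=probe_corr_method)

    samples = pm.samples.copy()
    if region_centroids is not None:
        assignment = assign_samples(samples, region_centroids, max_dist)
        samples = samples.loc[assignment.index]
        samples["region"] = assignment
        gene_expr = gene_expr[assignment.index]

    # SRS per gene within each donor, then concatenate donors back together
    pieces = []
    for donor, meta in samples.groupby("donor"):
        cols = meta.index
        if len(cols) < 3:
            raise ValueError(f"donor {donor} has fewer than 3 samples")
        pieces.append(srs_normalize(gene_expr[cols], axis=1))
    norm = pd.concat(pieces, axis=1)[gene_expr.columns]

    profiles = {
        donor: norm[meta.index].T.groupby(samples.loc[meta.index, "region"]).mean().T
        for donor, meta in samples.groupby("donor")
    }
    ds = differential_stability(profiles).reindex(norm.index).fillna(0.0)
    return ExpressionDataset(expr=norm, ds=ds, samples=samples)
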