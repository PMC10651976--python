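"""Gene-wise spatial association between expression and a group-difference map.

The phenotype is the mean t-value inside a sphere around each tissue sample's
coordinate.  Gene significance uses a max-|r| permutation null built from
spatially autocorrelated surrogate phenotypes, followed by a differential
stability (top-quantile) filter.  Gene sets from two datasets are partitioned
into "sensitive" (dataset-1-only) and "insensitive" (replicated with matching
sign) classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .expression import ExpressionDataset
from .group_stats import TStatMap
from .surrogates import SurrogateMaps

logger = logging.getLogger(__name__)

__all__ = [
    "SampledPhenotype",
    "GenePartition",
    "sample_phenotype",
    "gene_map_association",
    "partition_genes",
    "cross_disorder_overlap",
]


@dataclass
class SampledPhenotype:
    """Sphere-averaged statistic per expression sample."""

    values: np.ndarray  # mean t within sphere, per retained sample
    n_voxels: np.ndarray  # contributing voxel count per retained sample
    coords: np.ndarray  # (n_retained, 3) mm
    sample_ids: np.ndarray  # identifiers of retained samples
    radius: float


@dataclass
class GenePartition:
    sensitive: set[str]
    insensitive: set[str]

    def __post_init__(self) -> None:
        if self.sensitive & self.insensitive:
            raise ValueError("partition classes must be disjoint")


def sample_phenotype(
    tmap: TStatMap,
    affine: np.ndarray,
    sample_coords: np.ndarray,
    sample_ids: np.ndarray | None = None,
    radius: float = 6.0,
) -> SampledPhenotype:
    """Average the t-map over in-mask voxels whose centers lie within
    ``radius`` mm of each sample coordinate.

    Samples with no in-mask voxel in range are dropped with a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(sample_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("sample_coords must be (n, 3)")
    if sample_ids is None:
        sample_ids = np.arange(coords.shape[0])
    sample_ids = np.asarray(sample_ids)

    mask = tmap.mask
    ijk = np.column_stack(np.nonzero(mask))
    A = np.asarray(affine, dtype=float)
    centers = ijk @ A[:3, :3].T + A[:3, 3]
    tvals = tmap.t[mask]
    tree = cKDTree(centers)
    hits = tree.query_ball_point(coords, r=radius)

    values, counts, kept = [], [], []
    for s, idx in enumerate(hits):
        if len(idx) == 0:
            continue
        values.append(tvals[idx].mean())
        counts.append(len(idx))
        kept.append(s)
    n_dropped = coords.shape[0] - len(kept)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} samples had no in-mask voxel within {radius} mm and were dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no sample had in-mask voxels within the radius")
    kept = np.asarray(kept)
    return SampledPhenotype(
        values=np.asarray(values),
        n_voxels=np.asarray(counts, dtype=int),
        coords=coords[kept],
        sample_ids=sample_ids[kept],
        radius=radius,
    )


def _gene_correlations(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every row of G with y; zero-variance rows give r = 0."""
    yc = y - y.mean()
    ys = np.sqrt((yc**2).sum())
    Gc = G - G.mean(axis=1, keepdims=True)
    gs = np.sqrt((Gc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gc @ yc) / (gs * ys)
    return np.where(gs > 0, r, 0.0)


def gene_map_association(
    expr: ExpressionDataset,
    pheno: SampledPhenotype,
    B: int = 1000,
    seed: int = 0,
    ds_quantile: float = 0.5,
    alpha: float = 0.05,
    surrogate_engine: SurrogateMaps | None = None,
) -> pd.DataFrame:
    """Gene-wise Pearson correlation with the sampled phenotype, FWE-corrected
    by the permutation distribution of the maximum |r| over surrogate
    phenotypes.

    A gene is significant iff its FWE p-value is below ``alpha`` AND its DS
    score is in the top ``ds_quantile`` fraction of analyzed genes.

    Returns a DataFrame indexed by gene with columns
    ``r, p_fwe, ds, ds_pass, sign, significant``.
    """
    cols = [str(s) for s in pheno.sample_ids]
    missing = [c for c in cols if c not in expr.expr.columns]
    if missing:
        raise ValueError(f"{len(missing)} phenotype samples absent from expression data")
    if len(cols) < 10:
        raise ValueError("need >= 10 aligned samples")
    y = np.asarray(pheno.values, dtype=float)
    if y.std() == 0:
        raise ValueError("zero-variance phenotype")
    G = expr.expr[cols].to_numpy(dtype=float)

    r_obs = _gene_correlations(G, y)
    zero_var = G.std(axis=1) == 0
    if zero_var.any():
        logger.warning("%d zero-variance genes: r=0, p=1", int(zero_var.sum()))

    engine = surrogate_engine or SurrogateMaps(y, pheno.coords)
    ens = engine.generate(B, seed)
    max_abs = np.empty(B)
    for b in range(B):
        max_abs[b] = np.abs(_gene_correlations(G, ens.values[b])).max()

    abs_r = np.abs(r_obs)
    p_fwe = (1.0 + (max_abs[None, :] >= abs_r[:, None]).sum(axis=1)) / (B + 1.0)
    p_fwe[zero_var] = 1.0

    ds = expr.ds.reindex(expr.expr.index).to_numpy(dtype=float)
    ds_cut = np.quantile(ds, 1.0 - ds_quantile)
    ds_pass = ds >= ds_cut
    significant = (p_fwe < alpha) & ds_pass
    return pd.DataFrame(
        {
            "r": r_obs,
            "p_fwe": p_fwe,
            "ds": ds,
            "ds_pass": ds_pass,
            "sign": np.where(r_obs >= 0, "+", "-"),
            "significant": significant,
        },
        index=expr.expr.index.copy(),
    )


def partition_genes(assoc1: pd.DataFrame, assoc2: pd.DataFrame) -> GenePartition:
    """Split dataset-1 significant genes into clinically sensitive
    (dataset-1-only) and insensitive (significant in both with the same
    effect direction)."""
    u1, u2 = set(assoc1.index), set(assoc2.index)
    if not (u1 & u2):
        raise ValueError("association tables share no genes")
    sig1 = set(assoc1.index[assoc1["significant"]])
    sig2 = set(assoc2.index[assoc2["significant"]])
    insensitive = {
        g for g in sig1 & sig2 if assoc1.loc[g, "sign"] == assoc2.loc[g, "sign"]
    }
    sensitive = sig1 - insensitive
    return GenePartition(sensitive=sensitive, insensitive=insensitive)


def cross_disorder_overlap(
    partition: GenePartition, other: pd.DataFrame
) -> dict[str, dict]:
    """Fraction of each partition class significant in another disorder's
    association table.  Empty classes report ``proportion = None``."""
    sig_other = set(other.index[other["significant"]])
    out = {}
    for name, genes in (("sensitive", partition.sensitive),
                        ("insensitive", partition.insensitive)):
        n = len(genes)
        k = len(genes & sig_other)
        out[name] = {
            "n_class": n,
            "n_overlap": k,
            "proportion": (k / n) if n else None,
        }
    return out
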