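"""Gene-set annotation statistics.

Fisher/hypergeometric over-representation tests, ensemble-null category
scores for spatially autocorrelated phenotypes, and a specificity-index
(pSI) table for temporal (developmental-stage) enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "CategoryScoreResult",
    "PsiTable",
    "fisher_enrichment",
    "category_score_test",
    "compute_psi",
    "stage_enrichment",
    "celltype_enrichment",
    "CANONICAL_CELL_TYPES",
]

CANONICAL_CELL_TYPES = (
    "neurons",
    "astrocytes",
    "oligodendrocytes",
    "microglia",
    "macrophage",
)


@dataclass
class EnrichmentResult:
    """One-sided hypergeometric over-representation result."""

    query_size: int
    target_size: int
    overlap: int
    background_size: int
    odds_ratio: float
    p: float
    p_corrected: float
    family_size: int

    def __post_init__(self) -> None:
        if self.overlap > min(self.query_size, self.target_size):
            raise ValueError("overlap exceeds set sizes")


@dataclass
class CategoryScoreResult:
    category: str
    n_genes: int
    score: float
    p_perm: float
    p_corrected: float


@dataclass
class PsiTable:
    """Specificity-index p-values, genes x stages, each in (0, 1].

    ``si`` holds the underlying specificity index (mean fold-change rank,
    1 = most stage-specific) the p-values were computed from.
    """

    psi: pd.DataFrame
    threshold: float = 0.01
    si: pd.DataFrame | None = None

    def stage_sets(self, threshold: float | None = None) -> dict[str, set[str]]:
        """Genes specifically expressed per stage at ``pSI < threshold``."""
        th = self.threshold if threshold is None else threshold
        return {
            s: set(self.psi.index[self.psi[s] < th]) for s in self.psi.columns
        }


def fisher_enrichment(
    query: set[str],
    target: set[str],
    background: set[str],
    family_size: int = 1,
) -> EnrichmentResult:
    """Over-representation of ``target`` within ``query`` against
    ``background``.

    p is the one-sided hypergeometric upper tail P(X >= overlap); the odds
    ratio is the sample OR ``ad/bc`` (0 when the overlap is empty, inf when
    ``bc = 0`` with a positive overlap).  Bonferroni correction multiplies by
    ``family_size``.
    """
    query, target, background = set(query), set(target), set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not target <= background:
        raise ValueError("target must be a subset of the background")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    N = len(background)
    a = len(query & target)
    b = len(query) - a
    c = len(target) - a
    d = N - a - b - c
    p = float(stats.hypergeom.sf(a - 1, N, len(target), len(query)))
    p = min(p, 1.0)
    if a == 0:
        odds = 0.0
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        query_size=len(query),
        target_size=len(target),
        overlap=a,
        background_size=N,
        odds_ratio=odds,
        p=p,
        p_corrected=min(1.0, p * family_size),
        family_size=family_size,
    )


def category_score_test(
    categories: dict[str, set[str]],
    observed_abs_r: pd.Series,
    ensemble_abs_r: pd.DataFrame,
) -> list[CategoryScoreResult]:
    """Category-level scores (mean |r| over member genes) against an
    ensemble null.

    ``ensemble_abs_r`` is genes x E, column e holding |r| recomputed against
    the e-th randomized (autocorrelation-preserving) phenotype.  The per
    category p is the add-one permutation p against the E null scores;
    Bonferroni is over the number of scored categories.
    """
    if ensemble_abs_r.shape[1] < 20:
        raise ValueError("need an ensemble of >= 20 randomized phenotypes")
    measured = set(observed_abs_r.index)
    if not measured.issubset(set(ensemble_abs_r.index)):
        raise ValueError("ensemble gene universe must cover the observed one")

    scored: list[tuple[str, list[str]]] = []
    for cat, genes in categories.items():
        members = sorted(set(genes) & measured)
        if not members:
            warnings.warn(f"category {cat!r} has no measured genes; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        scored.append((cat, members))

    E = ensemble_abs_r.shape[1]
    n_cats = len(scored)
    out = []
    for cat, members in scored:
        score = float(observed_abs_r.loc[members].mean())
        null = ensemble_abs_r.loc[members].mean(axis=0).to_numpy()
        p = float((1.0 + np.sum(null >= score)) / (E + 1.0))
        out.append(
            CategoryScoreResult(
                category=cat,
                n_genes=len(members),
                score=score,
                p_perm=p,
                p_corrected=min(1.0, p * n_cats),
            )
        )
    return out


def compute_psi(
    stage_expr: pd.DataFrame,
    n_null: int = 1000,
    seed: int = 0,
    epsilon_scale: float = 1e-6,
) -> PsiTable:
    """Specificity-index p-values per gene and stage.

    For gene g and stage s, the specificity index SI is the mean, over every
    other stage j, of g's rank position (1 = largest) of the fold change
    ``x_s / x_j`` among all genes.  The null permutes gene identities
    (jointly across a stage's comparisons, preserving the dependence between
    fold changes that share the stage-s numerator);
    ``pSI = (1 + #{SI_null <= SI}) / (n_null + 1)``, so small pSI marks genes
    specifically elevated in that stage.

    Non-positive expression is handled by shifting all values by
    ``epsilon_scale * max`` before forming ratios.
    """
    genes = stage_expr.index
    stages = stage_expr.columns
    G, S = stage_expr.shape
    if S < 2:
        raise ValueError("need >= 2 stages")
    if G < 20:
        raise ValueError("need >= 20 genes")
    X = stage_expr.to_numpy(dtype=float)
    if X.min() <= 0:
        eps = epsilon_scale * X.max()
        shift = -X.min() + eps
        logger.info("shifting expression by %.3g to form fold changes", shift)
        X = X + shift

    rng = np.random.default_rng(seed)
    psi = np.empty((G, S))
    si_out = np.empty((G, S))
    for s in range(S):
        others = [j for j in range(S) if j != s]
        m = len(others)
        # rank (1 = largest) of the fold change s vs j, per comparison
        ranks = np.empty((G, m))
        for c, j in enumerate(others):
            fc = X[:, s] / X[:, j]
            ranks[:, c] = G + 1 - stats.rankdata(fc)  # 1 = largest FC
        si = ranks.mean(axis=1)
        # null: permute gene identities (jointly across the comparisons, so
        # the within-gene dependence between fold changes is preserved)
        null_si = rng.permuted(np.broadcast_to(si, (n_null, G)), axis=1)
        si_out[:, s] = si
        psi[:, s] = (1.0 + (null_si <= si[None, :]).sum(axis=0)) / (n_null + 1.0)
    return PsiTable(
        psi=pd.DataFrame(psi, index=genes, columns=stages),
        si=pd.DataFrame(si_out, index=genes, columns=stages),
    )


def stage_enrichment(
    gene_set: set[str],
    psi: PsiTable,
    background: set[str] | None = None,
    threshold: float = 0.01,
    n_gene_sets: int = 2,
) -> dict[str, EnrichmentResult]:
    """Fisher enrichment of ``gene_set`` in each stage's pSI-specific gene
    list, Bonferroni-corrected for ``n_gene_sets x n_stages`` tests."""
    universe = set(psi.psi.index) if background is None else set(background)
    if not gene_set <= universe:
        raise ValueError("gene set must lie inside the pSI gene universe")
    family = n_gene_sets * psi.psi.shape[1]
    out = {}
    for stage, target in psi.stage_sets(threshold).items():
        out[stage] = fisher_enrichment(gene_set, target & universe, universe, family)
    return out


def celltype_enrichment(
    gene_set: set[str],
    markers: dict[str, set[str]],
    background: set[str],
    n_gene_sets: int = 2,
    allowed_types: tuple[str, ...] | None = CANONICAL_CELL_TYPES,
) -> dict[str, EnrichmentResult]:
    """Fisher enrichment of ``gene_set`` in each cell type's marker list,
    Bonferroni-corrected for ``n_gene_sets x n_celltypes`` tests."""
    if allowed_types is not None:
        unknown = set(markers) - set(allowed_types)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")
    family = n_gene_sets * len(markers)
    return {
        ct: fisher_enrichment(gene_set, set(m) & background, background, family)
        for ct, m in markers.items()
    }
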