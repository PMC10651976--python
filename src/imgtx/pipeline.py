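"""End-to-end orchestration of the synthetic two-dataset analysis.

Runs cohort generation -> ALFF -> group permutation test -> sphere-sampled
gene-map association (per dataset) -> sensitive/insensitive partition ->
enrichment suite (DEG Fisher, ensemble category scores, pSI stages, cell
types) -> cross-disorder overlap, writing per-stage artifacts and a
machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, group_stats, io, synthetic
from .alff import AlffConfig, compute_alff
from .expression import build_dataset, ProbeMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs for one synthetic end-to-end run."""

    out_dir: str = "imgtx_run"
    seed: int = 0
    # cohort / grid
    n_per_group: int = 12
    n_volumes: int = 120
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: float = 3.0
    effect_scale_1: float = 1.5
    effect_scale_2: float = 0.3
    # between-subject amplitude heterogeneity per dataset (dataset 2 is the
    # clinically heterogeneous one: weaker effect, noisier cohort)
    heterogeneity_1: float = 0.35
    heterogeneity_2: float = 0.7
    # expression
    n_genes: int = 300
    n_signal: int = 20
    signal_rho: float | tuple[float, float] = (0.5, 0.9)
    n_samples: int = 250
    n_donors: int = 4
    # annotations
    n_categories: int = 20
    category_size_range: tuple[int, int] = (5, 40)
    n_stages: int = 10
    # analysis
    band: tuple[float, float] = (0.01, 0.08)
    drop_initial_volumes: int = 10
    radius: float = 6.0
    B_group: int = 5000
    B_assoc: int = 1000
    E_ensemble: int = 1000
    n_psi_null: int = 1000
    alpha: float = 0.05
    ds_quantile: float = 0.5

    def __post_init__(self) -> None:
        for name in ("B_group", "B_assoc", "E_ensemble", "n_psi_null"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.grid_shape = tuple(self.grid_shape)
        self.category_size_range = tuple(self.category_size_range)
        self.band = tuple(self.band)
        if isinstance(self.signal_rho, list):
            self.signal_rho = tuple(self.signal_rho)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["category_size_range"] = list(self.category_size_range)
        d["band"] = list(self.band)
        if isinstance(self.signal_rho, tuple):
            d["signal_rho"] = list(self.signal_rho)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def _dataset_association(cfg, truth, expr_ds, effect_scale, seed, stage: str,
                         heterogeneity: float = 0.35):
    """Cohort -> ALFF -> group test -> sampled phenotype -> association."""
    spec = synthetic.CohortSpec(
        n_per_group=cfg.n_per_group, n_volumes=cfg.n_volumes, tr=cfg.tr,
        grid_shape=cfg.grid_shape, voxel_size=cfg.voxel_size,
    )
    images, covars = synthetic.gen_cohort(spec, truth.effect_map, effect_scale,
                                          seed=seed,
                                          subject_field_sd=heterogeneity)
    acfg = AlffConfig(band_low=cfg.band[0], band_high=cfg.band[1], tr=cfg.tr,
                      drop_initial_volumes=cfg.drop_initial_volumes)
    maps = np.stack([compute_alff(img, acfg).standardized for img in images])
    mask = np.ones(cfg.grid_shape, dtype=bool)
    tmap = group_stats.permutation_group_test(
        maps, covars["group"].to_numpy(),
        covars[["age", "sex", "mean_fd"]].to_numpy(),
        mask, B=cfg.B_group, seed=seed + 1, alpha=cfg.alpha,
    )
    coords = expr_ds.coords
    pheno = association.sample_phenotype(
        tmap, spec.affine, coords,
        sample_ids=expr_ds.expr.columns.to_numpy(), radius=cfg.radius,
    )
    table = association.gene_map_association(
        expr_ds, pheno, B=cfg.B_assoc, seed=seed + 2,
        ds_quantile=cfg.ds_quantile, alpha=cfg.alpha,
    )
    logger.info("%s: %d significant genes", stage, int(table["significant"].sum()))
    return tmap, pheno, table


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full synthetic analysis; returns the summary dict.

    Artifacts (gene tables, partition GMT, enrichment JSON, summary JSON and
    the config) are written under ``cfg.out_dir``.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("truth", "expr", "annot", "ds1", "ds2", "ds3", "psi")}

    stage = "truth"
    try:
        truth = synthetic.make_truth(
            grid_shape=cfg.grid_shape, n_genes=cfg.n_genes,
            n_signal=cfg.n_signal, signal_rho=cfg.signal_rho,
            n_stages=cfg.n_stages, seed=seeds["truth"],
            voxel_size=cfg.voxel_size,
        )

        stage = "expression"
        coords = synthetic.gen_sample_coords(
            cfg.n_samples, cfg.grid_shape, cfg.voxel_size, seed=seeds["expr"]
        )
        bundle = synthetic.gen_expression(
            cfg.n_genes, coords, cfg.n_donors, truth, seed=seeds["expr"]
        )
        pm = ProbeMatrix(bundle.probes, bundle.probe2gene, bundle.pacall,
                         bundle.samples)
        expr_ds = build_dataset(pm, bundle.rnaseq)
        io.write_tsv(expr_ds.expr, out / "expression.tsv")
        io.write_tsv(expr_ds.samples, out / "samples.tsv")

        stage = "annotations"
        genes = list(expr_ds.genes)
        annot = synthetic.gen_annotations(
            list(bundle.true_profiles.index), cfg.n_categories,
            cfg.category_size_range, cfg.n_stages, truth, seed=seeds["annot"],
        )

        stage = "dataset1"
        tmap1, pheno1, assoc1 = _dataset_association(
            cfg, truth, expr_ds, cfg.effect_scale_1, seeds["ds1"], "dataset1",
            heterogeneity=cfg.heterogeneity_1)
        io.write_tsv(assoc1, out / "assoc_dataset1.tsv")
        stage = "dataset2"
        tmap2, pheno2, assoc2 = _dataset_association(
            cfg, truth, expr_ds, cfg.effect_scale_2, seeds["ds2"], "dataset2",
            heterogeneity=cfg.heterogeneity_2)
        io.write_tsv(assoc2, out / "assoc_dataset2.tsv")

        stage = "map_comparison"
        overlaps = group_stats.threshold_overlap(tmap1, tmap2)

        stage = "partition"
        part = association.partition_genes(assoc1, assoc2)
        io.write_gmt(
            {"clinically_sensitive": part.sensitive,
             "clinically_insensitive": part.insensitive},
            out / "partition.gmt",
        )

        stage = "enrichment"
        background = set(genes)
        fisher = {}
        for cls, qset in (("sensitive", part.sensitive),
                          ("insensitive", part.insensitive)):
            for deg_name, deg in (("up", annot.deg_up), ("down", annot.deg_down)):
                res = enrichment.fisher_enrichment(
                    qset & background, deg & background, background, family_size=4)
                fisher[f"{cls}_{deg_name}"] = dataclasses.asdict(res)

        # ensemble category scores against randomized phenotypes of dataset 1
        engine = association.SurrogateMaps(pheno1.values, pheno1.coords)
        ens = engine.generate(cfg.E_ensemble, seeds["ds1"] + 7)
        G = expr_ds.expr[[str(s) for s in pheno1.sample_ids]].to_numpy(float)
        abs_ens = np.abs(
            np.stack([association._gene_correlations(G, v) for v in ens.values],
                     axis=1)
        )
        cat_results = enrichment.category_score_test(
            annot.categories,
            assoc1["r"].abs(),
            pd.DataFrame(abs_ens, index=expr_ds.genes),
        )
        categories = [dataclasses.asdict(c) for c in cat_results]

        stage = "psi"
        psi = enrichment.compute_psi(
            annot.stage_expr.loc[annot.stage_expr.index.intersection(
                pd.Index(sorted(background)))],
            n_null=cfg.n_psi_null, seed=seeds["psi"],
        )
        stage_res = {
            cls: {s: dataclasses.asdict(r) for s, r in
                  enrichment.stage_enrichment(qset & set(psi.psi.index), psi).items()}
            for cls, qset in (("sensitive", part.sensitive),
                              ("insensitive", part.insensitive))
        }

        stage = "celltype"
        cell_res = {
            cls: {ct: dataclasses.asdict(r) for ct, r in
                  enrichment.celltype_enrichment(
                      qset & background, annot.markers, background).items()}
            for cls, qset in (("sensitive", part.sensitive),
                              ("insensitive", part.insensitive))
        }

        stage = "cross_disorder"
        _, _, assoc3 = _dataset_association(
            cfg, truth, expr_ds, cfg.effect_scale_1 * 0.75, seeds["ds3"],
            "dataset3", heterogeneity=cfg.heterogeneity_2)
        cross = association.cross_disorder_overlap(part, assoc3)

    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary = {
        "seed": cfg.seed,
        "n_genes_analyzed": len(genes),
        "n_signal_planted": len(truth.signal_genes),
        "n_significant_dataset1": int(assoc1["significant"].sum()),
        "n_significant_dataset2": int(assoc2["significant"].sum()),
        "n_sensitive": len(part.sensitive),
        "n_insensitive": len(part.insensitive),
        "overlap": [dataclasses.asdict(o) for o in overlaps],
        "fisher_deg": fisher,
        "category_scores": categories,
        "stage_enrichment": stage_res,
        "celltype_enrichment": cell_res,
        "cross_disorder": cross,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    io.write_json(summary, out / "summary.json")
    return summary
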