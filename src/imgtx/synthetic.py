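"""Synthetic data generators for the full pipeline.

Every pipeline input can be generated here with known ground truth: a
spatially smooth group-effect map, BOLD cohorts whose low-frequency amplitude
tracks that map, multi-donor probe-level expression with planted
map-correlated genes, and annotation resources (categories, DEG lists,
cell-type markers, developmental stage matrix) with planted structure.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .alff import TimeSeriesImage

__all__ = [
    "SyntheticTruth",
    "CohortSpec",
    "ExpressionBundle",
    "AnnotationBundle",
    "gen_effect_map",
    "gen_cohort",
    "gen_sample_coords",
    "gen_expression",
    "gen_annotations",
    "make_truth",
    "roman_stages",
    "write_inputs",
]

DEFAULT_GRID = (16, 16, 12)
DEFAULT_VOXEL_SIZE = 3.0

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII"]


def roman_stages(n: int) -> list[str]:
    """Stage labels I, II, ... (falls back to S13, S14, ... past XII)."""
    return [_ROMAN[i] if i < len(_ROMAN) else f"S{i + 1}" for i in range(n)]


@dataclass
class SyntheticTruth:
    """Planted ground truth shared across generators."""

    effect_map: np.ndarray
    signal_genes: set[str]
    signal_rho: float | dict[str, float]
    stage_specific_genes: dict[str, set[str]]
    marker_assignments: dict[str, set[str]]
    seed: int
    voxel_size: float = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        for stage, genes in self.stage_specific_genes.items():
            if len(genes) == 0:
                raise ValueError(f"stage {stage!r} has no genes")

    def rho_of(self, gene: str) -> float:
        """Target spatial correlation for one signal gene."""
        if isinstance(self.signal_rho, dict):
            return self.signal_rho[gene]
        return float(self.signal_rho)


@dataclass
class CohortSpec:
    """Shape of one synthetic case-control BOLD cohort."""

    n_per_group: int = 20
    n_volumes: int = 180
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size: float = DEFAULT_VOXEL_SIZE
    age_mean: float = 37.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 65.0)
    fd_mean: float = 0.06
    fd_sd: float = 0.04

    def __post_init__(self) -> None:
        if self.n_volumes < 32:
            raise ValueError("n_volumes must be >= 32")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.voxel_size
        return A


def gen_effect_map(
    grid_shape: tuple[int, int, int],
    smoothness: float,
    seed: int,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field on a voxel grid.

    White noise is convolved with an exponentially decaying kernel
    ``exp(-d / smoothness)`` (d in mm); ``smoothness = 0`` yields plain white
    noise.  Deterministic given the seed.
    """
    if any(s <= 0 for s in grid_shape):
        raise ValueError("grid dimensions must be positive")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid_shape)
    if smoothness == 0:
        field_ = noise
    else:
        rad_vox = max(1, int(np.ceil(3.0 * smoothness / voxel_size)))
        ax = np.arange(-rad_vox, rad_vox + 1) * voxel_size
        dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
        kernel = np.exp(-np.sqrt(dx**2 + dy**2 + dz**2) / smoothness)
        field_ = fftconvolve(noise, kernel, mode="same")
    field_ = field_ - field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - n, ok.size)
        out[n : n + take] = ok[:take]
        n += take
    return out


def gen_cohort(
    spec: CohortSpec,
    effect_map: np.ndarray,
    effect_scale: float,
    seed: int,
    n_sinusoids: int = 3,
    band: tuple[float, float] = (0.01, 0.08),
    base_amplitude: float = 1.0,
    subject_amp_sd: float = 0.2,
    noise_sd: float = 1.0,
    subject_field_sd: float = 0.35,
    subject_field_smoothness: float = 6.0,
) -> tuple[list[TimeSeriesImage], pd.DataFrame]:
    """Simulate a two-group BOLD cohort with a planted in-band amplitude
    effect.

    Each voxel's series is broadband Gaussian noise plus ``n_sinusoids``
    random-frequency in-band sinusoids whose amplitude in patients is scaled
    by ``1 + effect_scale * effect_map`` (clipped at 0).  Every subject also
    carries a smooth multiplicative amplitude-heterogeneity field
    (``1 + subject_field_sd * GRF``), giving realistic between-subject
    variance so group contrasts have finite, sample-size-dependent power.
    Covariates: age ~ truncated Normal(37, 12^2) on [18, 65], sex ~
    Bernoulli(0.5), mean FD ~ |Normal(0.06, 0.04^2)|.  ``effect_scale = 0``
    makes the groups exchangeable.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be >= 0")
    if spec.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if effect_map.shape != spec.grid_shape:
        raise ValueError("effect_map shape does not match grid_shape")
    rng = np.random.default_rng(seed)
    n_subj = 2 * spec.n_per_group
    groups = np.repeat([1, 0], spec.n_per_group)  # 1 = patient
    t = np.arange(spec.n_volumes) * spec.tr
    flat_effect = effect_map.ravel()
    n_vox = flat_effect.size

    images = []
    for s in range(n_subj):
        freqs = rng.uniform(band[0], band[1], size=n_sinusoids)
        phases = rng.uniform(0, 2 * np.pi, size=n_sinusoids)
        amp_subject = base_amplitude * np.exp(rng.normal(0.0, subject_amp_sd))
        gain = np.ones(n_vox)
        if groups[s] == 1:
            gain = np.clip(1.0 + effect_scale * flat_effect, 0.0, None)
        if subject_field_sd > 0:
            hetero = _grid_fields(1, spec.grid_shape,
                                  subject_field_smoothness,
                                  spec.voxel_size, rng)[0].ravel()
            gain = gain * np.clip(1.0 + subject_field_sd * hetero, 0.05, None)
        osc = sum(
            np.sin(2 * np.pi * f * t + ph) for f, ph in zip(freqs, phases)
        )  # (n_volumes,)
        series = (
            rng.standard_normal((n_vox, spec.n_volumes)) * noise_sd
            + (amp_subject * gain)[:, None] * osc[None, :]
        )
        data = series.reshape(*spec.grid_shape, spec.n_volumes)
        images.append(TimeSeriesImage(data, spec.affine, spec.tr))

    covars = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n_subj)],
            "group": groups,
            "age": _truncated_normal(
                rng, spec.age_mean, spec.age_sd, *spec.age_range, size=n_subj
            ),
            "sex": rng.integers(0, 2, size=n_subj),
            "mean_fd": np.abs(rng.normal(spec.fd_mean, spec.fd_sd, size=n_subj)),
        }
    ).set_index("subject_id")
    return images, covars


def gen_sample_coords(
    n_samples: int,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    seed: int = 0,
) -> np.ndarray:
    """Random sample coordinates (mm) strictly inside the voxel grid."""
    rng = np.random.default_rng(seed)
    hi = (np.array(grid_shape) - 1) * voxel_size
    return rng.uniform(0, hi, size=(n_samples, 3))


@dataclass
class ExpressionBundle:
    """Probe-level inputs plus references, as the expression module expects."""

    probes: pd.DataFrame  # probes x samples
    probe2gene: pd.Series
    pacall: pd.DataFrame  # boolean probes x samples
    rnaseq: pd.DataFrame  # genes x (subset of) samples
    samples: pd.DataFrame  # sample metadata: donor, region, x, y, z
    true_profiles: pd.DataFrame = field(repr=False, default=None)  # genes x samples


def _effect_at_coords(
    effect_map: np.ndarray, coords: np.ndarray, voxel_size: float
) -> np.ndarray:
    idx = np.round(coords / voxel_size).astype(int)
    shape = np.array(effect_map.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("sample coordinates fall outside the grid")
    return effect_map[idx[:, 0], idx[:, 1], idx[:, 2]]


def _grid_fields(
    n_fields: int,
    grid_shape: tuple[int, int, int],
    smoothness: float,
    voxel_size: float,
    rng,
) -> np.ndarray:
    """Batch of standardized Gaussian random fields on the voxel grid
    (white noise convolved with an exponential kernel)."""
    noise = rng.standard_normal((n_fields, *grid_shape))
    if smoothness > 0:
        rad_vox = max(1, int(np.ceil(3.0 * smoothness / voxel_size)))
        ax = np.arange(-rad_vox, rad_vox + 1) * voxel_size
        dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
        kernel = np.exp(-np.sqrt(dx**2 + dy**2 + dz**2) / smoothness)
        noise = fftconvolve(noise, kernel[None], mode="same", axes=(1, 2, 3))
    flat = noise.reshape(n_fields, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (flat / sd).reshape(n_fields, *grid_shape)


def gen_expression(
    n_genes: int,
    sample_coords: np.ndarray,
    n_donors: int,
    truth: SyntheticTruth,
    seed: int,
    n_probes_per_gene: int = 3,
    probe_noise_sd: float = 0.3,
    background_length_scale: float = 6.0,
    rnaseq_donors: int = 2,
    plant_bad_probe: bool = True,
    donor_consistency: float = 0.6,
) -> ExpressionBundle:
    """Generate probe-level expression with planted map-correlated genes.

    Signal genes (from ``truth``) follow
    ``rho * z(effect at coords) + sqrt(1 - rho^2) * noise``; background genes
    are spatially autocorrelated fields independent of the effect map.  Each
    gene gets ``n_probes_per_gene`` probes; when ``plant_bad_probe`` the last
    probe is anti-correlated with the gene profile (and hence with RNA-seq),
    so probe selection must discard it.

    Background genes mix a donor-shared field (weight ``donor_consistency``)
    with donor-specific fields, giving them lower differential stability than
    the donor-consistent signal genes.
    """
    coords = np.asarray(sample_coords, dtype=float)
    n_samples = coords.shape[0]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    if not truth.signal_genes <= set(genes):
        raise ValueError("signal_genes must be a subset of the generated universe")
    rng = np.random.default_rng(seed)

    effect = _effect_at_coords(truth.effect_map, coords, truth.voxel_size)
    z_eff = (effect - effect.mean()) / (effect.std() if effect.std() else 1.0)

    donor_labels = np.array(
        [f"D{(i * n_donors) // n_samples + 1}" for i in range(n_samples)]
    )
    vox_idx = tuple(np.round(coords / truth.voxel_size).astype(int).T)
    grid = truth.effect_map.shape
    shared = _grid_fields(n_genes, grid, background_length_scale,
                          truth.voxel_size, rng)
    profiles = shared[(slice(None), *vox_idx)]
    # dilute background genes with donor-specific spatial fields so their
    # cross-donor stability (DS) is lower than that of signal genes
    w = float(np.clip(donor_consistency, 0.0, 1.0))
    if w < 1.0:
        donor_part = np.empty_like(profiles)
        for donor in np.unique(donor_labels):
            cols = donor_labels == donor
            fields = _grid_fields(n_genes, grid, background_length_scale,
                                  truth.voxel_size, rng)
            donor_part[:, cols] = fields[(slice(None), *vox_idx)][:, cols]
        profiles = w * profiles + np.sqrt(1.0 - w**2) * donor_part
    # small nugget keeps coincident-voxel samples from being exact ties
    nug = 0.1
    profiles = (
        np.sqrt(1.0 - nug**2) * profiles
        + nug * rng.standard_normal(profiles.shape)
    )
    for gi, g in enumerate(genes):
        if g in truth.signal_genes:
            rho = truth.rho_of(g)
            noise = rng.standard_normal(n_samples)
            noise = (noise - noise.mean()) / noise.std()
            profiles[gi] = rho * z_eff + np.sqrt(max(0.0, 1 - rho**2)) * noise
    true_profiles = pd.DataFrame(
        profiles, index=genes, columns=[f"S{i + 1:04d}" for i in range(n_samples)]
    )
    sample_ids = list(true_profiles.columns)

    probe_rows, probe_ids, gene_of_probe = [], [], []
    for gi, g in enumerate(genes):
        for j in range(n_probes_per_gene):
            pid = f"{g}_p{j + 1}"
            base = profiles[gi]
            if plant_bad_probe and j == n_probes_per_gene - 1 and n_probes_per_gene > 1:
                row = -base + probe_noise_sd * rng.standard_normal(n_samples)
            else:
                row = base + probe_noise_sd * rng.standard_normal(n_samples)
            probe_rows.append(row)
            probe_ids.append(pid)
            gene_of_probe.append(g)
    probes = pd.DataFrame(probe_rows, index=probe_ids, columns=sample_ids)
    probe2gene = pd.Series(gene_of_probe, index=probe_ids, name="gene")
    pacall = pd.DataFrame(
        rng.random((len(probe_ids), n_samples)) < 0.95,
        index=probe_ids, columns=sample_ids,
    )

    # block-of-space region labels
    span = truth.voxel_size * max(truth.effect_map.shape) / 2.0
    block = np.floor(coords / span).astype(int)
    region_labels = [f"R{x}_{y}_{z}" for x, y, z in block]
    samples = pd.DataFrame(
        {
            "donor": donor_labels,
            "region": region_labels,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        },
        index=sample_ids,
    )

    rn_donors = sorted(set(donor_labels))[:rnaseq_donors]
    rn_cols = samples.index[samples["donor"].isin(rn_donors)]
    rnaseq = true_profiles[rn_cols] + 0.1 * rng.standard_normal(
        (n_genes, len(rn_cols))
    )
    return ExpressionBundle(
        probes=probes,
        probe2gene=probe2gene,
        pacall=pacall,
        rnaseq=rnaseq,
        samples=samples,
        true_profiles=true_profiles,
    )


@dataclass
class AnnotationBundle:
    """Annotation resources with one planted category = signal genes."""

    categories: dict[str, set[str]]
    planted_category: str
    deg_up: set[str]
    deg_down: set[str]
    markers: dict[str, set[str]]
    stage_expr: pd.DataFrame  # genes x stages


def gen_annotations(
    genes: list[str],
    n_categories: int,
    size_range: tuple[int, int],
    n_stages: int,
    truth: SyntheticTruth,
    seed: int,
    stage_elevation: float = 10.0,
) -> AnnotationBundle:
    """Generate category (GO-like), DEG, cell-type-marker and stage-matrix
    annotations with planted structure.

    One category is the signal-gene set itself; stage-specific genes get
    ``stage_elevation``-fold mean expression in their stage.
    """
    lo, hi = size_range
    if lo < 1 or hi > len(genes) or lo > hi:
        raise ValueError("size_range must lie within [1, n_genes]")
    if n_categories < 1:
        raise ValueError("need at least one category")
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes)

    categories: dict[str, set[str]] = {}
    planted = "CAT0001"
    categories[planted] = set(truth.signal_genes)
    for i in range(1, n_categories):
        size = int(rng.integers(lo, hi + 1))
        categories[f"CAT{i + 1:04d}"] = set(
            rng.choice(gene_arr, size=size, replace=False)
        )

    signal = sorted(truth.signal_genes)
    non_signal = sorted(set(genes) - truth.signal_genes)
    n_deg = max(5, len(genes) // 10)
    # down-regulated list overlaps the planted signal so Fisher tests have
    # recoverable structure; up-regulated is background-only
    n_sig_in_down = min(len(signal), max(2, n_deg // 3))
    down = set(rng.choice(np.array(signal), size=n_sig_in_down, replace=False))
    down |= set(rng.choice(np.array(non_signal), size=n_deg - n_sig_in_down,
                           replace=False))
    up = set(rng.choice(np.array(non_signal), size=n_deg, replace=False))

    markers = truth.marker_assignments or {}
    if not markers:
        types = ("neurons", "astrocytes", "oligodendrocytes", "microglia",
                 "macrophage")
        pool = rng.permutation(gene_arr)
        per = max(3, len(genes) // 25)
        markers = {
            t: set(pool[i * per : (i + 1) * per]) for i, t in enumerate(types)
        }

    stages = roman_stages(n_stages)
    base = rng.lognormal(mean=1.0, sigma=0.4, size=(len(genes), n_stages))
    stage_expr = pd.DataFrame(base, index=genes, columns=stages)
    for stage, sgenes in truth.stage_specific_genes.items():
        if stage not in stage_expr.columns:
            raise ValueError(f"truth references unknown stage {stage!r}")
        members = sorted(set(sgenes) & set(genes))
        stage_expr.loc[members, stage] *= stage_elevation
    return AnnotationBundle(
        categories=categories,
        planted_category=planted,
        deg_up=up,
        deg_down=down,
        markers=markers,
        stage_expr=stage_expr,
    )


def write_inputs(
    out_dir,
    truth: SyntheticTruth,
    bundle: ExpressionBundle,
    annotations: AnnotationBundle | None = None,
    cohort: tuple[list[TimeSeriesImage], "pd.DataFrame"] | None = None,
    write_bold: bool = False,
) -> None:
    """Write generated inputs to disk in their exchange formats.

    Effect map as NIfTI; covariates, expression matrices and sample metadata
    as TSV; gene sets as GMT; ground truth as JSON.  4D BOLD series are only
    written when ``write_bold`` is set (they are large).
    """
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([truth.voxel_size] * 3 + [1.0])
    io.save_nifti(truth.effect_map, affine, out / "effect_map.nii.gz")
    io.write_json(
        {
            "signal_genes": truth.signal_genes,
            "signal_rho": truth.signal_rho,
            "stage_specific_genes": {
                k: sorted(v) for k, v in truth.stage_specific_genes.items()
            },
            "marker_assignments": {
                k: sorted(v) for k, v in truth.marker_assignments.items()
            },
            "seed": truth.seed,
            "voxel_size": truth.voxel_size,
        },
        out / "truth.json",
    )
    io.write_tsv(bundle.probes, out / "probes.tsv")
    io.write_tsv(bundle.probe2gene.to_frame(), out / "probe2gene.tsv")
    io.write_tsv(bundle.pacall.astype(int), out / "pacall.tsv")
    io.write_tsv(bundle.rnaseq, out / "rnaseq.tsv")
    io.write_tsv(bundle.samples, out / "samples.tsv")
    if annotations is not None:
        io.write_gmt(annotations.categories, out / "categories.gmt")
        io.write_gmt(
            {"deg_up": annotations.deg_up, "deg_down": annotations.deg_down},
            out / "deg.gmt",
        )
        io.write_gmt(annotations.markers, out / "markers.gmt")
        io.write_tsv(annotations.stage_expr, out / "stage_expression.tsv")
    if cohort is not None:
        images, covars = cohort
        io.write_tsv(covars, out / "covariates.tsv")
        if write_bold:
            for sid, img in zip(covars.index, images):
                io.save_timeseries(img, out / f"{sid}_bold.nii.gz")


def make_truth(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    smoothness: float = 6.0,
    n_genes: int = 500,
    n_signal: int = 25,
    signal_rho: float | tuple[float, float] = 0.8,
    n_stages: int = 10,
    seed: int = 0,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> SyntheticTruth:
    """Convenience constructor tying together the planted structures.

    ``signal_rho`` may be a scalar (every signal gene gets the same target
    correlation) or a ``(low, high)`` pair drawn per gene.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i + 1:04d}" for i in range(n_genes)])
    signal = set(rng.choice(genes, size=n_signal, replace=False))
    if isinstance(signal_rho, (tuple, list)):
        lo, hi = signal_rho
        signal_rho = {g: float(rng.uniform(lo, hi)) for g in sorted(signal)}
    stages = roman_stages(n_stages)
    remaining = rng.permutation(np.array(sorted(set(genes) - signal)))
    per_stage = max(1, min(5, len(remaining) // max(1, n_stages)))
    stage_specific = {
        s: set(remaining[i * per_stage : (i + 1) * per_stage])
        for i, s in enumerate(stages)
    }
    effect = gen_effect_map(grid_shape, smoothness, seed=rng.integers(2**31),
                            voxel_size=voxel_size)
    return SyntheticTruth(
        effect_map=effect,
        signal_genes=signal,
        signal_rho=signal_rho,
        stage_specific_genes=stage_specific,
        marker_assignments={},
        seed=seed,
        voxel_size=voxel_size,
    )
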