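# imgtx

Imaging-transcriptomics association pipeline: from BOLD time series to
case-control ALFF difference maps, to spatially-aware gene-map association
with family-wise-error permutation correction, to a gene-set enrichment
suite — plus a synthetic-data module that generates every input with planted
ground truth, so the whole pipeline runs and is testable with no downloads.

## What's inside

| Module | Purpose |
| --- | --- |
| `imgtx.synthetic` | Generators for all pipeline inputs: smooth effect maps (Gaussian random fields), two-group BOLD cohorts with an in-band amplitude effect, multi-donor probe-level expression with planted map-correlated genes, and annotation resources (GO-like categories, DEG lists, cell-type markers, developmental-stage matrix). |
| `imgtx.alff` | Mean framewise displacement (Power convention), nuisance regression, and ALFF: mean square-root power over 0.01–0.08 Hz, standardized by the global (mask) mean. |
| `imgtx.group_stats` | Voxel-wise covariate-adjusted group inference via Freedman–Lane residual permutation with max-statistic FWE correction; threshold-overlap and surrogate-based spatial map correlation; demographic tests (Pearson chi-square, Mann–Whitney z, Monte-Carlo Lilliefors). |
| `imgtx.surrogates` | Variogram-matched, spatial-autocorrelation-preserving surrogate maps on arbitrary point sets (the null engine for map correlations and gene association). |
| `imgtx.expression` | Atlas-style expression preprocessing: intensity filtering, RNA-seq-guided probe selection, 2 mm sample assignment, scaled robust sigmoid normalization per donor, differential stability. |
| `imgtx.association` | Sphere-sampled phenotype (mean t in a 6 mm sphere per sample), gene-wise Pearson correlation with max-\|r\| surrogate-permutation FWE, DS top-quantile filter, sensitive/insensitive gene partition, cross-disorder overlap. |
| `imgtx.enrichment` | One-sided hypergeometric (Fisher) over-representation with Bonferroni families, ensemble-null category scores, specificity-index (pSI) tables and stage/cell-type enrichment. |
| `imgtx.pipeline` | End-to-end orchestration of the synthetic two-dataset analysis with a YAML config and JSON summary. |

## CLI

All commands live under a single `imgtx` entry point:

```bash
# end-to-end synthetic run (writes gene tables, partition GMT, summary JSON)
imgtx run --out demo_run --seed 7 --quick

# single-subject ALFF map
imgtx alff --in series.nii.gz --tr 2.0 --band 0.01 0.08 --drop 10 --out alff.nii.gz

# voxelwise permutation group test from a manifest TSV (subject_id, path, group, covariates)
imgtx groupstats --maps manifest.tsv --covars age sex mean_fd --perms 5000 --seed 7 --out stats/

# variogram-matched surrogates of a point-set map (TSV: value, x, y, z)
imgtx surrogate --map map.tsv --n 1000 --seed 11 --out surrogates.tsv

# expression preprocessing and gene-map association
imgtx expr-prep --probes probes.tsv --probe-map map.tsv --pacall pacall.tsv \
    --rnaseq rnaseq.tsv --samples samples.tsv --out dataset/
imgtx assoc --tmap t.nii.gz --expr dataset/ --radius 6 --perms 1000 --seed 3 --out genes.tsv

# Fisher enrichment of GMT query sets against GMT target sets
imgtx enrich --query q.gmt --target t.gmt --background genes.txt --out enrich.json
```

`imgtx run` accepts a YAML config (see `imgtx.pipeline.RunConfig` for every
knob; `RunConfig().to_yaml(path)` writes a template).

## Notes

- Permutation p-values always use the add-one rule, so they are never zero
  and are bounded below by `1/(B+1)`.
- Sign conventions: group t > 0 means patients > controls; Mann-Whitney z > 0
  means the first sample is stochastically larger.
- All generators and the pipeline are deterministic given their seeds.
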