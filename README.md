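# epidense

Per-molecule methylation-density classification for bisulfite sequencing
and quasi-digital melt-curve data.

Many methylation biomarkers fail in dilute samples (e.g. plasma cfDNA)
because the mean methylation level at a locus drowns the rare, densely
methylated tumor-derived molecules in low-level background methylation.
`epidense` instead works at the level of individual DNA fragments
(*epialleles*): each fragment's **methylation density** is the fraction of
its CpG sites that are methylated, and a sample's **epiallelic fraction**
at a density cutoff is the share of its material at or above that cutoff.
A sample is called positive when its epiallelic fraction at a learned
density cutoff `md*` is at least a learned fraction cutoff `ef*`; both
cutoffs are chosen jointly by exhaustively maximizing Youden's J
(TPR − FPR) on training data.

## What's in the box

| module | purpose |
| --- | --- |
| `epidense.density` | per-read density extraction from SAM/BAM (Bismark-style `XM` call strings), per-sample density tables, weighted/unweighted epiallelic fractions, tidy-CSV interchange |
| `epidense.classifier` | the joint (density, fraction) cutoff optimizer, per-cutoff ROC/AUC profiles, classification, bootstrap AUC CIs, published cutoff presets |
| `epidense.admixture` | in-silico dilution: spike tumor reads into healthy backgrounds at fixed ratios/depths and compare density-cutoff vs mean-methylation classification |
| `epidense.dreaming` | melt-curve input: temperature→density calibration (OLS vs sequencing-confirmed patterns), lattice quantization, conversion-efficiency QC, epialleles-per-mL normalization |
| `epidense.multimarker` | beta-value marker selection, repeated stratified 50:50 splits, linear-SVM combination of per-marker scores |
| `epidense.synthetic` | seeded generators for all of the above (cohorts, SAM fixtures, melt tables, beta matrices) with ground truth |

## CLI

Tally reads over a target region into a density table:

```sh
epidense READtoMD \
    --input sample.sam \
    --regions "chr19:58220000-58220800" \
    --overlap-mode full_containment \
    --out density.csv
```

Region strings are 1-based closed intervals; BED files are also accepted.
`--pooling-table lib2sample.csv` (columns `library,sample`) pools
replicate libraries; samples with no reads are reported and excluded.

Learn cutoffs from labeled density tables:

```sh
epidense MDBC \
    --cases cases.csv --controls controls.csv \
    --measure fraction --md-step 0.05 \
    --out-prefix results/run \
    --sampleValsAtMD 0.6
```

This writes the full TPR/FPR grid (`*_grid.csv`), the per-density-cutoff
performance profile (`*_profile.csv`), ROC points at the optimum
(`*_roc.csv`), the optimum plus its complete tie set (`*_optimum.json`)
and, with `--sampleValsAtMD`, per-sample scores at a fixed cutoff
(`*_valsAtMD.csv`). Measures: `fraction` (CpG-weighted), `per_ml_count`
(requires `--volumes`), `normalized_read_count`.

## Library example

```python
from epidense import score_samples, build_cutoff_grid, optimize_cutoffs
from epidense.synthetic import CohortSpec, generate_cohort

tables, truth = generate_cohort(CohortSpec(n_cases=20, n_controls=20,
                                           tumor_fraction=0.02, seed=1))
labels = {s: ("case" if s.startswith("case") else "control") for s in tables}
scores = score_samples(tables, labels)                # 0..1 grid, step 0.05
opt = optimize_cutoffs(build_cutoff_grid(scores))
print(opt.md_star, opt.ef_star, opt.j_star, opt.ties)
```

## Notes

- Densities are stored as exact integer pairs and compared to cutoffs by
  integer cross-multiplication, so a read of density 3/5 always passes a
  0.60 cutoff regardless of float representation.
- The density-zero grid point uses the strict rule: only fragments with
  density strictly above zero count.
- All stochastic components (simulators, bootstrap, splits) require an
  explicit seed.
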