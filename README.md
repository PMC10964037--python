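# benfc — brain entropy & seed connectivity for paired rs-fMRI

`benfc` analyses paired (pre/post-treatment) resting-state fMRI the way
entropy-mapping treatment studies do, end to end and fully testable on
synthetic data:

1. **Preprocessing** of aligned 4D volumes: discard, 8 mm Gaussian
   smoothing, 0.01–0.1 Hz zero-phase band-pass, nuisance regression
   (Friston-24 + global/WM/CSF), framewise-displacement scrubbing with
   cubic-spline interpolation (FD > 0.2 mm).
2. **Brain entropy (BEN) mapping**: voxel-wise fuzzy entropy,
   FuzzyEn = −ln(φ_{m+1}/φ_m) with baseline-removed templates, Chebyshev
   distance and graded similarity exp(−(d/r)²), m = 2, r = 0.2·SD.
3. **Group inference**: paired / two-sample t-maps with AlphaSim-style
   cluster-level Monte-Carlo correction (voxel p < 0.001, α = 0.05,
   smoothness estimated from group residuals), plus BH-FDR, Lilliefors
   normality and Mann-Whitney U for scalar endpoints.
4. **Seed connectivity**: mean time series of the significant entropy
   cluster against every voxel, Fisher-z transformed; clinical
   change/percent-change correlations with FDR.
5. **Molecular association**: parcel-profile Pearson correlation of the
   t-map against a parcels × genes expression table (BH-FDR, |r| ≥ 0.15
   selection), hub genes (degree > mean + 1 SD on a confidence ≥ 0.9
   interaction graph), regional expression ranking, and Spearman
   correlation with receptor density maps assessed by a 5000-draw
   within-subject label-permutation null with Bonferroni correction.

Because raw clinical data of such studies are not shared, the package
ships a first-class synthetic-cohort generator (`benfc.synth`) with known
ground truth — planted entropy decreases, connectivity increases, gene and
receptor correlations — so every stage is validated by recovery and
calibration tests rather than by fixtures.

It is aimed at methods researchers who want a desk-scale, fully seeded
re-implementation of this analysis family to probe (how detection power
depends on effect size, series length, confound model, correction scheme)
and at reviewers who want each step oracle-tested in isolation.

## Worked example

Simulate a demo cohort (20 subjects, 140 volumes, 3 mm voxels on a
20×24×20 grid) and run the planted-effect recovery analysis:

```python
from benfc.pipeline import (StatsParams, analyze_paired_cohort,
                            demo_preproc_config, demo_synth_config)
from benfc.synth import make_paired_cohort

cohort, truth = make_paired_cohort(demo_synth_config(seed=7))
res = analyze_paired_cohort(cohort, truth, preproc=demo_preproc_config(),
                            stats=StatsParams(n_sim=1000), seed=7)
print("min cluster size:", res["ben_min_cluster_size"])
print("negative clusters:", [(c.voxel_count, round(c.peak_t, 1))
                             for c in res["ben_report"].clusters])
print("Dice vs planted ROI:", round(res["ben_dice"], 2))
print("FC cluster voxels on target:", res["fc_target_overlap"])
```

prints (seed 7, one CPU, ~40 s):

```
min cluster size: 4
negative clusters: [(447, -18.0), (12, -5.8), (6, -4.4)]
Dice vs planted ROI: 0.76
FC cluster voxels on target: 80
```

i.e. the cluster correction demands ≥ 4 contiguous supra-threshold voxels;
the dominant negative cluster (447 voxels, peak t = −18.0) overlaps the
288-voxel planted regularity ROI at Dice 0.76 — the planted entropy
*decrease* is recovered in place — and the connectivity analysis seeded at
the planted seed region finds a significant positive cluster covering all
80 voxels of the coupling target.

The same stages are available as a CLI (`benfc simulate | ben | fc |
stats | gene-assoc | receptor-assoc | run`) and as numbered drivers under
`analysis/` (simulation, full pipeline, recovery study, null calibration)
that write their tables under `results/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package end to end at reduced scale — it simulates a fresh
cohort from the given seed, executes preprocessing, entropy mapping,
cluster-corrected inference, connectivity, and the gene/receptor
association stages, and writes the results JSON to `--out` (the pipeline
summary goes to stderr).

## Layout

```
src/benfc/        types, io, synth, preprocess, entropy, connectivity,
                  stats, molecular, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            unit + property tests and test_acceptance.py
docs/methods.md   model, parameters, synthetic-world rationale, limitations
```
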