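# gmnet

Individual gray-matter (GM) morphological brain networks from regional
voxel-value distributions, with graph-theoretical characterization and
covariate-adjusted group inference.

For each subject, the per-ROI distributions of GM volume values are
summarized by Gaussian kernel density estimates; every ROI pair is compared
with the symmetrized Kullback-Leibler divergence on a shared grid and
mapped to an edge weight `exp(-d)` in (0, 1], yielding an N x N
similarity-weighted connectivity matrix (N = atlas regions, e.g. 90 or
246). Matrices are thresholded over a sparsity range (default 0.10-0.34,
step 0.01); at each threshold the global metrics (global/local efficiency,
clustering coefficient, characteristic path length, and the small-world
indices gamma/lambda/sigma against degree-preserving rewired nulls) and
nodal metrics (degree, efficiency, betweenness) are computed and summarized
by the area under the curve (AUC) across thresholds. Group comparisons use
ANCOVA (age, gender, education, TIV as nuisance covariates) with
Bonferroni-corrected post hoc contrasts, plus partial Pearson correlations
between nodal metrics and clinical variables.

A synthetic-cohort generator produces three-group cohorts (HC / DM / DKD)
with a controllable distributional effect on designated ROIs and a clinical
covariate table (including kidney markers coupled to the imposed network
effect), so the entire pipeline runs end-to-end with no external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (brute-force
oracle equivalence, KDE/KLD properties, thresholding exactness, small-world
sanity, effect-recovery and null-calibration simulations); the recovery
simulation takes a few minutes.

## Command line

```bash
gmnet run-all --out-dir runs/demo --seed 1         # simulate -> report
gmnet simulate --config config.yaml                 # individual stages
gmnet network  --config config.yaml
gmnet metrics  --config config.yaml
gmnet stats    --config config.yaml
gmnet report   --config config.yaml
gmnet extract --gm sub01_gm.nii --atlas aal.nii --out sub01.tsv
```

Configuration precedence: defaults < `--config` YAML < flags. Stages are
resumable: each records content hashes in `manifest.json` and is skipped on
rerun when its config section and inputs are unchanged. Outputs are plain
TSV/CSV/JSON plus SVG plots.

Run directory layout:

```
cohort.csv                 subject table (group, covariates)
samples/<subject>.tsv      per-ROI voxel values
networks/<subject>.tsv     similarity matrices
metrics/auc.tsv            per-subject AUCs (global + nodal)
metrics/curves.tsv         per-threshold metric curves (long format)
stats/                     demographics, global ANCOVA, nodal screens,
                           correlations, results.json bundle
report/                    violin and correlation plots (SVG)
```

## API sketch

```python
from gmnet import (CohortConfig, generate_cohort, build_network,
                   metric_curves, SparsityGrid, ancova_group_test)

cohort, subjects = generate_cohort(CohortConfig(seed=1))
matrix = build_network(subjects[0])                  # 90 x 90 similarities
curves = metric_curves(matrix, grid=SparsityGrid())  # metrics + AUCs
```

Notable conventions: sparsity thresholding retains exactly
`round_half_up(S * N(N-1)/2)` strongest edges with deterministic
lexicographic tie-breaking; weighted clustering uses Onnela's form; path
metrics use 1/weight edge lengths, with unreachable pairs contributing zero
efficiency and `Lp` averaged over reachable pairs (flagged); the null
ensemble preserves the binary degree sequence and, in weighted mode, the
weight multiset. All randomness is seeded and reruns are bit-identical.
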