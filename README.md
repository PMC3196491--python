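# restgraph

Graph-theory analysis of resting-state functional connectivity and its
interaction with task-evoked activity, for two-group (patient vs control)
fMRI designs — together with a synthetic-cohort generator that makes every
step of the chain testable against known ground truth.

The package targets the workflow used in resting-state studies of chronic
heroin users versus non-drug users: build voxel-level correlation networks,
quantify their small-world topology against degree-preserving random nulls,
map group differences in nodal degree, convert the abnormal foci into a
weighted region-of-interest network, fit an event-related cue-reactivity
GLM, and ask whether resting hub strength predicts cue-evoked activation
and craving. It is aimed at methods researchers who want a tested, seeded,
end-to-end reference implementation of that analysis chain.

## The analysis

For each subject, node time series (gray-matter voxels on a regular
lattice) are band-passed to 0.01–0.08 Hz and residualized against the mean
white-matter and ventricle time courses plus the six rigid-body motion
parameters (the global signal is deliberately **not** removed). The Pearson
correlation matrix is thresholded over T = 0.36 … 0.60 in 0.01 steps; the
usable range is where every subject's graph is fully connected. At each
threshold the pipeline computes, per subject:

- clustering coefficient `C_i = e_i / (k_i (k_i−1)/2)` and its mean C,
- characteristic path length L (mean shortest-path edge count over pairs),
- global efficiency `E_glob` (mean of 1/d_ij; robust to disconnection),
- nodal degree D (hub strength),
- `γ = C/C_rand`, `λ = L/L_rand` and small-worldness `σ = γ/λ`, where the
  null values are means over graphs rewired by double-edge swaps (10 swaps
  per edge) that preserve the degree sequence exactly.

Group inference uses pooled-variance two-sample t-tests with
Benjamini–Hochberg FDR: across thresholds for σ, and across nodes for
degree, where FDR-surviving voxels are grouped into face-adjacent clusters
(minimum 3 voxels). Each abnormal anatomical region contributes a
12-mm-diameter spherical ROI centred on its maximally-abnormal voxel; ROI
mean time courses form a weighted network whose R(R−1)/2 edges are compared
between groups (Fisher-z) and correlated with dependence duration
controlling for age. A canonical double-gamma HRF GLM (128 s cosine
high-pass) estimates each patient's drug-cue > neutral contrast; finally,
resting ROI degree is correlated with the same region's contrast amplitude
and with the craving change (post − pre).

The synthetic cohort encodes the effects this chain should recover:
group-specific hub regions (elevated latent-factor loadings), a dependence
duration that scales patients' connectivity (so efficiency co-varies with
duration), and cue-reactivity amplitudes coupled to resting degree. See
`docs/methods.md` for the generative model and its limits.

## Worked example

A full study-scale run (16+16 subjects, ~200 gray voxels, 150 rest volumes,
240 task volumes; a few minutes on one core):

```python
import warnings
from restgraph import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, t_step=0.04, n_null=6)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)

sigma = (result.metrics.groupby(["group", "threshold"])["sigma"]
         .mean().unstack().round(2))
print("mean small-worldness sigma by group and threshold:")
print(sigma)
```

prints

```
mean small-worldness sigma by group and threshold:
threshold  0.36  0.40  0.44  0.48
group
CHU        1.13  1.23  1.38  1.63
NDU        1.13  1.24  1.41  1.68
```

σ > 1 throughout and growing with T: both groups' resting networks are
small-world, exactly the regime the voxel-level analysis assumes. The rest
of the chain:

```
networks fully connected up to T = 0.48
degree-contrast clusters (region, size, peak t): [(6, 75, -5.0)]
ROIs: ['roi00_region2', 'roi01_region3', 'roi02_region5', 'roi03_region6']
edgewise tests: 6 edges, 2 rejected
duration-efficiency partial r = -0.44 (p = 0.10)
craving pre vs post: t = 19.7, p = 4e-12

          roi  region  n  r_activation  p_activation  r_craving  p_craving
roi00_region2       2 16          0.98          0.00       0.77       0.00
roi01_region3       3 16          0.96          0.00       0.80       0.00
roi02_region5       5 16          0.33          0.21       0.65       0.01
roi03_region6       6 16          0.36          0.17       0.65       0.01
```

The degree contrast recovers exactly the four injected hub regions (2 and 3
elevated in patients, 5 and 6 in controls; the single 75-voxel cluster
spans the two adjacent control-hub regions, peak t = −5.0 in region 6).
Regions 2 and 3 are the regions whose task activation was coupled to
resting degree, and only they show strong degree–activation correlations
(r ≈ 0.96–0.98); craving change tracks their resting degree as well. The
duration–efficiency partial correlation recovers the injected negative
sign. Craving rises sharply after cue exposure, as simulated.

There is also a CLI mirroring the pipeline stages
(`restgraph synth|preprocess|voxelnet|metrics|contrast|roinet|taskglm|interaction|all`),
each writing TSV/NIfTI/JSON outputs plus a manifest with the configuration
hash:

```bash
restgraph all --config config.yaml --seed 1 --out results/run1
```

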