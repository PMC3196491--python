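# Methods

This note documents the models, numerical choices and limits of the
`restgraph` pipeline and of its synthetic-cohort generator. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Preprocessing

Node time series are band-passed to 0.01–0.08 Hz and then residualized, in
one joint least-squares step, against an intercept, the mean white-matter
and ventricle time courses, and the six rigid-body motion parameters. The
order (filter first, then regression) is fixed and recorded in the output
manifest. Choices worth spelling out:

- **Filter realization.** FFT-domain masking with a one-bin raised edge
  (each bin averaged with its neighbours) and the DC bin forced to zero.
  This has exactly zero phase shift and is linear; it is not idempotent at
  the two edge bins (their gain is 0.5). No filter family is canonical for
  this band; the FFT mask was chosen for transparency and invertibility.
- **Confounds live in the same frequency space.** Confound columns are
  band-passed with the identical filter before regression, so the
  regression cannot reintroduce out-of-band variance. A confound column
  left with numerically zero in-band variance (std ≤ 1e−10) is dropped
  with a warning rather than allowed to make the design rank-deficient.
- **Motion parameters enter raw** — no derivatives or squares.
- **The global mean signal is never a regressor.** Removing it shifts the
  correlation distribution and makes the sign of correlations ambiguous;
  the thresholding step below depends on interpretable positive r.
- Rank-deficient confound matrices raise an error naming the collinear
  columns (found by testing which columns can be removed without reducing
  the rank).

## Voxel networks and the threshold sweep

Edges are defined by `r >= T` (inclusive; ties at the threshold are edges)
and only for positive correlations — `|r| >= T` is available by flag but
not the default, because the analysis keeps signs interpretable. The sweep
grid is 0.36–0.60 in 0.01 steps (25 values). `find_lower_bound_threshold`
returns the **largest** grid threshold at which every subject's graph is
fully connected; since connectivity is monotone non-increasing in T, the
usable sweep is every grid value up to that bound. If no grid value
connects all subjects the grid minimum is returned with a warning, and the
pipeline aborts with an instructive error rather than computing path
lengths on fragmented graphs.

## Graph metrics and nulls

- Clustering uses the local form `C_i = t_i / (k_i(k_i−1)/2)`; nodes with
  degree < 2 get `C_i = 0` (common convention). Triangles are counted as
  `diag(A³)/2` via `((A·A)∘A)·1`, never by forming A³.
- Path length L averages BFS shortest-path edge counts over unordered
  pairs and raises on disconnected input; callers gate on the
  connectedness bound above. Global efficiency averages `1/d` with
  unreachable pairs contributing 0, so it tolerates disconnection.
- Null graphs: double-edge swaps with `10 × |E|` attempted swaps; swaps
  creating self-loops or multi-edges are rejected, so the degree sequence
  is preserved exactly and the graph stays simple. The ensemble default is
  20 nulls per graph (standard error of the null means a few percent at
  desk cost); the swap budget of 10 per edge is the analysis's stated
  constant, the ensemble size is ours.
- `σ = γ/λ` with `γ = C/C_rand`, `λ = L/L_rand`. γ and λ are also reported
  separately. A null that disconnects (rare at the densities involved) has
  its L computed on its largest component, with the count logged.

## Inference

- Group comparisons are pooled-variance (Student) two-sample two-tailed
  t-tests (df = n₁+n₂−2); Welch is available by flag. Zero pooled variance
  is flagged degenerate (p = 1 when the means agree, p → 0 otherwise).
- Multiple testing is Benjamini–Hochberg FDR throughout. The voxel-wise
  "corrected" comparison is taken as BH across nodes for consistency with
  the sweep's explicit FDR; Bonferroni is a flag away.
- Degree-contrast clusters use 6-connectivity (faces only) on the voxel
  lattice; clusters under 3 voxels are dropped. Clusters are attributed to
  the anatomical region of their peak (max |t|) voxel, with ties broken to
  the lowest node index so reruns are identical.
- The most significant sweep threshold is the argmin of p, ties broken
  toward larger T. The duration–efficiency partial correlation is
  evaluated at that threshold and reported for the full sweep.
- Partial correlation residualizes both variables on the covariates plus
  intercept and correlates residuals; p comes from
  `t = r √((n−2−k)/(1−r²))`. A constant covariate is collinear with the
  intercept and contributes nothing.

## ROI networks

ROI spheres are 12 mm in diameter (inclusive Euclidean radius of 6 mm
around the centre voxel's mm coordinate), restricted to gray matter, one
per anatomical region that contains surviving contrast voxels; the centre
is that region's maximum-|t| surviving voxel. Edge weights are Pearson
correlations of ROI mean time courses. Edgewise group tests are run on
Fisher-z transformed weights by default (variance stabilizing; raw-r mode
by flag for literal replication); |r| = 1 makes z infinite and raises,
naming the edge. Edge indexing is the row-major upper triangle, identical
across subjects and groups.

## Task GLM

The HRF is the canonical double-gamma
`h(t) = gampdf(t;6,1) − gampdf(t;16,1)/6`, peak-normalized; stimulus
boxcars are convolved at 0.1 s resolution and sampled at volume times.
Slow drift is absorbed by discrete-cosine regressors with periods above
128 s, included in the design (the same projection as pre-filtering, with a
simpler contract). First-level fits are per-node OLS without temporal
autocorrelation modelling — a deliberate simplification relative to full
prewhitening packages; with the generator's white task noise it is exact,
with real data it understates first-level variance. The second level is a
one-sample random-effects t-test on subject contrast maps with FDR at 0.01
and a cluster-extent rule of more than 20 voxels (applied after FDR, in
that order).

## Rest–task interaction

Restricted to the patient group. Degree is taken at the sweep's most
significant threshold and averaged over each ROI's members (peak-voxel
degree by flag); it is correlated with the ROI-mean contrast amplitude and
with the craving change (post − pre).

## The synthetic cohort

Per subject, region latent signals follow a one-factor model
`u_r = a_r f + √(1−a_r²) e_r` (unit variance by construction, so the
implied region correlation is `a_r a_s` — positive definite whenever every
|a_r| < 1; loadings ≥ 1 raise an error naming the offending region
blocks). Voxels add: white noise (SD 0.7), a shared global-signal
component (loading 0.7) that emulates the unremoved global signal and
gives the correlation floor real resting data shows, a shared
sum-of-three-cosines drift with all power below 0.01 Hz (provably removed
by the bandpass), and shared white-matter/ventricle leakage (0.3) whose
sources are also written into the WM/ventricle voxels so the confound
extraction can recover them. Because drift, global and confound components
load **equally** on all gray voxels, two same-region voxels are identical
in the noise-free limit — a deliberate sharp test point.

Injected effects:

- **Hubs.** Two hub regions per group (patients: 2, 3; controls: 5, 6)
  with loading 0.9 against a base of 0.35. Hub voxels gain
  cross-region edges at every sweep threshold; the degree contrast should
  find those regions and no others.
- **Duration.** For patients, the whole coupling vector (region loadings
  and global loading) is scaled by `1 + slope·z(duration)` with slope
  −0.1 and duration uniform on 19–182 months (z standardized to ±1 at the
  range ends); connection density, and hence global efficiency, falls
  with duration. Scaling the global loading is essential: with ~44
  effective temporal degrees of freedom in the 0.01–0.08 Hz band of a
  150-volume run, modulating only the weak region loadings would be
  invisible against correlation sampling noise.
- **Degree–activation coupling.** The heroin-vs-neutral amplitude of the
  patient hub regions is `1.2 + 0.5·(D_r − 90)/40` (neutral fixed at
  0.8), where `D_r` is the subject's analysed region-mean degree at
  threshold 0.40; 90/40 centre/scale the realized degree distribution.
  Craving is `pre ~ N(0.6, 1.4²)` clipped to [0, 10] and
  `post = pre + 4.9 + 1.5·z̄ + noise`, reproducing the target pre/post
  craving means (0.6 and 5.5); the craving distribution across subjects is
  otherwise unconstrained by the analysis and is flagged as a stand-in in
  the output metadata.
- Ages are uniform on 25–49 years; event schedules are 48 trials of 2 s
  with ISI uniform on 4–12 s, rescaled to fill the 480 s acquisition
  window exactly (as constrained stimulus-delivery protocols do); the
  unconstrained expected duration is 48·(2+8) = 480 s.

What the generator does **not** emulate: spatial autocorrelation beyond
region blocks, cardiac/respiratory physiology, scanner artifacts,
temporally autocorrelated noise, motion-coupled signal changes, or any
mapping of synthetic regions onto real anatomy. Passing recovery tests
therefore show that the chain detects the effects it is built to detect
under its own assumptions — not that it would behave identically on real
data with structured noise.

## Problem sizes and observed behaviour

Recovery and calibration suites run at study scale — 16+16 subjects, a
7×7×6 lattice (~235 gray voxels, 10 regions), 150 rest volumes, 240 task
volumes — with 25 replicates for recovery and 50 for null calibration;
the end-to-end pipeline example uses a 0.04-step sweep and 6 nulls per
graph. These sizes keep a full run in minutes on one core while leaving
every qualitative property (connectivity range, small-world regime, hub
detectability) intact.

One behaviour deserves honest mention: BH FDR permits on the order of
`q × (number of rejections)` false voxels per contrast. Those false
rejections are spatially correlated (region-block noise), so occasionally
(roughly one replicate in ten) they cohere into a minimum-size cluster
outside the injected hub regions. Cluster reports attribute each cluster
to its peak region, and the recovery suite counts a replicate as a success
when every cluster peak lies in an injected hub region and at least 80 %
of surviving voxels are hub voxels; demanding literally zero stray voxels
would fail at the rate FDR itself allows.

## Known limitations

- Voxel counts are two orders of magnitude below real voxel-level network
  analyses; absolute degree values and cluster sizes are not comparable
  to values from full-resolution data.
- The per-subject correlation floor fluctuates with the realized variance
  of the shared global factor (~44 temporal dof), producing common-mode
  degree variance across subjects. This is realistic and is the main
  power constraint on the degree contrast at n = 16.
- No AR modelling at the first level, no permutation or cluster-extent
  null at the second; inference is parametric throughout.
- The craving model is a stand-in (flagged in metadata): its distribution
  across subjects is not identified by the analysis being emulated.
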