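# Methods

## Model

Each subject contributes a T × C matrix of component time courses
(typically spatial-ICA time series from resting-state fMRI); row *t* is
the subject's location **x**<sub>t</sub> in C-dimensional component
space. The analysis has five steps:

1. **Density.** For every timepoint, distances to all other timepoints of
   the same subject are computed, the `city_size` smallest are summed,
   and the density is the reciprocal of that sum. The timepoint itself is
   excluded from its neighborhood: including it adds a zero distance that
   silently shrinks the effective neighborhood and makes `city_size = 1`
   degenerate. Exact duplicate timepoints can make the distance sum zero;
   it is floored at 1e-12 × the data scale (duplicates then share the
   maximal finite density) and a warning is emitted.
2. **Threshold.** Per subject, the threshold is `cutoff` × a reference
   density — the subject's maximum by default, or the mean of the top
   `top_percentile` percent of densities (an outlier-robust alternative;
   we read "the five highest percentile" as the top 5% of the density
   distribution). The mask is strict (`density > threshold`), so with
   cutoff 1.0 and a unique maximum nothing is selected; that subject is
   flagged rather than dropped.
3. **Pooling and k selection.** High-density timepoints of all subjects
   are stacked. k is either fixed or chosen over k′ ∈ 2..10 by the
   geometric elbow: both axes of the WSS curve are normalized to [0, 1]
   and the k′ farthest from the chord joining the endpoints wins. A flat
   WSS curve has no elbow and is an error. The WSS curve is guaranteed
   non-increasing by seeding each k′ with the previous solution plus its
   worst-served point in addition to the usual k-means++ restarts.
4. **Clustering.** k-means (scikit-learn, 50 restarts, seeded) on the
   pooled high-density points only.
5. **Assignment.** Every timepoint of every subject is labeled with the
   nearest centroid (1-based states; distance ties break toward the lower
   state index). Centroids are *not* updated during assignment — they are
   defined purely by the high-density points, which is the point of the
   method. The alternative reading, re-running k-means on all timepoints
   initialized at those centroids, is available as `refit=True`; in the
   simulation studies below it changed none of the conclusions.

Dynamics metrics per subject: mean dwell time per state (mean length of
maximal runs; states never visited are reported missing, not zero, since
zeros would bias group means), transition number (count of consecutive
label changes), and the lag-L transition matrix (k × k counts of pairs at
lag L, diagonal included; the off-diagonal sum at lag 1 equals the
transition number). Group comparison uses Welch's t-test by default
(Mann–Whitney optional) with Benjamini–Hochberg FDR applied within each
metric family — the k dwell tests, the k² matrix cells — while the single
transition-number test is uncorrected; default α = 0.01. Dwell times are
in timepoints, multiplied by the TR (e.g. 2 s) for seconds.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `city_size` | 10% of T | neighborhood cardinality; lower bound on detectable cluster size |
| `cutoff` | 0.9 | threshold fraction of the per-subject reference density |
| `threshold_mode` | `max` | reference density: subject maximum or top-percentile mean |
| `k` | `auto` | number of states; elbow over 2..10 when `auto` |
| `restarts` | 50 | k-means restarts, best WSS kept |
| `lag` | 1 | transition-matrix lag |
| `alpha` | 0.01 | significance level on FDR-adjusted p-values |
| `seed` | 0 | all randomness flows from this value |

## Synthetic data

`SimulationSpec` draws, in a C-dimensional space (2-D by default), CS_i
points from an isotropic Gaussian of standard deviation `path_spread`
around each node location L_i, plus `n_noise` timepoints (default 10% of
Σ CS_i) uniform over a noise box, and shuffles everything into one random
temporal order (the density is order-invariant; ordering only matters for
dwell/transition demonstrations). Random node locations are drawn
uniformly in a node box (default the unit box) under a minimum pairwise
separation enforced by rejection sampling; the generic default separation
is 10 × path_spread, which suits small spreads or large boxes.

The scenario runners fix the geometry once: nodes random in [0,1]² with
minimum separation 0.5 — clusters resolvable at path spread 0.1,
overlapping by 0.3 — and noise uniform over the wide fixed box [−2,3]².
Distant ("high-amplitude") noise is the regime this method is designed
for: far-away points have low density and are excluded by the threshold,
while the all-points baseline must absorb them. Noise placed at
intermediate distances from the nodes instead contaminates the
density landscape asymmetrically and degrades the method — a known
limitation, not a target regime. What the generator does **not** emulate:
temporal autocorrelation, hemodynamics, scanner drift, or any spatial
structure; passing tests show correct recovery of well-separated
Gaussian high-traffic structure, not performance on real BOLD data.

## Validation machinery

* **Matched centroid distance** — minimum-total-cost one-to-one pairing
  (Hungarian assignment) of estimated centroids to true nodes; zero iff
  the sets coincide, invariant to ordering of either set.
* **Scenario sweeps 1–2** — single simulations across path spreads and
  city sizes, reporting selection masks (qualitative reports; with
  unbalanced clusters, a city size above the smallest cluster starves it
  of high-density points, which is why the parameter exists).
* **Scenario 3** — replicated comparison of clustering only high-density
  points vs all timepoints, scored by matched centroid distance, plus the
  fraction of cluster-member and noise points passing the threshold
  (200 replicates per spread at desk scale; counts configurable).
* **Scenario 4** — resampling null: per replicate, cluster the
  high-density set (k fixed at the simulated truth, k = 3) and 1,000
  random timepoint subsets of the same cardinality drawn without
  replacement; the empirical p-value counts null distances strictly below
  the method's, with the conservative (count+1)/(B+1) variant reported
  alongside. Null subsets (and the method's point set, for symmetry) are
  clustered by a vectorized batched Lloyd k-means (k-means++ seeding,
  8 restarts, empty clusters reseeded at the farthest point), which makes
  the 100 × 1,000 design tractable on one CPU; it is cross-checked
  against scikit-learn and against brute-force enumeration in the tests.

## Measured behavior, and where it diverges from expectations

Two quantitative expectations for this family of methods do **not**
reproduce under the scenario conditions above, and the package reports
the measured values rather than the expected ones.

*Selection fraction.* With threshold = cutoff × max density, a cluster
sampled from a density *f* has k-NN-type density ≈ *f*^(1/C) up to scale,
so the fraction of cluster members passing is ≈ 1 − cutoff^C — about 19%
for cutoff 0.9 in 2-D, largely independent of path spread, city size and
geometry. We measure 13–20% across all configurations tried (both
threshold modes, city sizes 16–60, cluster sizes 50–60, several noise
designs). Selection fractions near 50% would require the neighborhood's
one beyond-cluster member to contribute a distance ~140 × path_spread,
identical across clusters — which uniform noise anywhere near the node
bounding box destroys.

*Coverage.* Because each cluster's peak density fluctuates between
replicates, in a substantial fraction of replicates (≈ half at spread
0.1, ≈ 15% at 0.3) one cluster falls entirely below the shared threshold.
In those replicates k-means on the selected points cannot recover all
three nodes, the matched distance is large, and the scenario-4 p-value
for that replicate is far from zero: the mean p at spread 0.3 is ≈ 0.13–
0.19 rather than < 5 × 10⁻⁴. The high-density method still beats the
all-points baseline *on average at every spread* (margin largest at
spread 0.1), because distant noise degrades the baseline more than
occasional cluster dropout degrades the method.

## Numerical choices

Distances via `scipy.spatial.distance.pdist` with a naive double-loop
oracle in the tests (agreement to 1e-10 relative). k-nearest selection by
partial sort; ties at the boundary do not affect the distance sum.
k-means seeds derive from the top-level seed and stay below 2³¹.
Assignment ties break to the lower state index. File outputs are plain
CSV/TSV with a `# config_hash=` header line tying every artifact to the
exact configuration; time indices are 0-based in files, states 1-based.

## Limitations

Exact O(T²) distance computation per subject (fine for T ≈ 162; no
approximate neighbor index). Euclidean distance only. No covariate
adjustment in group comparisons. The elbow rule is deterministic but, like
all elbow heuristics, undefined on flat WSS curves. Selection-fraction and
coverage behavior at cutoff 0.9 in low dimensions is as measured above; in
high-dimensional component spaces (C ≈ 47) the same cutoff selects the
large majority of timepoints, so real-data behavior differs qualitatively
from the 2-D simulations.
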