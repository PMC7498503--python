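# Methods

`morphorep` quantifies single-neuron reconstructions (SWC trees) with four
families of feature representations and benchmarks how well each family
discriminates cell types under a standardized nested-cross-validated linear
readout. This note records the models, conventions, numerical choices and
limitations behind the implementation.

## Reconstructions and preprocessing

A reconstruction is a rooted tree of nodes, each with a 3D position (µm), a
radius and a compartment type (soma / axon / dendrite). The straight line
between a node and its parent is a *sub-segment*; the path between
consecutive branch points (or a branch point and a tip) is a *segment*
(branch). Axes follow the slice convention: x = slice width, y = slice depth
(microscope viewing axis), z = cortical or retinal depth.

Preprocessing, in order:

1. **Soma consolidation.** All somatic nodes collapse into a single root at
   the centroid of the convex hull of their positions (mean of hull
   vertices; degenerate hulls fall back to the mean of unique positions),
   with the mean somatic radius. For reconstructions lacking soma labels,
   any node with radius above a threshold (1 µm for retinal bipolar cells)
   is first relabelled somatic.
2. **Branch-type harmonization.** Within each branch, node types are set to
   the majority type of the branch's sub-segments. Exact axon/dendrite ties
   resolve to axon — deterministic, and biased toward the compartment that
   dominates these data.
3. **Centering.** Cortical cells are soma-centered; bipolar cells are
   soma-centered in x/y with a user-supplied z offset placing z = 0 at the
   inner-plexiform-layer onset.
4. **Resampling** (cortical data) to ~1 µm node spacing. Each sub-segment of
   length L is split into ceil(L/spacing) equal pieces by linear
   interpolation. This preserves path length exactly (points stay on the
   original polyline), keeps the soma, branch points and tips bit-exact, and
   makes resampling an exact fixed point.
5. **Depth-axis smoothing** (cortical data): a 3rd-order Savitzky–Golay
   filter with a 21 µm window applied to the y coordinate of each unbranched
   run (after 1 µm resampling a window in µm is a window in samples). Runs
   shorter than the window are left unfiltered rather than shrinking the
   window. Smoothing after resampling can stretch individual sub-segments
   slightly beyond the nominal spacing; this is inherent to smoothing a
   resampled polyline and is left uncorrected.

Geometry conventions that the literature does not fix uniquely:

* **Branch order** is centrifugal: the soma has order 0 and every branch
  point passed increments the order. A branch point itself carries the order
  of its parent-side branch; the soma is never counted as a branch point
  even with several stems.
* **Path angle** is measured between consecutive direction vectors, so a
  straight continuation scores 0° (the opposite convention, 180° for
  straight, also exists).
* **Root angle** is the angle between a segment's chord and the outward
  radial direction from the soma to the segment end; radial growth scores 0°.
* **Euler root angles** decompose the rotation taking the outward radial
  direction onto the segment chord as extrinsic rotations about the fixed
  x, y, z axes, with magnitudes reported in [0, 180]°. The rotation order
  and intrinsic/extrinsic choice are conventions; they are applied uniformly
  so the resulting histograms are comparable across cells.

## Feature representations

All representations are computed per *modality* — the full neuron, the axon
subtree, or the dendrite subtree (soma always included as root).

**Density maps.** Points are sampled every 25 nm along the skeleton, then
min–max normalized per dataset and modality (ranges are fitted on the data
or supplied as a config). The normalized cloud is projected onto an axis
(x/y/z) or a plane (xy/xz/yz) and binned into 100 or 100×100 bins spanning
[−0.1, 1.1] per axis (bin width 0.012, half-open floor binning; coordinates
outside the span — possible under supplied fixed ranges — are clipped into
the boundary bins and counted in a log rather than dropped, so mass stays
interpretable). Histograms are smoothed with an 11-bin (or 11×11) Gaussian
kernel, σ = 2 bins, truncated and renormalized to unit sum, applied with
zero-padded "same" convolution. Flattened maps give 100 or 10,000 features.

**Morphometric statistics.** 24 single-valued summaries: branch point / tip
/ stem counts, x/y/z extents, mean neurite radius, total length, surface and
volume (each sub-segment a truncated cone, π(r+R)·√((R−r)²+h²) and
πh(r²+rR+R²)/3; the soma is excluded — soma-adjacent sub-segments use the
child radius at both ends since the somatic radius is incommensurate with
neurites), maximal tip-to-soma path length, maximal branch order, maximal
Euclidean segment length, median intermediate and terminal segment lengths,
median and 99.5th-percentile path angle, median and 99.5th-percentile
log-tortuosity (tortuosity = segment path length / chord length ≥ 1),
min/mean/max branch angle, maximal branch-point degree, and tree asymmetry.
Percentiles interpolate linearly between order statistics; the 99.5th
percentile stands in for the maximum to blunt reconstruction artefacts.
Statistics undefined on a degenerate topology (e.g. branch angles of an
unbranched cell) are recorded as 0 with a warning so feature matrices stay
finite.

**Tree asymmetry** is the weighted *sum* over branch points of the
proportional sum of absolute deviations,
PSAD(p) = m/(2(m−1)(n−m)) · Σᵢ |rᵢ − n/m|, where m is the out-degree of p,
n the leaf count of its subtree and rᵢ the leaf counts of the daughter
subtrees; a branch point contributes only when its subtree has more than 3
leaves. The classical definition averages instead of summing; the sum is
implemented as the formula is written, and the fully balanced tree still
scores 0.

**Morphometric distributions.** 17 one-dimensional histograms/vectors
(branch angles, path angles, root angles, three Euler root angles — 20 bins
over [0, 180]°; branch-order counts up to the dataset maximum; Euclidean
segment lengths, path and Euclidean distances of branch points and tips to
the soma — 20 bins up to dataset maxima; node radii — 30 bins; Sholl
intersection profiles in the xy/xz/yz projections — 36 circles equally
spaced from the soma to the maximal projected radius, one crossing counted
per sub-segment straddling a circle; and three 10-dimensional 3-star-motif
vectors) plus 6 two-dimensional histograms pairing branch/path angles and
radii with branch order or path distance. Histograms store raw counts, not
densities — counts keep mass interpretable and PCA absorbs scale. 2D
binning matches the corresponding 1D axes (so thickness-based 2D histograms
are 30×20 while angle-based ones are 20×20) and shares the binning code, so
the value-axis marginal of every 2D distribution reproduces its 1D
counterpart exactly.

The 3-star motif vector counts, in the subgraph induced by the i·10% of
nodes closest to a center (tree path distance), one motif per bifurcation
and one more per additional branch: a node of undirected induced degree
d ≥ 3 contributes d − 2. The center is the soma, or (averaged variants) 100
random nodes drawn with a seeded generator; the companion per-decile
maximal-distance vector uses the maximal Euclidean distance from the center
within each decile subgraph (the center-to-node maximum, not the all-pairs
diameter, which would be quadratic in the decile size).

**Persistence.** Each neurite tree yields a persistence diagram under four
filter functions (radial distance, path length, branch order, z-projection;
all zero at the soma): every tip births a branch at its filter value;
moving rootward, at each branch point all but the largest-birth branch die
at the branch point's value (elder rule; multifurcations kill all
non-survivors simultaneously; birth ties resolve to the smaller tip index).
The survivor dies at the soma with death 0, so the diagram has exactly one
pair per tip. Under the path-length filter the summed lifetimes equal the
total neurite length — each micrometre of neurite is alive in exactly one
branch — which the tests exploit as an exact conservation oracle. Diagrams
are rendered as Gaussian persistence images: a 2D KDE (scipy `gaussian_kde`,
Scott's rule) of the (birth, death) points evaluated on a 100×100 grid over
[0, max_birth]×[0, max_death] with dataset-level maxima, or a 1D KDE of the
lifetimes sampled at 100 points on [0, max_birth]. KDE is fitted per cell on
that cell's diagram. Degenerate diagrams (fewer points than the KDE needs,
or singular covariance) fall back to a sum of isotropic Gaussians with
bandwidth 1% of max_birth, logged. Negative lifetimes (possible under the
radial and z filters) are clipped to 0 before the 1D KDE. Note that at very
small diagram sizes Scott's rule oversmooths: the two-lifetime diagram
{3, 1} produces a single peak at 2, not a bimodal density.

## Classification benchmark

Every representation feeds the same supervised pipeline:

* Per training fold: PCA keeping the smallest number of components with
  cumulative explained variance ≥ 0.90, all components then divided by the
  standard deviation of the first training PC — this puts differently sized
  representations on one scale so they can be concatenated into combined
  feature sets. The raw 24-statistic vector is z-scored instead (and
  PCA-reduced like the rest when used inside a combination).
* Elastic-net logistic regression, mixing parameter α = 0.5 (equal lasso
  and ridge weights), intercept unpenalized, no internal re-standardization.
  The penalty path has 100 log-spaced values from the data-derived
  λ_max = maxⱼ |xⱼ·(y − ȳ)|/(nα) down to 10⁻³·λ_max, solved by warm-started
  SAGA with a fixed random state. λ is chosen on an inner stratified 3-fold
  CV by the one-standard-error rule: the largest λ whose mean inner log-loss
  is within one SE of the minimum.
* Outer loop: 10-times-repeated stratified 5-fold CV, random state 17, so
  fold assignments are bit-identical across runs. Types with five or fewer
  cells cannot be stratified and are rejected.
* Metrics: test-set log-loss (probabilities clipped to [1e−15, 1−1e−15]),
  accuracy, macro-F1 and Matthews correlation (defined as 0 on a
  single-class truth). Chance level is ln K for K balanced classes.
  3-nearest-neighbour and decision-tree classifiers run under the identical
  outer CV as alternative schemes (without log-loss, which is meaningless
  for them).

Small samples interact with the one-standard-error rule: with ~12 cells per
type, inner-fold losses are noisy, the rule picks strong penalties, and the
classifier's probabilities stay conservative even when the classes separate
perfectly — mean log-loss then plateaus around 0.15–0.2 rather than
approaching 0. This matters when interpreting absolute log-losses at small
n; relative comparisons between representations are much more stable.

## Comparing representations

The mean log-loss difference between representations A and B over a pair
pool P is δ(A,B) = (1/|P|) Σₚ (ℓ(B,p) − ℓ(A,p)). Pairs sharing a type are
dependent, so the SE of δ comes from a jackknife across *types*: each type
is left out with all its pairs, giving leave-one-out estimates δ₋τ and
SE = √[(n−1)/n · Σ(δ₋τ − δ̄)²] with n the number of types. p-values are
two-sided z-tests, reported unadjusted. Ranking selects, per modality, the
top five representations by mean pairwise log-loss, takes the union, and
appends the best-performing morphometric distribution so every family stays
represented.

For visualization, per-representation PCA-reduced and PC1-scaled features
are concatenated and embedded with exact t-SNE (perplexity 50, capped below
(n−1)/3 as t-SNE requires; fixed seed; random initialization). Per-type 95%
coverage ellipses use the minimum covariance determinant estimator with the
χ²(2) 0.95 quantile, so a single outlying cell cannot inflate an ellipse.

## Robustness to partial tracings

Incomplete tracings are simulated by removing ⌊f·B⌋ of the B branches at
fraction f ∈ {0.1, …, 0.9}, ranked by descending branch order (ties: larger
start-node path distance first, then smaller node index) — the distal
material an incomplete tracing loses first. A removed branch takes its
entire subtree (descendants have at least its order, so removal sets are
automatically nested across fractions); at least one stem always survives.
The removal unit is the branch *count*, not branch length. Chance level is
estimated by rerunning the identical pipeline on label permutations drawn
from a seeded generator; the min–max band of the shuffled log-losses
brackets ln 2 for balanced pairs.

## Synthetic populations

The generator emulates the regime of locally projecting cortical
interneurons — axon-dominated cells whose types differ mainly in axonal
arbor placement and extent — with a recursive bifurcating random walk: each
segment is a jittered straight walk (step 2 µm, per-step Gaussian direction
jitter), each segment end forks into two daughters up to a fixed depth.
Dendrites: 3 stems, depth 3, segment length 30 ± 8 µm. Axons: 2 stems,
depth 5, segment length 60 ± 15 µm, grown from an anchor displaced along z
by a per-cell stratification depth (cell-to-cell SD 15 µm) and flattened
laterally with a soft 180 µm radius cap. These depths and stem counts give
an expected axonal length share of 2·31·60/(2·31·60 + 3·7·30) ≈ 0.86,
matching the axon-dominated regime of interneuron tracings (realized share
0.85–0.86 over a population).

The default two-type population plants a 75 µm (five cell-to-cell SDs)
stratification-depth difference; a null population draws both types from
identical parameters. The default of 20 cells per type is at the
well-sampled end of real interneuron datasets and was fixed by the
generator's calibration runs: at that size the z-density benchmark resolves
the planted difference at mean log-loss below 0.1, whereas at ~12 cells per
type the one-standard-error shrinkage keeps losses in the 0.05–0.2 range
despite near-perfect accuracy (see above). All randomness flows from one
seed through spawned numpy generators, so equal seeds give byte-identical
SWC output.

What the generator does **not** emulate: realistic branch-angle and
tortuosity statistics, radius tapering, boutons, layer boundaries,
staining-specific truncation, or any biophysical growth rule. Passing
benchmarks on these populations shows the pipeline recovers planted,
well-defined differences; it does not certify performance on real tracings,
where within-type variability is richer and labels are noisy.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
200 random trees for the structural property suites; two-type populations
of 20 cells per type (the calibrated default) for the planted-signal and
chance-level checks; and ten 8-cell-per-type replicate populations with a
single outer repeat for the representation-ranking recovery check, which
tests ordering rather than absolute loss. These sizes are the package's
chosen desk-scale study conditions; the full 10-repeat outer CV is the
default everywhere a config is not passed explicitly.

## Known limitations

* Real-data normalization ranges, histogram maxima and persistence-image
  rectangles are dataset-level state; for reproducing published numbers on
  real datasets they must be supplied as configs rather than refitted.
* The SAGA path solver approximates glmnet's coordinate descent; λ paths
  agree in geometry (λ_max anchor, log spacing) but selected λs can differ
  within one inner-CV SE.
* Euler root angles depend on an arbitrary but fixed decomposition
  convention; compare them only within this package.
* MCD ellipses need enough cells per type (≥ 3 for points, more for a
  stable scatter); tiny types get points without ellipses.
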