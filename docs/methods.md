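# Methods

This note records the models, numerical choices, and validation logic
behind `flowpheno`, in the order the pipeline runs them.

## Data model and scales

An `EventTable` is an events × markers matrix with per-event
`sample_id`, `batch_id`, and `group` metadata and a `scale` flag.
Operations declare which scale they need: gating and transformation
consume `raw` fluorescence units; alignment, correction, clustering,
annotation, and transfer operate on the `transformed` display scale.
Event order within a sample is preserved everywhere; the only sampling
step (down-sampling) is seeded.

FCS support covers uncompressed list-mode 3.0/3.1 files with float,
double, or fixed-width integer data in either byte order ($MODE,
$DATATYPE, $BYTEORD, $PAR, $TOT, $PnB/$PnN/$PnS, $BEGINDATA/$ENDDATA
honored). FCS 2.0 and instrument-grade FCS *writing* are out of scope;
the included writer emits just enough of the standard (float32,
little-endian) to round-trip test fixtures. Marker names come from $PnS
when present, else $PnN.

Pregating is declarative: an ordered list of threshold gates
(marker, direction, cutoff) and ratio gates (e.g. an FSC-A/FSC-H window
as an aggregate proxy), applied sequentially with per-gate retention
counts. Cutoffs are configuration with no universal defaults — debris
and aggregate boundaries are panel- and instrument-specific, so the
shipped gate template is a structure to fill in, not a calibration.

## Logicle transform

The display scale is the fraction of the `M + A` decades: raw intensity
x maps to the unique y with `B(y) = x`, where

    B(y) = a·exp(b·y) − c·exp(−d·y) − f.

Constants follow the standard construction: with span = M + A,
w = W/span, x2 = A/span, x1 = x2 + w, x0 = x2 + 2w, b = span·ln 10, d is
the root of `2(ln d − ln b) + w(b + d) = 0` on (0, b); a, c, f are then
fixed so that B(1) = T and B(x1) = 0. B is strictly increasing
everywhere (B′ = a·b·e^{by} + c·d·e^{−dy} > 0), so the forward transform
is a well-posed scalar root-find: a 2048-point grid interpolation seeds
Newton iteration, converged to 10⁻⁸ in y (verified against independent
bisection in the tests).

Numerical/domain choices:

- The transform is the plain biexponential over its whole domain. It is
  monotone and smooth, and the inverse is closed-form.
- Defaults W = 0.5, M = 4.5, A = 0 (the usual spectral-cytometry
  display); T = 2²² per channel, overridable per marker. T is a display
  convention — every downstream quantity (landmarks, shifts, cluster
  geometry on the display scale) is invariant to its choice because the
  generator and the pipeline share it.
- Values above B(1) are clamped to y = 1 with a counted warning.
  Strongly negative values are solved exactly on a small negative
  display extension (the working range is extended below y = 0 far
  enough to represent −0.2·T) so that forward/inverse round-trip to
  1e−6 relative over [−0.1·T, T]; positions above 1 are a domain error
  for the inverse.
- Scatter-role channels are linearly rescaled to [0, 1] by T rather than
  logicle-transformed.

## Negative-peak batch alignment

Assumption: each marker's negative (unstained/negative-lineage) events
form the lowest-position density mode, and technical batch effects move
that mode additively on the display scale. Per batch × marker the
landmark is located by a Gaussian KDE with Silverman's bandwidth on a
512-point grid over the observed range; a local maximum counts as a mode
only if it reaches 5% of the global density maximum (guards against
tail ripples), and grid endpoints are eligible (truncated
distributions). Constant input returns that constant; fewer than 200
events is an insufficient-data error and the batch falls back to shift
0 with a warning.

`shift(batch, marker) = landmark(reference) − landmark(batch)`; the
reference batch (config `align.reference_batch`, else the first batch)
has shift exactly 0 unless a marker is anchored to an explicit FMO
landmark, in which case every batch — including the reference — moves to
that landmark. Manual per-batch/per-marker overrides in config reproduce
choices an operator would make by inspection. Shifts are additive on the
display scale only, and alignment is idempotent on well-formed data:
re-estimated shifts after application fall below 0.01 display units on
the planted-shift fixture. Alignment is per `batch_id`; per-sample
alignment and full distribution warping are out of scope.

## Balanced down-sampling

When a cohort exceeds the cap (default 200,000 events), each batch gets
an equal quota (cap / n_batches, largest-remainder rounding with ties
broken by batch order). A batch smaller than its quota contributes all
its events; its surplus is redistributed proportionally to the remaining
batches' sizes, iterating until feasible. Within-batch selection is
uniform under the seed; since batches are visited in sorted order, the
chosen within-batch ranks depend only on the seed and the batch
composition, not on event order.

## Harmony correction

The correction implements the iterative procedure of soft k-means with a
batch-diversity penalty plus per-cluster linear correction:

1. **Cluster.** On L2-normalized rows, soft assignments
   R_ik ∝ exp(−‖z_i − c_k‖²/σ) · ((E_kb + 1)/(O_kb + 1))^θ for the
   event's batch b, where O = Rᵀ·Φ are observed cluster × batch counts
   and E their expectation under the global batch frequencies.
   Assignments are refreshed in random blocks (5% of events) with O and
   E updated incrementally — the equilibration that makes the penalty
   converge instead of oscillate.
2. **Correct.** For each cluster, a ridge-penalized weighted regression
   of the original embedding on [1, Φ] (intercept unpenalized and
   retained, batch coefficients penalized with λ = 1 and subtracted,
   weighted by R_k).

Defaults: K = clip(n/30, 2, 100) clusters initialized by k-means
(seeded), σ = 0.1, θ = 2, 10 k-means rounds within up to 10 outer
iterations, early exit when the embedding moves < 10⁻⁴. Deterministic
given the seed. A single batch passes through unchanged with a warning.
The correction runs on the transformed, aligned marker matrix directly
for panels of this size (≤ 20 markers); a PCA front-end is available in
config for larger panels.

The quality contract is behavioral, measured by `batch_mixing_score` —
the mean normalized entropy of batch labels among each event's k nearest
neighbors (1 = perfectly interleaved, 0 = separated; 1 by convention for
a single batch): on a two-batch planted-shift cohort the score rises
from ~0 to > 0.9 while Leiden's recovery of the true populations (ARI)
is preserved, and on batch-free data the mean per-event displacement
stays below 0.05 display units.

## Graph clustering

The global kNN graph is exact (brute-force-equal Euclidean neighbor
lists — an accelerated index would have to be verified exact to be
admissible). Default k = 20, matching the integration step for internal
consistency. Undirected edges are the union of directed kNN relations,
weighted by the Jaccard overlap of the endpoints' neighbor sets with the
endpoint itself included — so mutual duplicates sharing all other
neighbors weigh exactly 1. Plain unit weights are available via config.

Leiden runs on RB-configuration modularity with a per-step resolution
parameter and fixed seed; labels are renumbered by decreasing cluster
size, ties broken by the smallest contained event index. Subclustering
reuses the global graph: the target cluster's induced subgraph is
extracted (no neighbor re-search), its edge weights divided by their
subgraph maximum so resolution values remain comparable across levels,
and Leiden runs again; children extend the parent's label path. The
tests hold this equivalent to running Leiden directly on an
independently rebuilt induced subgraph. Clusters with equivalent
cell-type annotations are consolidated into one flat cluster named by
the smallest merged label. Resolution values are per-dataset
configuration; there is no automatic resolution selection.

A practical geometry note: on strongly separated Gaussian populations
the SNN graph has no cross-population edges, so no resolution merges
them — a "cluster that is secretly a mixture" arises from moderately
separated subsets or from coarser, externally supplied parent labels,
and that is the regime the subclustering tests exercise.

## Annotation statistics

Per (cluster, marker): mean display-scale intensity; mean-corrected
intensity (cluster mean − unweighted grand mean over all events, so
size-weighted cluster means reconstruct the grand mean to 1e−9);
log-fold change as the difference between the cluster's mean and the
mean of all other events — differences on the display scale are
decade-linear at high intensity, which is what makes this a fold change;
and the fraction of events above the marker's positivity landmark
(default: aligned negative peak + 2× the KDE bandwidth; configurable).
Cell types are assigned by an ordered rule list of threshold predicates
over these statistics — first match wins, a fallback label covers the
rest — replacing manual annotation with a reproducible, versionable
config. Dot-plot tables (and a small matplotlib helper) expose the same
numbers for inspection.

## Label transfer

The neighbor search spans all events; the vote is restricted to
annotated neighbors. Confidence is the majority count over the number of
annotated neighbors (config `denominator: k` divides by k instead —
strictly more conservative). An event is discarded when it has no
annotated neighbors, the vote ties, or confidence falls below X/100
(default X = 80; at that threshold a tie can never pass anyway, but
ties are discarded explicitly). Every candidate is either labeled or
discarded; the plurality label of discarded events is retained so
percent mapped can attribute them: for each type,
100 · retained / (retained + discarded-with-that-plurality), with an
empty candidate pool reported as missing, not 0%. Raising X can only
shrink the retained set (asserted across X ∈ {50…100}), and on
well-separated populations transfer accuracy exceeds 0.98 at k = 20,
X = 80. Distance-weighted or probabilistic transfer is out of scope.

## Proportion statistics

Proportions are per sample and parent-relative: `parent_spec` maps each
cell type to its denominator population ("all", or another type — the
parent population then counts the parent's own label plus all labels
declaring it as parent), so nested subsets (CD62L-high within CD4) are
first-class. Zero-parent samples yield missing proportions and leave the
test family.

- **Wilcoxon rank-sum**: midrank ties; exact enumeration p when
  n1 + n2 ≤ 12 and tie-free, else normal approximation with tie and
  continuity corrections. Exactness is held to a full-enumeration oracle
  over every rank configuration for n1 = n2 ≤ 4.
- **Kolmogorov–Smirnov**: D = sup |ECDF difference|; exact p when both
  n ≤ 10, else the asymptotic Kolmogorov distribution at effective size
  n1·n2/(n1+n2). Held to a permutation-enumeration oracle on the same
  grid.
- **Benjamini–Hochberg**: step-up q(i) = min_{j≥i} m·p(j)/j, one family
  per test statistic per run (WRS and KS families are not pooled;
  configurable). Held to a direct step-up implementation on 1,000 random
  vectors.
- **Welch's t**: from summaries (mean, sd, n) — the interface published
  blood-count tables force — or from raw values;
  Welch–Satterthwaite df; both-sds-zero degenerates to p = 1 (equal
  means) or p = 0 with a warning. Held to a quadrature oracle for the
  t tail.

All tests are two-sided. Calibration is verified by simulation: under a
null cohort (no group effect) the WRS type-I error at α = 0.05 sits
within 0.05 ± 0.015 over 2,000 replicates, and a 1.5× proportion shift
in one population with 20 samples per group is detected at q < 0.05 in
≥ 80% of 200 replicates. An optional per-cell expression comparison is
exposed through `ks_two_sample` on pooled per-cell values; pooling cells
across samples is pseudo-replication and inflates significance, so its
p-values rank effects rather than test them. Covariate-adjusted or
mixed-effects modeling is out of scope.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with ground truth exact by construction:

- Populations are Gaussian per marker **on the display scale** — the
  scale on which real populations look compact — then mapped through the
  inverse logicle to raw intensities, so preprocessing is exercised
  end-to-end and display-scale geometry is the ground truth.
- Batch effects are additive display-scale shifts (what alignment
  corrects); raw-scale gain effects are deliberately not simulated.
- Per-sample proportions are Dirichlet draws around group-adjusted means
  (multiplicative per-population group effects, renormalized;
  concentration 200 by default — a realistic between-animal spread of a
  few percentage points for mid-sized populations); observed counts are
  multinomial given the sample's event total, which is lognormal.
- Overlap populations draw a per-event mixing coefficient between two
  parents, producing diffuse transitional bridges; the canonical
  "blend" fixture instead interpenetrates two nearly-touching parents
  with a broad cloud, because a population only maps poorly under label
  transfer when it has no exclusive territory of its own.
- Optional debris/doublet events for pregate testing are constructed in
  the tests directly (extreme ratio/threshold values).

Fixture conditions are fixed in `generate_fixture_library`: a
3-population fixture with ≥ 8 sd separation on defining markers; a
two-batch fixture with a planted 0.10 display-unit shift; the
blend/percent-mapped fixture above; a nested CD62L-high/low-within-CD4
fixture; and a 1.5×-shift cohort with 20 samples per group. Marker names
(CD5, CD4, CD8, CD21, CD14, MHCII, CD62L, viability) are evocative
labels only. What passing these tests shows is that the pipeline's
machinery is correct under its own assumptions; real spectral data adds
unmixing residual correlations, autofluorescence, non-Gaussian
population shapes, and gain-type batch effects that the generator
deliberately does not model, so thresholds tuned on synthetic cohorts
(resolutions, rule cutoffs, gates) always need per-panel review.

## Orchestration and reproducibility

The CLI (`flowpheno run|simulate|validate|stats`) is a thin layer over
the library. Config validation reports every error at once and echoes
the defaults-filled document into the run directory; the run manifest
records package/interpreter versions, per-stage seeds (each stochastic
stage uses its own seed, defaulting to the global one), parameters, and
per-stage event counts. All artifacts are delimited text written with a
fixed float format, so identical configs and seeds reproduce runs
byte-for-byte; an analysis-only rerun (`rerun_analysis`) recomputes the
proportion and comparison tables from the cached labels alone. A stage
failure aborts with the stage name and leaves partial artifacts next to
a `FAILED` marker.

Problem sizes in the test suite and acceptance script — cohorts of a few
thousand to ~12,000 events, 2,000 null replicates at the proportion
level, 200 power replicates — were chosen as the smallest sizes at which
each quantity is stable to well within its asserted tolerance; the
down-sampling checks use full-size (450,000-event) metadata tables since
only the metadata matters there.

## Known limitations

- No spectral unmixing, spillover handling, or FCS 2.0; compensation is
  assumed done upstream.
- Alignment assumes a detectable negative mode per marker per batch;
  markers expressed on essentially all cells need an FMO landmark or a
  manual shift.
- Harmony-style correction removes location (per-cluster mean) batch
  effects; batch-specific variance or shape differences remain.
- Exact kNN is quadratic in events for the percent-mapped/transfer path;
  tens of millions of events would need an (exact-verified) accelerated
  index behind the existing interface.
- UMAP determinism holds per environment (single-threaded, fixed seed);
  coordinates are not guaranteed identical across library versions.
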