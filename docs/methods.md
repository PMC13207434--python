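# Methods

## Problem

At medium resolution (~4–10 Å) a cryo-EM density map shows α-helices as rods
and β-strands as thin, often fragmented densities, but no residue-level
detail.  Map-side detectors reduce each visible secondary-structure element
(SSE) to a *density stick*: an ordered list of 3-D axis points.  On the
sequence side, a predicted or fitted atomic model provides each SSE as an
ordered N→C Cα trace.  Topology determination then consists of two coupled
decisions per stick: *correspondence* (which model SSE does it depict?) and
*orientation* (is its point order the N→C reading or the reverse?).  Both
sets are incomplete in practice — detectors miss, split and merge elements —
so the matching is partial and abstention must be handled and scored.

`ssetopo` implements the downstream topology stage only.  Model building
(I-TASSER/AlphaFold class tools) and density-map SSE detection
(SSETracer/SSEHunter class tools) are upstream producers of its inputs.
Both inputs are assumed to be expressed in a common Cartesian frame; the
pipeline asserts bounding-box overlap but never superimposes.

## Correspondence as type-split supervised classification

Let S = {s_i} be the model SSEs and V = {v_j} the sticks.  Both sets are
split by SSE type, and one classifier per type is trained with each model SSE
as its own class (label = the SSE id).  Each stick of that type is then
classified; the predicted label *is* the proposed correspondence.  The type
split makes helix-to-strand confusions impossible by construction.

**Feature space.**  Every element (trace or stick) is reduced to a fixed
vector: its polyline resampled to k points at equal arc-length stations
(k = 16 for helices, 8 for strands by default — helices are longer and
curvier), the centroid of those points, the unit principal axis of the raw
points (sign fixed first→last so reversal is visible in feature space), the
total arc length in Å, and the raw point count; 3k + 8 dimensions in all.
With this layout a 1-nearest-neighbour rule degenerates to direct curve
proximity, which is the behaviour we want from the parameter-free baseline.
A per-dimension standardizer is fit on the training matrix only and reused at
prediction; constant dimensions standardize to 0.  Voxelization (floor-based,
half-open cells) is retained for representation and diagnostics; the
classifiers operate on the continuous features, which keeps the decision
geometry exact rather than grid-quantized.

**One sample per class.**  A single protein provides exactly one natural
sample per class, which margin- and ensemble-based classifiers cannot use.
Training sets for those kinds are therefore augmented: J = 8 samples per
class, the unperturbed vector plus 7 replicas whose resampled coordinates
carry isotropic Gaussian jitter σ_aug = 0.75 Å (seeded).  σ_aug is set well
below half the guaranteed inter-SSE separation so augmentation can never
bleed classes together; J = 8 is the smallest count at which the SVM and
forest fits were observed to be stable.  The 1-NN (Voronoi) classifier uses
J = 1: its prototype is the exact geometry and jitter could only hurt.

**Classifier kinds and defaults.**  Four families are exposed: linear SVM
(C = 1), RBF SVM (C = 1, γ = 0.01 ≈ 1/n_features, the standard heuristic for
standardized inputs — larger γ collapses the kernel to near-zero between any
two distinct SSE geometries), random forest (100 trees, unlimited depth,
min-split 2, seeded), and the parameter-free Euclidean 1-NN.  Confidence is
reported on each kind's native scale: negative nearest-sample distance,
decision value, or vote fraction.  Hyperparameters can be tuned by
benchmark-level exhaustive grid search (highest mean F1 across proteins; ties
to the first configuration in sorted-key grid order); the default grids are
C ∈ {0.1, 1, 10, 100}, γ ∈ {0.001, 0.01, 0.1, 1}, trees ∈ {100, 300},
depth ∈ {∞, 10, 20}, min-split ∈ {2, 5}.

**Rejection and conflict resolution.**  Classifiers are forced-choice, so two
mechanisms produce unmatched predictions: an optional confidence threshold
(off by default, for parity with forced-choice benchmarking), and conflict
resolution.  Raw predictions may be many-to-one; each contested label is
awarded to the claimant with the smallest orientation-free DTW cost
min(forward, backward) against the SSE's resampled Cα trace (ties break by
stick id).  Losers fall back to their next-best still-unclaimed label if it
clears the threshold, otherwise they are left unmatched.  This greedy rule is
deterministic and one-to-one; a globally optimal assignment (minimum total
cost) is a possible alternative we deliberately did not make the default, as
greedy-by-cost is the simplest reading consistent with per-stick
classification.

## Orientation by dynamic time warping

For a matched pair, the DTW cost between the Cα trace and the stick is
computed twice — stick as stored, and stick reversed.  The recurrence is the
textbook one on squared point distances with D(0,0) = 0, +∞ boundaries and
min over insertion/deletion/match; the cost is the raw accumulated sum,
unnormalized (normalization by path length cancels in the forward/backward
comparison of a single stick; a length-normalized variant exists, default
off, for comparing across sticks).  Direction is +1 only when the forward
cost is strictly smaller; ties resolve to −1 and are logged, since they
indicate palindromic or degenerate geometry.  No warping-window constraint is
applied — sequences are short (tens of points), so the full matrix is cheap.

## Evaluation protocol

With incomplete matching, counts are defined over pairs: TP = predicted pairs
present in the reference, FP = predicted pairs absent from it, FN = reference
pairs missed or wrongly assigned, TN = model SSEs correctly left unmatched.
A wrong correspondence is deliberately counted as both an FP and an FN — the
strictest consistent convention.  Precision, recall and F1 are reported on a
0–100 scale with explicit degenerate conventions (0 when their denominators
vanish).  Per-type accuracy is TP of that type over reference pairs of that
type, as a fraction in [0, 1].  Direction accuracy is computed over correctly
matched pairs only — the direction of a wrong match is meaningless.
Per-protein F1 can be aggregated over sequence-length groups (default cut
points 96/145/228/341/1703, half-open left-closed intervals, last closed) and
methods compared by the classical paired t-test (two-sided, n−1 df); a
zero-variance difference vector yields a distinct degenerate status rather
than a fabricated p-value.

## Synthetic data

The generator produces desk-scale, fully ground-truthed proteins.

*Model side.*  Helices are canonical Cα spirals (radius 2.3 Å, rise
1.5 Å/residue, 100°/residue); strands are near-linear traces with an
alternating ±0.9 Å zig-zag and 3.3 Å/residue rise — standard protein
geometry, so element sizes resemble real annotated sets.  Lengths are drawn
per SSE (helices 8–20 residues, strands 4–10 by default).  Each SSE is
randomly oriented and centered on its own cell of a cubic grid; cells are
assigned by a seeded permutation of the whole grid and centers are jittered
by ±5% of the cell edge.  The permutation + jitter matter: a type-blocked
raster layout would leave entire coordinate axes nearly constant within a
type, which is both unrealistic and degenerate under feature standardization
(near-zero-variance dimensions amplify stick noise arbitrarily).  The cell
edge is the configured placement spacing (20 Å) plus the largest possible SSE
extent, guaranteeing a minimum inter-SSE gap of several Å — far above 2× the
training jitter.

*Stick side.*  Per SSE, in a documented fixed order: a dropout decision
(removed SSEs go to the unmatched ground truth); resampling of the Cα trace
to ~1 axis point per 1.5 Å of arc; erosion of a fraction of points from each
end; additive isotropic Gaussian noise (normals are drawn unconditionally and
scaled by σ, so toggling σ leaves the other draws untouched); fragmentation
at a uniform interior point into at most two children (the larger child
carries the ground-truth pair, the smaller becomes an unmatched stick, and
full parentage is kept in a provenance map); and point-order reversal
(ground-truth direction −1).  All draws come from per-SSE substreams keyed by
the SSE id, so corruption modes can be toggled independently without
perturbing each other.

*What the generator does not emulate:* merging of sticks across neighbouring
SSEs (frequent in real β-sheets), detector confidence profiles, map-intensity
features, model-side error beyond geometry, and anisotropic or spatially
varying noise.  Passing tests on synthetic data therefore demonstrate the
correctness and internal consistency of the pipeline and its robustness to
the modelled corruption modes — not performance on real maps, where upstream
detection quality dominates.

## Numerical choices and edge cases

- Resampling preserves endpoints exactly; a degenerate (single-point or
  all-coincident) input yields k copies of the point.  Resampling is exactly
  idempotent on straight segments and vertex-aligned equal-chord curves; on
  general polylines a second pass shifts points slightly (chord shortcutting),
  which is irrelevant downstream because every consumer resamples the raw
  points once.
- The principal axis comes from an eigen-decomposition of the 3×3 scatter
  matrix; an exactly ambiguous sign (axis orthogonal to first→last) keeps the
  eigenvector as returned.
- DTW ties in conflict resolution break by lexicographic stick id; direction
  ties resolve to −1 (logged).
- Forest training and augmentation take explicit seeds; repeated runs with
  identical configuration are byte-identical, which the test suite asserts.
- Problem sizes used in the shipped checks — 65-SSE clean identity, 20
  replicates of 30-SSE corrupted proteins, 20 replicates per noise level for
  the degradation sweep, 1,000 direction trials, 200 DTW oracle pairs — were
  chosen to exercise the largest benchmark scale the method targets while
  keeping a full run in the order of a minute.

## Known limitations

- Real benchmark reproduction requires external structures, maps and
  third-party detectors and is out of scope; all quantitative claims here are
  about the synthetic study conditions above.
- The greedy conflict resolver can propagate a wrong winner into a cascade of
  next-best reassignments on heavily corrupted inputs; a global assignment
  mode is the natural extension.
- Strand sticks sampled at 1.5 Å spacing have ~2.2× more points than the
  strand has residues, so the raw-count feature dimension is systematically
  offset between the two sides; with standardization and well-separated
  classes this is harmless, but it is the first dimension to revisit for
  borderline real-data cases.
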