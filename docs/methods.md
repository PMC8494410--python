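# Methods

## Problem setting and assumptions

`imlseg` segments N regions of interest at once from a sparse user drawing
with N+1 labels (the extra label is background). Inputs are one or more
scalar channels on a single voxel grid; the package *validates*
co-registration (size and orientation exact; spacing within relative
1e-4; origin within 1e-3 mm — header float noise) but never registers.
Non-identical orientation matrices are rejected rather than resampled: the
method's contract is that the inputs already live on one grid. 2D images
are first-class (D = 2 throughout); a 3D file with a singleton axis is
squeezed.

The model is patient-specific: everything is learned from the drawn voxels
of the scan being segmented, so no claim of generalization across scans is
made or needed.

## Preprocessing

Resampling triggers when max(spacing) − min(spacing) > 0.1 mm (strictly
greater, with a 1e-9 guard so header values intended to sit exactly at the
margin are not pushed over it by float representation) or when the grid
has ≥ 10,000,000 voxels. The working spacing is the smallest isotropic
value s ≥ min(spacing) for which ∏_d round(size_d·spacing_d/s) < 10⁷. The
optimality criterion defines the answer; the search is an implementation
choice: a closed-form seed (∏ extents / cap)^(1/D) snapped to a 0.01 mm
grid anchored at min(spacing), stepped upward until the predicate holds.
Anchoring at min(spacing) makes the result exactly monotone in the cap.
The returned spacing can therefore sit up to one 0.01 mm step above the
continuous optimum, which is far below scanner spacing precision.

Intensities are interpolated linearly, labels nearest-neighbor, with
nearest-neighbor extrapolation at the outer half-voxel edge of the grid
(the resampled extent can exceed the last source voxel center; clamping
beats inventing zeros there). Channels are standardized to zero mean and
unit *population* standard deviation; a constant channel maps to zeros
rather than erroring. Predictions are restored to the original grid by
nearest-neighbor resampling, so the output geometry equals the input
geometry bit-for-bit.

## Adaptive geodesic distance maps

For channel I (standardized) and a label's seed voxels, the map at v is
the cheapest path cost from any seed, a step between neighboring voxels
p, q costing

    dist_mm(p, q) + λ·|I(p) − I(q)|

on the full neighborhood (8 neighbors in 2D, 26 in 3D). Each of the
C·(N+1) maps is normalized to [0, 1] independently (per-map scaling keeps
each feature comparable across labels regardless of its absolute range).

**λ (`intensity_weight`, default 10.0)** prices intensity change in mm of
travel: because channels have unit variance, λ = 10 makes a one-σ jump
cost 1 cm. This is the parameter that turns the maps into soft region
masks — crossing a tissue boundary (several σ) must dominate ordinary
within-tissue travel (a few mm), otherwise the maps degenerate into plain
distance-from-the-drawing transforms and the classifier learns spatial
shortcuts that do not generalize beyond the strokes. We observed exactly
that failure mode at λ of order 1 (foreground Dice collapsing to ~0.2 on
phantoms whose intensities alone separate classes almost perfectly), and
stable recovery for λ in the 10–20 range; the default is the smaller,
round value.

**Solver.** Alternating forward/backward raster sweeps over the full
neighborhood, with a convergence stop ("no value changed in a sweep") and
a pass budget (`max_passes`, default 4 — one pass = one directional
sweep). Two sweep pairs suffice on convex-ish stroke geometry; winding
shortest paths need more, so tests that assert exact agreement with a
Dijkstra reference (to 1e-9, on random 16×16 and 8×8×8 fields) run with a
budget of 64 and rely on the early stop, which typically triggers after
≤ 12 sweeps. The Dijkstra implementation is an independent oracle (sparse
graph + `scipy.sparse.csgraph`), never the production path.

## Features, training set, scaling

Feature order is fixed: C intensities (input channel order), C·(N+1) AGD
values (channel-major, label-minor), D voxel indices (coordinate maps use
indices, not mm — their stated range is 0..size−1). Only drawn voxels
become training rows. Above 3000 rows, a balanced subset of exactly 3000
is drawn: per-class quotas by largest-remainder apportionment (every class
keeps ≥ 1 row; remainder ties break toward the smaller class id), rows
within a class chosen uniformly under the config seed (default 42).

All features are min-max scaled to [0, 1] with bounds learned from the
training rows; application rows are clipped. The chi-squared and
histogram intersection kernels require nonnegative inputs, and a shared
scaling keeps the three kernels' inputs identical; the RBF kernel is
indifferent to the affine map up to its grid-searched γ.

## Ensemble

Kernels: rbf(x,y) = exp(−γ‖x−y‖²); chi2(x,y) = exp(−γ Σ (xᵢ−yᵢ)²/(xᵢ+yᵢ+ε)),
ε = 1e-10; hist(x,y) = Σ min(xᵢ, yᵢ) (no γ). All three SVMs see
precomputed Gram matrices (libsvm via scikit-learn, one-vs-one
multiclass), trained on identical rows. Hyperparameters come from an
exhaustive stratified k-fold grid search maximizing mean CV accuracy:
C ∈ {0.1, 0.5, 2.5, 12.5, 62.5, 312.5, 1562.5} (log-5 steps),
γ ∈ {10⁻³, …, 10} where applicable, 5 folds; ties prefer smaller C, then
smaller γ. If the smallest class has fewer samples than the fold count,
folds shrink to that count (min 2) with a warning. Folds are unshuffled,
so training is deterministic. Prediction fuses the three votes by
majority; a three-way split defers to the RBF model (verified exhaustively
against a brute-force plurality oracle). Whole-volume prediction is
chunked (8192 rows) to bound Gram-matrix memory.

## Pipeline and the corrective loop

`segment` runs: resampling plan → resampling → standardization → AGD stack
→ features → training rows → balanced cap → scaling → ensemble training →
whole-volume prediction → restore to original grid → background-to-0
mapping (the background class, by default the largest drawn label, is
emitted as 0 unless `emit_background` is set). `refine` merges corrective
strokes over the previous drawing (new strokes win on conflicts) and
re-runs `segment` from scratch — stateless retraining keeps the loop
exactly reproducible; AGD maps are recomputed because the seeds changed.
Identical inputs and seed give bit-identical outputs.

## Synthetic phantoms

`make_phantom` builds C-channel images in which each class has a constant
per-channel mean plus i.i.d. Gaussian noise — the minimal structure the
method exploits in real multiparametric scans (per-tissue contrast across
channels). Defaults: 64×64 in-plane × 48 slices at 1 mm isotropic, two
spherical foreground classes on background, means one unit apart in at
least one channel, noise σ = 0.15 (≈ 6.7σ class separation, chosen so the
phantom satisfies its own defining contract: classes recoverable by
nearest-mean thresholding at ≥ 99% accuracy — a phantom whose truth a
threshold cannot recover is not a usable ground truth). What the phantom
deliberately lacks: bias fields, partial-volume boundaries, texture,
spatially correlated noise. Passing phantom tests shows the machinery is
correct and the features behave as designed, not that clinical accuracy
matches any cohort.

`make_scribbles` draws waypoint-directed random-walk strokes (dilated to a
thickness, clipped one voxel inside the class) covering ≈ a given fraction
of each class. The waypoints make strokes sweep across the class region
the way a quick human drawing does; purely local random walks produce
pathologically clustered drawings whose coordinate/AGD features mislead
the classifier. `make_corrective_scribbles` emulates the second-pass user:
true-label strokes over each connected error region of ≥ 20 voxels, plus
a reinforcement round of ordinary scribbles over every class (default 1%
coverage) — without reinforcement, classes that were already correct
receive no new evidence while corrections flood the training set, and
their boundaries can drift on retraining.

## Numerical choices and degenerate inputs

- Both-masks-empty Dice is 1 (agreement on absence); Pearson r on
  zero-variance input raises.
- Constant standardized channel → zeros; constant AGD map → zeros after
  normalization; constant feature → 0 after scaling.
- A class whose strokes vanish during label downsampling raises a
  missing-class error naming the class (the user should draw thicker).
- Labels are int32 end-to-end; float label files are accepted only if
  integral to 1e-6.

## Known limitations

- With very few strokes per class (single-digit training rows), retraining
  after corrections can shift boundaries of classes that were not
  corrected: the AGD features of every voxel depend on *all* seeds, so new
  strokes perturb the whole representation. The reinforcement component of
  the correction round exists precisely to stabilize this; per-class Dice
  is then non-decreasing in our scripted two-iteration runs, but the
  guarantee is empirical, not structural.
- The raster-sweep solver under the default 4-pass budget is an
  approximation on adversarial (spiral-like) intensity fields; converged
  runs match Dijkstra exactly.
- Grid-search accuracy is dominated by the largest class when drawings are
  very unbalanced; the tie-break toward small C then keeps the simplest of
  the equally-scoring models.
- DICOM series, 4D inputs, on-the-fly registration, bias-field correction
  and probabilistic outputs are out of scope.
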