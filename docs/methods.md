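# Methods

This package implements, at desk scale, a complete pipeline for asking
whether image-computable models make human-like 3D shape inferences: it
generates procedural 3D objects and matte-grey renders, builds
within-category match-to-sample trials, trains small single-view and
multi-view networks, simulates human cohorts, and scores models with the
alignment statistics used in visual psychophysics (accuracy, trial-wise
similarity, leave-one-out noise ceiling, STD distances, random-observer
band).  This note records the models, the defaults, and the design
decisions that were genuinely open.

## Procedural shapes

An object starts as an axis-aligned box whose edge lengths are drawn
uniformly from `base_size_range` (default 0.7-1.4 length units; the range
is configuration because only "set by a random seed" is specified upstream
of any concrete value).  A random face is then extruded k times, k uniform
in `[extrude_min, extrude_max]` (default 5-10).  Each extrusion translates
the face along its outward normal tilted by a random angle (uniform in
`[0, angle_range]`, default `angle_range = pi/5`) about a random azimuth,
by a random length (default 0.3-0.9).  Every extrusion removes one face and
adds one top and k side quads, so the mesh stays a closed, consistently
oriented 2-manifold with Euler characteristic 2; this invariant is checked
after generation and preserved by construction at every step.

The cage is smoothed with Catmull-Clark subdivision (default 2 levels for
standalone generation; corpus rendering uses 1 level, which at 32x32 pixels
is visually indistinguishable and four times cheaper).  The subdivision is
the classic scheme (face points, edge points, moved vertices with the
`(Q + 2R + (n-3)P)/n` rule), implemented directly because the generator and
its topology guarantees are the point of the module.

Cages whose triangles intersect (tested pairwise with a Moller segment
-triangle test under an axis-aligned-box broad phase, tolerance 1e-6 of the
bounding-box diagonal) are rejected and resampled, with the rejection count
recorded.

### Categories

A corpus category is a *prototype extrusion program*: base extents plus the
full step sequence, drawn once per category (and itself validated against
self-intersection).  Each object re-runs the program with its steps
jittered — log-normal perturbation of lengths and extents, Gaussian
perturbation of tilt, azimuth and face choice — with relative scale
`jitter` (default 0.35).  Members of a category therefore share coarse 3D
structure and differ in detail, which is the regime where within-category
match-to-sample requires fine shape inference rather than category
recognition.  If a jittered draw keeps self-intersecting, the jitter for
that object is annealed toward the (valid) prototype, so generation always
terminates.  Meshes are centred and scaled to unit bounding radius before
rendering so object size never leaks identity.

## Rendering

The renderer is a deterministic z-buffer rasterizer: perspective camera on
a sphere (radius 3 object-radii) looking at the centroid, square image
plane at unit distance with half-extent 0.47 (chosen so a unit-radius
object always fits in frame with margin), flat Lambertian shading with a
single directional light *fixed in camera coordinates* plus an ambient
term.  Fixing the light to the camera means illumination is identical
relative to every viewpoint, so shading cannot carry viewpoint information.
Viewpoints are area-uniform on the full sphere (normalised Gaussian
triples), the maximum-entropy reading of "sampled from a sphere".  Images
are row-major, origin top-left, intensities in [0, 1], background exactly
0.  Visibility uses perspective-correct interpolated depth; backfaces are
culled by projected winding, which is exact for closed oriented meshes.

## Trials, batches and difficulty conditions

Pairs are object-disjoint and within-category: objects of a category are
shuffled and paired up, so no object appears in two pairs.  (Disjointness
is what actually guarantees the design's novelty property — no participant
ever sees an object twice — once each pair's two trials are split across
the two batches.)  Each pair yields exactly two trials with sample/target
and lure roles swapped.  Sample and target viewpoints are drawn uniformly
without replacement from the object's render catalog; the lure viewpoint is
unconstrained.  The two trials of a pair always land in different batches;
batch sizes are equal.

Difficulty conditions are defined from a models-x-pairs correctness matrix
("zoo"): pairs are sorted by mean-over-models accuracy and cut into
`n_bins` (default 5) contiguous near-equal-count bins, bin 1 hardest; ties
break lexicographically by pair id everywhere, so every ordering is
reproducible.  Adversarial selection takes the k (default 150) pairs with
lowest mean zoo accuracy.  Quantile binning was chosen because the reported
per-condition designs are equal-sized sessions; the bin edges themselves
are not specified anywhere upstream.

## Simulated cohorts

A cohort is participants x trials Bernoulli: P(correct on trial t for
participant i) = clamp(p_t + s_i, 0, 1), with per-trial difficulty p_t ~
Beta(c m, c (1-m)) and per-participant skill s_i ~ Normal(0, skill_sd).
Defaults m = 0.89, c = 10, skill_sd = 0.043: with 150 trials, binomial
noise alone gives a participant-accuracy sd of ~0.026, and the skill
spread brings the combined sd to ~0.05, matching a high-performing online
cohort on this task.  Two batches alternate across participants;
missingness is explicit (a participant has no entry for the other batch's
trials) and never imputed; per-trial human means use only observed
responses, weighting responses (not participants) equally.

## Mini models

All four model families run on a small reverse-mode automatic
differentiation core written for this package (float64 numpy; broadcasting
arithmetic, matmul, strided im2col convolution, the usual nonlinearities),
so training is deterministic bit-for-bit under a fixed seed.  The shared
encoder is a strided 3x3 convolution stack (default channels 8/16/32 at
32x32 input) with a linear readout to the latent (default 48D): structural
fidelity is kept at the latent/hypernetwork/field level rather than in
backbone depth, which matters little at this resolution.

* **Light field network (conditional neural field).**  The encoder infers a
  shape latent from one image; one two-layer ReLU hypernetwork per field
  layer (hidden 64) maps the latent to that layer's weights and bias; the
  field itself is a 4-layer ReLU MLP (hidden 32) from the 6 Plucker
  coordinates of a ray to its colour, with a *linear* RGB head.  (A
  squashing output head saturates against the constant-background solution
  — background pixels are exactly 0 — and kills the gradient before any
  ray structure is learned; with a linear head single-scene overfitting
  reaches per-pixel MSE ~1e-3.)  Rendering queries one ray per pixel
  through the image plane.  The multi-view objective renders a different
  view of the input object (target camera given at render time only, never
  to the encoder); the single-view objective re-renders the input view.
  Training minimises MSE over a random subsample of rays (default 96 per
  image per step); background masking is available behind a flag, default
  off.  Features: the latent, or the field weights flattened layer by
  layer (weight matrix row-major, then bias), PCA-reduced by default to 16
  components fit transductively on the evaluation stimuli.
* **Autoencoders.**  Encoder to latent, MLP decoder (hidden 128, sigmoid
  pixels) back to the image.  The multi-view variant appends a learned
  linear embedding (16D) of the target camera's flattened 3x4 extrinsic
  matrix to the latent and reconstructs the target view.  Feature: the
  latent.
* **Contrastive encoder (multi-view by construction).**  Two views of each
  object per step, in-batch InfoNCE on cosine similarities, symmetrised
  over the two view roles.  In-batch negatives only — the stated objective
  is "relative to negative samples in the minibatch", and a momentum queue
  would add unstated hyperparameters.  Temperature default 0.15: with
  desk-scale batches (~36 negatives) the sharper temperatures used with
  many thousands of negatives made training noticeably less stable across
  seeds.  Feature: the embedding.
* **Classifier (single-view by construction).**  Encoder plus linear head,
  cross-entropy over category labels.  Feature: the penultimate (latent)
  layer.

Single-view code paths index exactly one view per object per step and
never touch a second view.  Optimiser is Adam (lr 2e-3 default); every
training run records a per-epoch loss trace.

## Alignment statistics

A trial is correct when cos(sample, target) strictly exceeds
cos(sample, lure); exact ties count incorrect (the conservative reading of
"higher").  An all-zero embedding raises an error naming the stimulus
rather than silently scoring 0.  Trial-wise similarity is the cosine
between a binary outcome vector and the cohort's per-trial mean
accuracies; for an accuracy-0 vector it is defined as 0 with a warning so
baseline sweeps over a full accuracy grid stay total.  The noise ceiling
is the leave-one-participant-out mean of that similarity within the
cohort, restricted to each participant's observed trials (sd reported with
ddof 0).  STD distances are (score - reference mean) / reference sd.

The random-observer band places k = round(a n) (minimum 1) correct
responses uniformly at random for each accuracy a on a 0.01-step grid,
computes similarity to the human means, and takes the 2.5th/97.5th
percentiles over 1000 simulations; percentiles use linear interpolation
between order statistics (numpy default), stated so bands are exactly
reproducible.  For n <= 12 trials the band is cross-checked in the tests
against exhaustive enumeration of all C(n, k) placements.

## Study conditions for the scaled experiments

The headline comparison (multi-view contrastive vs single-view
autoencoder) runs on a corpus of 8 categories x 32 objects x 20 views at
32x32, with 20 objects per category for training and 12 for evaluation
trials; models train 250 epochs (batch 36).  The out-of-distribution
probe retrains the multi-view models with one category held out (four
categories in turn) for 300 epochs and compares each to its
all-categories counterpart on identical trials built only from the
held-out category's evaluation objects — the comparison that isolates
training-distribution membership from category difficulty.  The longer
schedule matters because specialisation to the training categories — the
effect being measured — grows with training, and averaging over four
held-out categories is what makes the small desk-scale drop (a few
accuracy points) measurable above pair-sampling noise.  These sizes are
the package's chosen desk-scale study conditions: large enough that the
contrastive/single-view ordering and the out-of-distribution drop are
stable across seeds, small enough to run on one CPU core in minutes.

## What the synthetic data does and does not show

The corpus emulates the structure of the original stimuli — matte-grey
renders, sphere-sampled viewpoints, within-category shape similarity — but
not their content: categories are abstract extrusion prototypes, not
vehicles and furniture; images are 32x32, not photorealistic; cohorts are
Bernoulli observers with a Beta difficulty profile, not people.  Passing
tests therefore demonstrate that the *pipeline and statistics* behave as
specified and that the qualitative model-family ordering (multi-view above
single-view; in-distribution above out-of-distribution) emerges under
controlled conditions.  They do not certify numerical agreement with any
full-scale result, which would require the original stimulus sets and
pretrained model zoos.

## Numerical choices and degenerate inputs

* Extrusion face normals use Newell's method, robust to the non-planar
  quads that subdivision and tilted extrusion produce.
* The camera up vector projects world-z out of the view direction,
  falling back to world-x within 1e-8 of the poles.
* Binning with all-equal zoo accuracies degenerates to near-arbitrary
  quantiles and warns.
* A trial observed by only the held-out participant is dropped from that
  participant's noise-ceiling comparison with a warning.
* PCA uses the full SVD solver for determinism; the projection object is
  kept on the reduced feature set.
* Per-stage seeds derive from the master seed by SHA-256 of
  `"{seed}:{stage}"`, so stages can be re-run independently and no two
  stages share a stream.

## Known limitations

* The rasterizer flat-shades per triangle; at 1 subdivision level faceting
  is visible.  This is shared by every view of every object and does not
  favour any model family.
* Contrastive and autoencoder results at this scale have seed-to-seed
  spread of a few accuracy points; conclusions are only drawn from
  orderings that are stable across seeds.
* The optional loader for deposited behavioural data maps common column
  namings into the response schema but has only been exercised against
  synthetic stand-ins generated in the tests, since the deposit is not
  bundled.
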