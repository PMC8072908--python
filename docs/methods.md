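# Methods

## Overview

`mammocad` implements a four-stage breast-mass detection pipeline for
grayscale mammograms:

1. **Morphological highlighting.** Grayscale erosion with a small
   elliptical structuring element (7×7 by default) removes isolated bright
   noise, then dilation with a large elliptical element (50×50) expands
   every surviving bright region into a near-elliptical plateau.  The two
   stages deliberately use different elements, so the composite is *not* a
   morphological opening; it is a shape normalizer that makes bright,
   mass-like regions easy to find with a single circular template.
2. **Template matching.** A parametric circular template (68×60 px, centre
   intensity 117 ramping linearly down to 104 at the inscribed-ellipse
   boundary, 104 outside) is slid over the preprocessed image.  Each patch
   P is scored by the squared-difference distance
   `D(i,j) = Σ_m Σ_n [P(m,n) − T(m,n)]²` (no square root).  Because a raw
   distance has no absolute scale, candidates are thresholded on the
   normalized *matching degree* `1 − D / sqrt(ΣP² · ΣT²)`, which maps an
   exact match to 1, is clipped to [0, 1], and is invariant enough to
   intensity scale to admit a fixed threshold (0.7 by default).  Candidates
   are the local maxima of the degree map (a cell ≥ its 8 neighbours;
   plateaus contribute their centroid), each carrying a template-sized box.
3. **Patch classification.** Overlapping candidates are merged to a
   fixpoint (union box whenever IoU > 0.3), cropped from the *original*
   image, resized to 200×200 and classified by a small CNN (three blocks of
   128 kernels — 5×5, 3×3, 3×3 — each conv → batch-norm → ReLU → 2×2
   max-pool; FC-1024; softmax-2).  Candidates with P(mass) below the
   decision threshold (0.5) are rejected.
4. **PSO bounding-box refinement.** Each accepted box is refined by a
   particle swarm over (centre x, centre y, width, height) inside the box
   expanded by 30% of its width/height on every side.  Velocities follow
   `V ← V + cp·rand()·(pbest_pos − X) + cg·rand()·(gbest_pos − X)`,
   `X ← X + V`, with cp = cg = 0.5, 20 particles, 20 iterations; the
   fitness of a decoded box is the classifier's P(mass) for its crop.

## Design choices in ambiguous territory

Several details are under-determined by the published description; the
choices below are this package's own and are localized in config objects.

- **Matching degree.** Only the squared-difference distance is given a
  formula; the thresholded "degree" in [0, 1] is not.  We use the
  normalization `1 − D / sqrt(ΣP²·ΣT²)` (a standard normalized
  squared-difference similarity).  Conventions for degenerate patches:
  both patch and template all-zero → 1 (identical); exactly one all-zero
  → 0.  The raw distance map remains available.
- **Distance exactness.** `D` is computed via
  `ΣP² − 2·corr(P, T) + ΣT²` with an FFT cross-correlation plus
  integral-image window sums; for integer-valued inputs the result is
  rounded to the nearest integer, which makes it *exact* (all true values
  are integers far below 2⁵³).
- **Border policy** for morphology: edge replication, so constant images
  are fixed points and borders are not darkened.
- **Merging**: the merged box is the union (smallest enclosing box), the
  merged degree the max of the pair; pairs are merged highest-IoU-first to
  a fixpoint with deterministic tie-breaks (degree desc, x, y), making the
  result independent of input order.
- **PSO best-position bookkeeping.** The published pseudo-code assigns a
  fitness *scalar* to `pbest` yet subtracts `pbest` from a position
  *vector*; as printed it cannot execute.  We keep best positions and best
  fitnesses separately per particle and globally — the canonical PSO the
  update equations intend.
- **PSO initialization.** The pseudo-code starts every particle at the
  rough box with zero velocity, under which the velocity update produces
  zero motion forever.  Particle 0 stays at the rough box (so the returned
  fitness is never below the rough box's); by default the rest are drawn
  from a Gaussian around the rough box (σ = 25% of its width/height per
  coordinate) with small random velocities (≤ 10% of the region size).
  Refinement is a *local* regression of an already-located box; scattering
  particles uniformly over the whole search region (available as
  `init="scatter"`) turns it into a global search that can jump to a
  spurious probability maximum far from the rough box — observed as
  occasional large overlap losses on synthetic phantoms.
- **PSO numerics.** No inertia weight (the update has none), so velocity
  magnitudes do not decay; they are clamped to ±15% of the search-region
  size per coordinate — the PSO literature's usual vmax of 10–20% of the
  dynamic range — since a ±50% clamp lets a particle cross the entire
  region in two steps, degenerating into random search.  Decoded boxes are
  clamped to the search region with a minimum size of 8×8 px; `rand()` is
  drawn independently per coordinate, per term, per particle, per
  iteration.  Two early-exit rules, both config-exposed: iteration stops
  once the swarm best reaches 1 − 10⁻⁶ (fitness is bounded by 1, so less
  than 10⁻⁶ of fitness can be forgone), and — in the detection pipeline's
  default configuration — after 5 consecutive sweeps in which the swarm
  best improved by less than 10⁻³ (`stagnation_patience`; the iteration
  cap stays at 20).  The gbest trace is padded to full length so it
  remains comparable across runs.
- **CNN details not specified upstream**: stride-1 zero-padded ("same")
  convolutions and 2×2/stride-2 pooling (giving 25×25×128 feature maps
  before flattening); conv → BN → ReLU → pool block order; He weight
  initialization from a config seed; intensities divided by 255 before the
  network; cross-entropy loss; batch size 8 (chosen for single-core CPU
  training: per-image step cost is flat across batch sizes while peak
  memory scales linearly, and smaller batches give more SGD updates per
  epoch at the fixed learning rate 10⁻⁴).
- **Stopping rule**: training stops at 200 epochs (50 in the acceptance
  runs; see below) or as soon as the training accuracy — recomputed on the
  full training set after each epoch, in inference mode — reaches 100%.
- **Evaluation.** A detection is a true positive iff greedily matched
  one-to-one (by descending probability, then IoU) to an unclaimed truth
  box at IoU ≥ 0.5 (configurable); TPR and FPI are detection-level over
  accepted candidates, while accuracy/precision/recall/F1 are computed at
  the candidate-classification level (was each merged candidate correctly
  called mass or background), which is how a TPR and a recall can be
  reported as distinct numbers.

## The NumPy network

No deep-learning framework is used: the classifier runs on a small NumPy
layer library (`mammocad.nn`) written for single-core CPUs.  Convolutions
are im2col + GEMM in NHWC layout; the patch matrix is assembled
offset-by-offset with contiguous strided copies; all large activations and
gradients live in persistent per-layer buffers reused across minibatches
(on one core, allocating and first-touching fresh hundreds-of-MB
temporaries costs far more than the GEMMs).  Max-pool backward routes
gradients by value equality; in the measure-zero event of an exact tie
within a window both cells receive the gradient.  Training is reproducible
bit-for-bit from the config seed on a given platform.  Peak resident
memory at batch 8 is ≈2.7 GB (dominated by the first block's 200×200×128
activations and the 80000×1024 dense layer).

## Synthetic phantoms

Real screening data (DDSM) is neither required nor bundled.  The
`mammocad.synth` module generates seeded phantoms that emulate exactly the
gross structure the pipeline relies on: a dark background (level 40),
smooth low-frequency tissue-like texture (Gaussian-filtered white noise,
σ ≈ 12 px, amplitude 8), additive Gaussian pixel noise (σ = 4), and 1–3
bright elliptical masses (semi-axes 26–33 × 22–29 px, peak 70–95 above
background, edges blurred with σ = 3 px) planted at known, non-overlapping
locations, all on an 8-bit intensity scale.  Mass sizes are chosen on the
scale of the 68×60 matching template — the operating regime of a
fixed-template detector; the published method itself misses masses whose
highlighted shape departs from that template.  Intensities are placed so
that after preprocessing mass plateaus land in the template's 104–117
regime (degree ≈ 0.9–1.0) while the dilated background stays near degree
0.55–0.65, below the 0.7 threshold.

Placement respects the detector's resolution geometry.  The 50×50
dilation expands every mass footprint by ~25 px per side, so two masses
whose expanded footprints touch are highlighted as a single region that no
single-template matcher can resolve into two detections; phantoms
therefore enforce an edge-to-edge gap of 50 px (two dilation radii)
between mass boxes.  Likewise a mass closer to the border than the
template half-size plus the dilation radius (≈ 60 px) produces a clipped,
spatially biased score plateau, so masses keep a 64 px margin.  Both
constants derive from the kernel and template geometry, not from data.

Training patches follow the published dataset construction: mass patches
are ground-truth boxes with ≤ 10% random jitter in position and size;
background patches (intersection-free with every mass box) are drawn half
from the *brightest* mass-free structure in each phantom and half
uniformly.  The bright negatives matter: the published training set's
backgrounds are all template-matching false candidates — bright non-mass
regions — and without such hard negatives the classifier cannot rank
partially aligned crops, which the PSO fitness requires.

What the phantoms do *not* model: pectoral muscle, skin line, labels and
artifacts, ductal/vascular structure, spiculated or non-elliptical masses,
and scanner-specific noise.  Passing the synthetic acceptance suite
therefore demonstrates that every stage is implemented and wired correctly
and that the method behaves as designed in its intended regime — not that
it reproduces clinical detection rates on DDSM.

## Problem sizes in the test and acceptance runs

The acceptance suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen as a deliberate study design: phantoms are 512×384 (no
resizing; the 1500×2000 resize default applies to full mammograms),
classifier training uses 400 patches (200 per class) capped at 50 epochs
with held-out evaluation on 100 patches from a disjoint phantom stream,
and the pipeline is evaluated on 20 (test suite) or 12 (acceptance script)
two-mass phantoms from a third disjoint stream.  Unit tests exercise the
same code paths on further reduced configurations (e.g. a 32×32-input,
8-kernel classifier).

## Known limitations

- The PSO fitness is the probability head of a classifier that stops
  training as soon as it reaches 100% training accuracy — on clean
  synthetic patches that is a single epoch, which leaves the network
  underfit.  How such a network *ranks* different mass-containing crops is
  partly an idiosyncrasy of the training draw: with some training seeds
  refinement reliably tightens boxes, with others it can degrade them and
  the probability–overlap correlation weakens or inverts.  The study
  condition therefore fixes the training stream and initialization (seed
  0) and varies the evaluation data; robustness across training draws
  would require a stronger stopping rule or harder training data than the
  published recipe specifies.
- Greedy detection-truth matching can in principle differ from the optimal
  assignment; on random small instances the test suite observed no
  disagreement, but no optimality guarantee is claimed.
- The matching degree saturates for bright constant patches; discrimination
  relies on the background staying well below the template's intensity
  band, which the morphology's dilation stage is responsible for.
- Multi-channel input is handled by channel averaging only; no true
  luminance weighting.
- The CNN runs in float32; bitwise reproducibility holds per platform/BLAS,
  not across platforms.
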