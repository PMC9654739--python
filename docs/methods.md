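# Methods

`olivesort` re-creates, in software, a conveyor-belt pipeline for grading
olive fruit into five quality classes — Bad Black, Good Black, Bad Green,
Good Green, Top Green — defined by skin veraison (green → black ripening) and
visible damage. The pipeline has four computational stages: colorimetric
calibration, belt acquisition (encoder + segmentation + tracking),
classification, and sorter-stream evaluation. A synthetic-data generator
supplies every input with exact ground truth.

## Thin-plate-spline colour calibration

Each acquired frame contains a 24-patch ColorChecker chart with published
sRGB values (the classic pre-2014 table is the default; the edition is
selectable because published value sets differ). The measured patch colours
`c_i ∈ R³` and reference colours `y_i` define a vector-valued thin-plate
spline over RGB space, one scalar TPS per output channel with shared
geometry:

    f(x) = a₀ + a·x + Σᵢ wᵢ φ(‖x − cᵢ‖),   Σᵢ wᵢ = 0,  Σᵢ wᵢ cᵢ = 0.

The linear system (kernel block `K + λI`, affine block `P = [1 | c]`, side
conditions `Pᵀw = 0`) is solved once for all three channels. Two kernels are
offered: `r3d`, φ(r) = r, the biharmonic fundamental solution in three
dimensions and the natural choice for the 3-D colour domain (default); and
`r2logr`, φ(r) = r² log r, the classical 2-D kernel, for fidelity to
2-D-derived implementations. Both interpolate the 24 control points exactly
at λ = 0, and the tests exercise both. The 3-D vector fit (rather than
channel-wise 2-D projections) is the default because the colour distortions
being corrected mix channels.

λ defaults to 0 — exact interpolation — because the chart measurement is a
mean over hundreds of pixels and essentially noise-free; λ > 0 is available
for noisy charts, and the calibration report shows the control-point RMSE so
the trade-off is visible (smoothing strictly increases it). Degenerate
geometry (coincident or coplanar measured patches) makes the λ = 0 system
singular; the fit detects it up front and names the offending patches.

Corrected images are clipped to [0, 255], never rescaled, preserving sRGB
range semantics; the fraction of clipped pixels is reported. Chart patch
ROIs come from configuration (a YAML list of 24 `[x, y, w, h]` rectangles)
or from the generator: automatic chart detection is out of scope.

## Belt acquisition

The belt position is read from a two-channel rotary encoder with 1024 ticks
per revolution. ×4 quadrature decoding advances the count on every valid
Gray-code transition of the channel pair, yielding 4096 effective counts per
revolution and the direction of rotation; transitions where both channels
flip simultaneously are ambiguous and are tallied rather than applied.
Displacement is `count / (4·ticks_per_rev) × roller_circumference`. The belt
runs at 1 cm/s with a frame every 15 s, so consecutive frames are 15 cm
apart; with the default synthetic field of view of 20 cm (400 px at
0.05 cm/px — the real camera geometry is not published, so the scale is a
configuration parameter) frames overlap by 5 cm and no fruit is lost at
frame boundaries. Without an encoder trace, frame positions fall back to
`timestamp × belt speed`.

Segmentation is a background-colour distance threshold (Euclidean RGB,
default tolerance 40) followed by 8-connected components with a minimum area
(default 50 px); the source material does not specify a method, so the
simplest one adequate for a uniform belt was chosen. A detection's belt
coordinate is the frame's belt position plus its centroid column times the
pixel scale. Detections of the same olive across overlapping frames are
merged when their belt coordinates agree within 1 cm and their transverse
rows within 12 px; the representative crop is taken from the frame where the
bounding box sits farthest from the image borders (earliest frame on ties),
avoiding views truncated at a frame edge.

## Classifier and training protocol

The dataset is split 70/30 by a seeded uniform permutation with
`|train| = floor(0.7·n)` — at the study composition of 557 crops this gives
389/168. Training is stochastic gradient descent with momentum (0.9, a
conventional value; it is not stated in the protocol), mini-batch 10, 10
epochs, reshuffling every epoch, keeping the partial final batch, so 557
crops train for exactly 390 iterations. No data augmentation. Validation
accuracy is logged every 6 iterations on the held-out test set, which never
contributes gradients. The head is a softmax over the five classes; the
predicted class is the largest probability component, ties broken toward the
lowest class index.

The backbone is pluggable. The default, `compact_cnn`, is a from-scratch
numpy network: 32×32 RGB input (crops are centre-padded to square with their
border colour, then bilinearly resized), one 3×3 convolution with 8 filters,
ReLU, 2×2 average pooling, a 64-unit dense ReLU layer, and the 5-way softmax.
It trains on one CPU core in a few seconds. Learning rates: the protocol
default of 1e-4 is retained on `TrainConfig` and suits fine-tuning a
pretrained backbone; a randomly initialised compact net needs a larger step,
so `TrainConfig.for_compact_net()` sets 1e-2, which reaches perfect held-out
accuracy on the default synthetic composition. All stochastic stages (split,
shuffling, weight initialisation) take explicit seeds.

## Sorter-stream evaluation

Re-imaging a sorter's output streams on the conveyor and classifying them
produces a streams-by-classes cross-tabulation. From it the module computes:
column composition percentages (`col_total / grand_total × 100`, one
decimal), stream purity (share of a stream's row in the classes of its
nominal colour group — Bad/Good Black are black; Bad/Good/Top Green are
green — nearest integer percent), and blend fractions (share of the grand
total in a chosen class subset, nearest integer percent; monotone under
superset inclusion). All rounding is half-away-from-zero, matching how such
tables are reported. Ingested tables that carry printed row totals are
checked against recomputed marginals; disagreements are flagged in the
report, not fatal, since published tables do occasionally contain such
inconsistencies. Lot bookkeeping (summing per-colour lot weights per sorting
speed) is a one-line helper kept here for completeness.

## Synthetic data

The generator emulates the study conditions: olives as hard-edged ellipses
(no anti-aliasing, so segmentation ground truth is exact) on a uniform belt
background, class-conditioned mean colours with Gaussian pixel noise
(σ = 4), defect spots (1–3 dark-brown ellipses) on the "Bad" classes, frame
sequences at 1 cm/s × 15 s spacing, the 24-patch chart under known smooth
distortions, and ideal 90°-phase-shifted encoder waveforms. The default
dataset composition is the study lot: 114/113/80/112/138 crops per class,
557 total. Class mean colours are invented (no pixel statistics exist for
the real fruit): greens around (90, 140, 60), blacks around (45, 35, 50),
chosen so that pairwise class-mean separation is at least 5 noise standard
deviations — separable but not trivially so, which makes the ≥0.95
held-out-accuracy property well-posed.

Colour distortions: `affine` (gain 0.9, offset 10), `gamma_mix` (per-channel
gamma 1.3 plus mild channel mixing), and `random_smooth`, which draws
per-acquisition gamma/gain/offset/mixing parameters to model illumination
drift between acquisitions — the reason a chart is imaged in every frame of
the real rig. Every generator output carries a machine-readable truth
record; no test reads external data.

What the generator does **not** model: specular highlights, shading and
shadows, texture within the fruit, motion blur, belt vibration, partial
occlusion between touching fruit, or sensor noise correlated across
channels. Passing tests therefore demonstrate the correctness of the
pipeline's arithmetic and its behaviour under controlled colour drift, not
field performance on real fruit imagery.

## Pipeline

`run_pipeline` chains the stages — generate, (calibrate), segment/track,
train/classify, evaluate — with every random stage seeded from one root seed
via independent spawned streams, so identical configs produce byte-identical
summary JSON. The virtual sorter routes held-out olives into
colour × speed streams, flipping the colour decision with a configurable
error rate (default 0.2) to mimic an imperfect physical sorter, and the
stream evaluator scores the classifier's predictions per stream. With
per-acquisition drift enabled, the calibrated run's held-out accuracy is
expected to meet or exceed the uncalibrated run's, and the default problem
sizes (557 crops, 24 olives over ~4 frames) keep a full run under ten
seconds on one CPU core.

## Known limitations

- The compact backbone keys on colour and coarse shape; classes separable
  only by subtle texture would need a deeper (or pretrained) backbone.
- Track merging assumes a forward-running belt and sparse, non-touching
  fruit; clusters of touching olives segment as one component.
- TPS extrapolation outside the convex hull of the 24 measured chart
  colours is unconstrained; extreme pixels rely on the affine tail and are
  clipped on output.
- The quadrature decoder assumes logic-level samples; analogue glitches must
  be cleaned upstream (invalid transitions are only counted).
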