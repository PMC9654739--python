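# olivesort

A toolkit for conveyor-belt optical grading of olive fruit. Olives destined
for extra virgin olive oil are classified into five quality classes defined
by skin veraison and visible damage — **Bad Black, Good Black, Bad Green,
Good Green, Top Green** — and the toolkit covers the whole imaging pipeline
around that classification:

- **`colorcal`** — thin-plate-spline (TPS) colour calibration: a 24-patch
  ColorChecker chart with known sRGB values is imaged in each frame, and a
  vector-valued TPS over RGB space,
  `f(x) = a₀ + a·x + Σᵢ wᵢ φ(‖x − cᵢ‖)` with the standard side conditions,
  warps the measured patch colours onto the reference values and corrects
  every pixel of the frame.
- **`acquisition`** — ×4 quadrature decoding of a two-channel rotary encoder
  (1024 ticks/rev → 4096 counts/rev), belt-coordinate conversion,
  background-threshold segmentation of olive blobs, and merging of
  detections across overlapping frames (belt at 1 cm/s, frame every 15 s)
  into per-fruit tracks.
- **`classifier`** — a 5-class softmax classifier trained with SGDM
  (mini-batch 10, 10 epochs, reshuffled every epoch, partial final batch
  kept: a 70/30 split of 557 crops trains on 389 crops for exactly 390
  iterations). The default backbone is a compact numpy conv net that trains
  on a CPU in seconds; backbones are pluggable.
- **`sorter_eval`** — scoring an industrial sorter's output streams against
  the conveyor classifier: stream × class cross-tabulation, composition
  percentages, stream purity, and oil-blend fractions.
- **`synthgen`** — synthetic olives, frames, charts and encoder waveforms
  with exact ground truth, emulating the acquisition geometry above.
- **`cli`** — the `olivesort` command (`synth`, `calibrate`, `segment`,
  `train`, `predict`, `evaluate`, `run`) and a fully seeded end-to-end
  pipeline with byte-reproducible summaries.

## Worked example: scoring a sorter run

The sorter routes fruit into colour × vibrator-speed streams; re-imaging
each stream on the conveyor and classifying the crops gives a stream-by-class
count table, which the evaluator turns into the statistics a mill cares
about:

```python
import numpy as np
from olivesort import sorter_eval

counts = np.array([
    [187, 81, 531, 281, 21],    # Black slow
    [28, 266, 63, 132, 283],    # Green slow
    [60, 36, 262, 127, 10],     # Black fast
    [10, 89, 25, 67, 153],      # Green fast
])
ct = sorter_eval.StreamCrossTab(
    ("Black slow", "Green slow", "Black fast", "Green fast"),
    sorter_eval.CLASS_ORDER, counts,
)
print("composition %:", sorter_eval.column_percentages(ct))
for s in ct.rows:
    print(f"{s} purity: {sorter_eval.stream_purity(ct, stream_id=s)}%")
for b in sorter_eval.STANDARD_BLENDS:
    print(f"{b.name}: {sorter_eval.blend_fraction(ct, b)}% of the lot")
```

prints

```
composition %: (10.5, 17.4, 32.5, 22.4, 17.2)
Black slow purity: 65%
Green slow purity: 88%
Black fast purity: 65%
Green fast purity: 90%
superior EVOO: 17% of the lot
high quality green: 40% of the lot
high quality: 72% of the lot
```

Reading: 10.5% of all sorted fruit was Bad Black, 17.2% Top Green; 65% of
what the sorter ejected as "black" really was black fruit (at either speed);
and pressing only the Top Green class would use 17% of the lot, Top + Good
Green 40%, adding Good Black 72%.

An end-to-end synthetic run — generate a drifting-illumination conveyor
scene, calibrate from the in-frame chart, segment, track, train and
evaluate — is one call:

```sh
olivesort run --out runs/demo        # writes summary.json, tracks.csv, crosstab.csv
```

or from Python, `olivesort.cli.run_pipeline({"seed": 5, "distortion":
"random_smooth", "calibration": {"enabled": True}}, "runs/demo")`. On the
default configuration the calibrated run reaches held-out accuracy 1.0
versus 0.83 uncalibrated, with all 24 placed olives recovered as single
tracks.

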