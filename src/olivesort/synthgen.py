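"""Synthetic conveyor scenes with exact ground truth.

Emulates the study conditions end to end: olive-shaped blobs with
class-conditioned colour and defect statistics on a belt background, frame
sequences consistent with a 1 cm/s belt and 15 s frame interval (so
consecutive frames overlap), a 24-patch chart under known smooth colour
distortions, and ideal quadrature encoder waveforms.  Rendering is hard-edged
(no anti-aliasing) so segmentation ground truth is exact, and every output
ships a machine-readable truth record.

The five class colour models are invented (no pixel statistics are published
for the real fruit): greens around (90, 140, 60), blacks around (45, 35, 50),
defect spots dark brown, with pairwise class-mean separation at least five
noise standard deviations so the classes are separable yet non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import QUAD_CYCLE, EncoderTrace, FrameRecord
from .classifier import CLASSES, LabeledDataset
from .colorcal import ChartObservation, ChartReference, classic_reference

__all__ = [
    "BACKGROUND_RGB",
    "TABLE_CLASS_COUNTS",
    "ClassColorModel",
    "SceneSpec",
    "OlivePlacement",
    "default_class_model",
    "make_crop",
    "make_dataset",
    "make_frames",
    "make_distorted_chart",
    "make_encoder_trace",
    "distort_colors",
    "sample_smooth_distortion",
    "apply_smooth_distortion",
    "regular_placements",
]

BACKGROUND_RGB = (150, 150, 155)

# Dataset composition of the labelled study lot (557 crops).
TABLE_CLASS_COUNTS = {
    "Bad Black": 114,
    "Good Black": 113,
    "Bad Green": 80,
    "Good Green": 112,
    "Top Green": 138,
}


@dataclass(frozen=True)
class ClassSpec:
    mean_rgb: tuple
    sigma: float = 4.0
    spot_count_range: tuple = (0, 0)      # inclusive; >0 only for "Bad" classes
    spot_rgb: tuple = (70, 40, 25)
    spot_radius_range: tuple = (2, 5)


@dataclass(frozen=True)
class ClassColorModel:
    """Per-class colour/defect statistics plus the belt background colour."""

    classes: dict
    background_rgb: tuple = BACKGROUND_RGB

    def __post_init__(self) -> None:
        if set(self.classes) != set(CLASSES):
            raise ValueError("model must cover exactly the 5 classes")

    def min_separation_over_sigma(self) -> float:
        means = np.array([self.classes[c].mean_rgb for c in CLASSES], dtype=float)
        sigma = max(self.classes[c].sigma for c in CLASSES)
        d = np.linalg.norm(means[:, None] - means[None, :], axis=2)
        return float(d[np.triu_indices(len(CLASSES), 1)].min() / max(sigma, 1e-12))


def default_class_model() -> ClassColorModel:
    return ClassColorModel(
        classes={
            "Bad Black": ClassSpec((45, 35, 50), spot_count_range=(1, 3)),
            "Good Black": ClassSpec((60, 50, 65)),
            "Bad Green": ClassSpec((100, 120, 55), spot_count_range=(1, 3)),
            "Good Green": ClassSpec((95, 150, 70)),
            "Top Green": ClassSpec((80, 170, 60)),
        }
    )


def _render_ellipse(canvas, center_rc, axes_rc, color):
    h, w = canvas.shape[:2]
    rr, cc = np.ogrid[:h, :w]
    mask = ((rr - center_rc[0]) / axes_rc[0]) ** 2 + (
        (cc - center_rc[1]) / axes_rc[1]
    ) ** 2 <= 1.0
    canvas[mask] = color
    return mask


def make_crop(cls: str, model: ClassColorModel | None = None, seed: int = 0, size: int = 64):
    """Render one labelled olive crop; returns ``(image, truth)``.

    The olive is a hard-edged ellipse of the class colour with per-pixel
    Gaussian noise; "Bad" classes receive at least one dark defect spot.
    """
    model = model or default_class_model()
    if cls not in model.classes:
        raise ValueError(f"unknown class {cls!r}")
    spec = model.classes[cls]
    rng = np.random.default_rng(seed)
    img = np.empty((size, size, 3), dtype=float)
    img[:] = model.background_rgb
    center = (size / 2.0, size / 2.0)
    axes = (
        size * 0.32 * (1 + rng.uniform(-0.1, 0.1)),
        size * 0.40 * (1 + rng.uniform(-0.1, 0.1)),
    )
    olive_mask = _render_ellipse(img, center, axes, spec.mean_rgb)

    lo, hi = spec.spot_count_range
    n_spots = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    spot_centers = []
    for _ in range(n_spots):
        r = rng.uniform(*spec.spot_radius_range)
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.6)
        sc = (center[0] + rho * axes[0] * np.sin(theta), center[1] + rho * axes[1] * np.cos(theta))
        _render_ellipse(img, sc, (r, r), spec.spot_rgb)
        spot_centers.append((float(sc[0]), float(sc[1])))

    if spec.sigma > 0:
        noise = rng.normal(0.0, spec.sigma, img.shape)
        img[olive_mask] += noise[olive_mask]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {
        "class": cls,
        "mean_rgb": tuple(float(v) for v in spec.mean_rgb),
        "sigma": spec.sigma,
        "spot_count": n_spots,
        "spot_centers": spot_centers,
        "center": center,
        "axes": tuple(float(a) for a in axes),
        "olive_area_px": int(olive_mask.sum()),
    }
    return img, truth


def make_dataset(
    counts: dict | None = None,
    seed: int = 0,
    size: int = 64,
    model: ClassColorModel | None = None,
    out_dir=None,
):
    """Generate a labelled crop dataset; defaults to the study composition
    (114/113/80/112/138 across the five classes, 557 crops total).

    Returns ``(LabeledDataset, manifest DataFrame, truths)``; with ``out_dir``
    the crops are written as PNGs next to a ``manifest.csv``.
    """
    counts = dict(counts) if counts is not None else dict(TABLE_CLASS_COUNTS)
    model = model or default_class_model()
    seeds = np.random.SeedSequence(seed).spawn(sum(counts.values()))
    items, truths, rows = [], [], []
    i = 0
    for cls in CLASSES:
        for k in range(counts.get(cls, 0)):
            crop_seed = seeds[i].generate_state(1)[0] % (2**31)
            img, truth = make_crop(cls, model, seed=int(crop_seed), size=size)
            items.append((img, cls))
            truths.append(truth)
            rows.append({"crop_path": f"crop_{i:05d}.png", "label": cls})
            i += 1
    manifest = pd.DataFrame(rows, columns=["crop_path", "label"])
    if out_dir is not None:
        from pathlib import Path
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (img, _), row in zip(items, rows):
            Image.fromarray(img).save(out / row["crop_path"])
        manifest.to_csv(out / "manifest.csv", index=False)
    return LabeledDataset(tuple(items)), manifest, truths


# --------------------------------------------------------------------------
# Colour distortions and the chart
# --------------------------------------------------------------------------

_MIX = np.array(
    [[0.95, 0.04, 0.01], [0.02, 0.95, 0.03], [0.03, 0.02, 0.95]]
)


def sample_smooth_distortion(rng: np.random.Generator) -> dict:
    """Draw per-acquisition distortion parameters (illumination drift model).

    Each acquisition of the real rig sees its own illumination/sensor state,
    which is why a chart is imaged in every frame.  The drift is modelled as
    per-channel gamma plus gain/offset and a mild channel mixing.
    """
    return {
        "gamma": rng.uniform(1.05, 1.5, 3).tolist(),
        "gain": float(rng.uniform(0.85, 1.05)),
        "offset": float(rng.uniform(-10.0, 15.0)),
        "mix": float(rng.uniform(0.0, 0.06)),
    }


def apply_smooth_distortion(rgb, params: dict):
    x = np.clip(np.asarray(rgb, dtype=float) / 255.0, 0.0, 1.0)
    u = x ** np.asarray(params["gamma"], dtype=float)
    m = (1.0 - params["mix"]) * np.eye(3) + params["mix"] / 2.0 * (
        np.ones((3, 3)) - np.eye(3)
    )
    out = (u @ m.T) * 255.0 * params["gain"] + params["offset"]
    return np.clip(out, 0, 255)


def distort_colors(rgb, distortion):
    """Apply a known smooth colour distortion to an (..., 3) array in [0,255].

    ``distortion`` is either a fixed id (``identity``; ``affine`` = gain 0.9
    plus offset 10; ``gamma_mix`` = per-channel gamma 1.3 followed by a mild
    channel-mixing matrix) or a parameter dict from
    :func:`sample_smooth_distortion`.  Results are clipped.
    """
    x = np.asarray(rgb, dtype=float)
    if isinstance(distortion, dict):
        return apply_smooth_distortion(x, distortion)
    if distortion == "identity":
        return x.copy()
    if distortion == "affine":
        return np.clip(0.9 * x + 10.0, 0, 255)
    if distortion == "gamma_mix":
        u = np.clip(x / 255.0, 0.0, 1.0) ** 1.3
        return np.clip(u @ _MIX.T * 255.0, 0, 255)
    raise ValueError(f"unknown distortion {distortion!r}")


def make_distorted_chart(
    reference: ChartReference | None = None,
    distortion: str = "identity",
    seed: int = 0,
    patch_size: int = 20,
    gap: int = 4,
    noise_sigma: float = 0.0,
):
    """Render the 24-patch chart (6x4 grid) under a colour distortion.

    Returns ``(image, observation_truth, patch_rois)`` where the observation
    pairs the exact distorted patch colours with the reference values.
    """
    reference = reference or classic_reference()
    distorted = distort_colors(reference.patch_rgb, distortion)
    ncol, nrow = 6, 4
    w = ncol * patch_size + (ncol + 1) * gap
    h = nrow * patch_size + (nrow + 1) * gap
    img = np.empty((h, w, 3), dtype=float)
    img[:] = 20.0  # chart border
    rois = []
    for i in range(24):
        r, c = divmod(i, ncol)
        x = gap + c * (patch_size + gap)
        y = gap + r * (patch_size + gap)
        img[y : y + patch_size, x : x + patch_size] = distorted[i]
        rois.append((x, y, patch_size, patch_size))
    if noise_sigma > 0:
        img += np.random.default_rng(seed).normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    obs = ChartObservation(distorted, reference, tuple(rois))
    return img, obs, rois


# --------------------------------------------------------------------------
# Frame sequences
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OlivePlacement:
    belt_coord_cm: float       # belt coordinate of the olive centre
    row_px: float              # transverse pixel row of the centre
    axes_px: tuple = (10.0, 12.0)   # (row, col) semi-axes
    cls: str = "Top Green"


def regular_placements(
    n: int,
    start_cm: float = 2.0,
    spacing_cm: float = 2.0,
    row_px: float = 100.0,
    classes=None,
) -> tuple:
    """Olives at a regular distance along the belt, as on the real conveyor."""
    classes = list(classes) if classes is not None else ["Top Green"] * n
    return tuple(
        OlivePlacement(start_cm + i * spacing_cm, row_px, cls=classes[i]) for i in range(n)
    )


@dataclass(frozen=True)
class SceneSpec:
    """A conveyor scene: belt kinematics, frame geometry and olive layout."""

    belt_speed_cm_s: float = 1.0
    frame_interval_s: float = 15.0
    frame_shape: tuple = (200, 400)     # (H, W) px
    px_to_cm: float = 0.05
    n_frames: int = 2
    placements: tuple = ()
    chart_origin: tuple | None = None   # (x, y) top-left, fixed in the image
    distortion: str = "identity"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.frame_shape) <= 0:
            raise ValueError("frame_shape must be positive")
        if self.px_to_cm <= 0:
            raise ValueError("px_to_cm must be positive")

    @property
    def fov_cm(self) -> float:
        return self.frame_shape[1] * self.px_to_cm

    @property
    def frame_shift_cm(self) -> float:
        return self.belt_speed_cm_s * self.frame_interval_s


def make_frames(spec: SceneSpec, model: ClassColorModel | None = None):
    """Render the frame sequence for a scene; returns ``(frames, truth)``.

    Frame k starts at belt coordinate ``k * speed * interval``; every olive
    whose ellipse overlaps a frame's field of view is rendered there (clipped
    at the frame edge), so olives in the overlap region appear twice.
    """
    model = model or default_class_model()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape
    frames, clean_frames = [], []
    visibility = {i: [] for i in range(len(spec.placements))}
    chart_rois = None
    chart_obs = None
    for k in range(spec.n_frames):
        pos = k * spec.frame_shift_cm
        canvas = np.empty((h, w, 3), dtype=float)
        canvas[:] = model.background_rgb
        for i, pl in enumerate(spec.placements):
            col = (pl.belt_coord_cm - pos) / spec.px_to_cm
            if col + pl.axes_px[1] < 0 or col - pl.axes_px[1] >= w:
                continue
            _render_ellipse(canvas, (pl.row_px, col), pl.axes_px, model.classes[pl.cls].mean_rgb)
            visibility[i].append(k)
        if spec.chart_origin is not None:
            chart_img, chart_obs, rois = make_distorted_chart(distortion="identity")
            x0, y0 = spec.chart_origin
            ch, cw = chart_img.shape[:2]
            if y0 + ch > h or x0 + cw > w:
                raise ValueError("chart does not fit inside the frame")
            canvas[y0 : y0 + ch, x0 : x0 + cw] = chart_img
            chart_rois = [(x0 + x, y0 + y, rw, rh) for (x, y, rw, rh) in rois]
        clean = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        distorted = distort_colors(canvas, spec.distortion)
        if spec.noise_sigma > 0:
            distorted = distorted + rng.normal(0.0, spec.noise_sigma, distorted.shape)
        img = np.clip(np.rint(distorted), 0, 255).astype(np.uint8)
        frames.append(
            FrameRecord(image=img, timestamp=k * spec.frame_interval_s, belt_position=pos, index=k)
        )
        clean_frames.append(clean)
    truth = {
        "placements": [
            {
                "belt_coord_cm": pl.belt_coord_cm,
                "row_px": pl.row_px,
                "axes_px": pl.axes_px,
                "class": pl.cls,
                "visible_frames": visibility[i],
            }
            for i, pl in enumerate(spec.placements)
        ],
        "frame_positions_cm": [k * spec.frame_shift_cm for k in range(spec.n_frames)],
        "frame_shift_cm": spec.frame_shift_cm,
        "background_rgb": model.background_rgb,
        "chart_rois": chart_rois,
        "clean_frames": clean_frames,
    }
    return frames, truth


# --------------------------------------------------------------------------
# Encoder waveforms
# --------------------------------------------------------------------------


def make_encoder_trace(
    revolutions: float,
    ticks_per_rev: int = 1024,
    direction: str = "forward",
) -> EncoderTrace:
    """Ideal 90-degree-phase-shifted square waves over a given rotation.

    The decoded x4 count is ``round(4 * ticks_per_rev * revolutions)`` with
    the sign of the direction.
    """
    if ticks_per_rev <= 0:
        raise ValueError("ticks_per_rev must be positive")
    if revolutions < 0:
        raise ValueError("revolutions must be non-negative")
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    steps = round(4 * ticks_per_rev * revolutions)
    sign = 1 if direction == "forward" else -1
    samples = [QUAD_CYCLE[(sign * i) % 4] for i in range(steps + 1)]
    if len(samples) == 1:
        samples.append(samples[0])  # an empty-motion trace still has samples
    return EncoderTrace(tuple(samples), ticks_per_rev=ticks_per_rev)
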