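"""Belt acquisition: quadrature encoder decoding, segmentation, tracking.

The belt position is measured by a two-channel rotary encoder (1024 ticks per
revolution).  x4 quadrature decoding counts every edge of either channel,
giving 4096 effective counts per revolution and the direction of rotation.
Frames taken every 15 s at 1 cm/s overlap along the belt, so one olive can
appear in consecutive frames; detections are merged into tracks by their belt
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "EncoderTrace",
    "BeltState",
    "FrameRecord",
    "OliveDetection",
    "OliveTrack",
    "QUAD_CYCLE",
    "quadrature_decode",
    "counts_to_displacement",
    "segment_olives",
    "deduplicate_tracks",
    "read_encoder_csv",
    "write_encoder_csv",
    "tracks_to_frame",
]

# Forward quadrature cycle of the (A, B) channel pair.  One step along this
# cycle is one quarter-tick (+1 count); one step against it is -1.
QUAD_CYCLE = ((0, 0), (0, 1), (1, 1), (1, 0))
_CYCLE_INDEX = {s: i for i, s in enumerate(QUAD_CYCLE)}


@dataclass(frozen=True)
class EncoderTrace:
    """Ordered logic samples of the encoder's A and B channels."""

    samples: tuple  # sequence of (A, B) in {0, 1}^2
    ticks_per_rev: int = 1024

    def __post_init__(self) -> None:
        if self.ticks_per_rev <= 0:
            raise ValueError("ticks_per_rev must be positive")
        if len(self.samples) == 0:
            raise ValueError("trace must contain at least one sample")
        object.__setattr__(self, "samples", tuple((int(a), int(b)) for a, b in self.samples))

    def reversed(self) -> "EncoderTrace":
        return EncoderTrace(self.samples[::-1], self.ticks_per_rev)


@dataclass(frozen=True)
class BeltState:
    """Accumulated quadrature counts, net direction and invalid transitions."""

    count: int
    direction: str  # forward | reverse | unknown
    invalid_transitions: int = 0


def quadrature_decode(trace: EncoderTrace) -> BeltState:
    """x4-decode an encoder trace.

    Every valid Gray-code transition of (A, B) moves the count by +/-1;
    a transition where both channels flip simultaneously is ambiguous and is
    tallied as invalid without moving the count.
    """
    states = np.fromiter(
        (_CYCLE_INDEX[s] for s in trace.samples), dtype=np.int64, count=len(trace.samples)
    )
    step = (states[1:] - states[:-1]) % 4
    count = int((step == 1).sum() - (step == 3).sum())
    invalid = int((step == 2).sum())
    direction = "forward" if count > 0 else "reverse" if count < 0 else "unknown"
    return BeltState(count=count, direction=direction, invalid_transitions=invalid)


def counts_to_displacement(
    count: int, ticks_per_rev: int, roller_circumference_cm: float
) -> float:
    """Convert quadrature counts to a signed belt displacement in cm."""
    if ticks_per_rev <= 0:
        raise ValueError("ticks_per_rev must be positive")
    if roller_circumference_cm <= 0:
        raise ValueError("roller circumference must be positive")
    return count / (4.0 * ticks_per_rev) * roller_circumference_cm


@dataclass(frozen=True)
class FrameRecord:
    """One camera frame with its belt coordinate.

    ``belt_position`` is the belt coordinate (cm) of the frame's leading edge
    (image column 0); in a forward run it is non-decreasing over frames.
    """

    image: np.ndarray
    timestamp: float
    belt_position: float
    index: int = 0


@dataclass(frozen=True)
class OliveDetection:
    """A single segmented blob in one frame."""

    frame_index: int
    bbox: tuple[int, int, int, int]     # (x, y, w, h) in pixels
    centroid_px: tuple[float, float]    # (row, col)
    belt_coord: float                   # cm along the belt
    area_px: int
    crop: np.ndarray
    border_distance: int = 0            # min pixel distance of bbox to frame borders


@dataclass(frozen=True)
class OliveTrack:
    """Detections of one physical olive merged across overlapping frames."""

    track_id: int
    detections: tuple
    representative_crop: np.ndarray

    @property
    def belt_coord(self) -> float:
        return float(np.mean([d.belt_coord for d in self.detections]))


def segment_olives(
    frame: FrameRecord,
    background_rgb,
    tolerance: float = 40.0,
    min_area_px: int = 50,
    px_to_cm: float = 0.05,
    crop_margin: int = 4,
) -> list[OliveDetection]:
    """Segment foreground blobs against a background colour model.

    Pixels whose Euclidean RGB distance from ``background_rgb`` exceeds
    ``tolerance`` form the foreground mask; 8-connected components of at least
    ``min_area_px`` pixels become detections.  The belt coordinate of a
    detection is the frame's belt position plus its centroid column scaled by
    ``px_to_cm``.  Crops are tight bounding boxes padded by ``crop_margin``
    and clipped to the frame.
    """
    img = np.asarray(frame.image, dtype=float)
    bg = np.asarray(background_rgb, dtype=float)
    mask = np.linalg.norm(img - bg[None, None, :], axis=2) > tolerance
    labels = measure.label(mask, connectivity=2)
    h, w = mask.shape
    detections = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        x0 = max(0, c0 - crop_margin)
        y0 = max(0, r0 - crop_margin)
        x1 = min(w, c1 + crop_margin)
        y1 = min(h, r1 + crop_margin)
        crop = np.asarray(frame.image)[y0:y1, x0:x1].copy()
        row, col = region.centroid
        detections.append(
            OliveDetection(
                frame_index=frame.index,
                bbox=(c0, r0, c1 - c0, r1 - r0),
                centroid_px=(float(row), float(col)),
                belt_coord=frame.belt_position + float(col) * px_to_cm,
                area_px=int(region.area),
                crop=crop,
                border_distance=int(min(c0, r0, w - c1, h - r1)),
            )
        )
    detections.sort(key=lambda d: d.belt_coord)
    return detections


def deduplicate_tracks(
    detections,
    match_tolerance_cm: float = 1.0,
    row_tolerance_px: float = 12.0,
) -> list[OliveTrack]:
    """Merge detections of the same olive seen in overlapping frames.

    Detections whose belt coordinates agree within ``match_tolerance_cm`` and
    whose transverse pixel rows agree within ``row_tolerance_px`` are one
    physical olive.  The representative crop comes from the frame where the
    bounding box sits farthest from the image borders (earliest frame on
    ties), so truncated edge views are avoided.
    """
    remaining = sorted(detections, key=lambda d: (d.belt_coord, d.frame_index))
    groups: list[list[OliveDetection]] = []
    for det in remaining:
        placed = False
        for group in groups:
            ref = group[0]
            if (
                abs(det.belt_coord - ref.belt_coord) <= match_tolerance_cm
                and abs(det.centroid_px[0] - ref.centroid_px[0]) <= row_tolerance_px
                and all(det.frame_index != g.frame_index for g in group)
            ):
                group.append(det)
                placed = True
                break
        if not placed:
            groups.append([det])
    tracks = []
    for tid, group in enumerate(groups):
        best = max(group, key=lambda d: (d.border_distance, -d.frame_index))
        tracks.append(
            OliveTrack(track_id=tid, detections=tuple(group), representative_crop=best.crop)
        )
    return tracks


def read_encoder_csv(path, ticks_per_rev: int = 1024) -> EncoderTrace:
    """Read a two-column (A, B) logic trace CSV."""
    df = pd.read_csv(path)
    return EncoderTrace(
        tuple(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(int))),
        ticks_per_rev=ticks_per_rev,
    )


def write_encoder_csv(trace: EncoderTrace, path) -> None:
    pd.DataFrame(trace.samples, columns=["A", "B"]).to_csv(path, index=False)


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Flatten tracks into the CSV export layout (one row per detection)."""
    rows = []
    for t in tracks:
        for d in t.detections:
            x, y, w, h = d.bbox
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": d.frame_index,
                    "x": x,
                    "y": y,
                    "w": w,
                    "h": h,
                    "belt_cm": round(d.belt_coord, 4),
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "w", "h", "belt_cm"])
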