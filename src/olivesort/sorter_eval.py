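"""Scoring an optoelectronic sorter's output streams against the classifier.

Each physical output stream of the sorter (e.g. "Black slow" = olives ejected
as black at the slow vibrator speed) is re-imaged on the conveyor belt and
classified into the five quality classes.  The cross-tabulation of streams
(rows) against classes (columns) yields composition percentages, stream
purity (the share of a stream matching its nominal colour group) and
oil-blend fractions (the share of all olives falling in a chosen class
subset).

Percentages are reported at the granularity the field uses: composition to
one decimal, purity and blend fractions to the nearest integer percent, both
with round-half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ORDER",
    "DEFAULT_COLOR_GROUPS",
    "StreamCrossTab",
    "ColorGroupMap",
    "BlendSpec",
    "crosstab",
    "column_percentages",
    "stream_purity",
    "blend_fraction",
    "evaluation_report",
    "lot_totals",
    "read_crosstab_csv",
    "write_crosstab_csv",
]

# Column order of the stream-by-class table (the conveyor classes).
CLASS_ORDER = ("Bad Black", "Bad Green", "Good Black", "Good Green", "Top Green")

DEFAULT_COLOR_GROUPS = {
    "Bad Black": "black",
    "Good Black": "black",
    "Bad Green": "green",
    "Good Green": "green",
    "Top Green": "green",
}


def _round_half_away(x: float, ndigits: int = 0) -> float:
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class ColorGroupMap:
    """Total, disjoint mapping of the 5 classes onto {black, green}."""

    groups: dict = field(default_factory=lambda: dict(DEFAULT_COLOR_GROUPS))

    def __post_init__(self) -> None:
        if set(self.groups) != set(CLASS_ORDER):
            raise ValueError("colour-group map must cover exactly the 5 classes")
        if not set(self.groups.values()) <= {"black", "green"}:
            raise ValueError("groups must be 'black' or 'green'")

    def __getitem__(self, cls: str) -> str:
        return self.groups[cls]


@dataclass(frozen=True)
class BlendSpec:
    """An oil-blend scenario: the subset of classes sent to the press."""

    name: str
    included_classes: tuple

    def __post_init__(self) -> None:
        if not self.included_classes:
            raise ValueError("blend must include at least one class")
        unknown = set(self.included_classes) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes in blend: {sorted(unknown)}")


@dataclass(frozen=True)
class StreamCrossTab:
    """Counts of sorter output streams (rows) by conveyor classes (columns)."""

    rows: tuple            # stream ids, e.g. ("Black slow", "Green slow", ...)
    cols: tuple            # class names
    counts: np.ndarray     # (n_streams, n_classes) non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape must be n_streams x n_classes")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "cols", tuple(self.cols))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row(self, stream_id: str) -> np.ndarray:
        if stream_id not in self.rows:
            raise KeyError(f"unknown stream {stream_id!r}")
        return self.counts[self.rows.index(stream_id)]


def crosstab(stream_predictions: dict, class_order=CLASS_ORDER) -> StreamCrossTab:
    """Tabulate per-stream predicted-label lists into a StreamCrossTab."""
    index = {c: i for i, c in enumerate(class_order)}
    rows = tuple(stream_predictions)
    counts = np.zeros((len(rows), len(class_order)), dtype=int)
    for r, stream in enumerate(rows):
        for label in stream_predictions[stream]:
            if label not in index:
                raise ValueError(f"unknown class {label!r} in stream {stream!r}")
            counts[r, index[label]] += 1
    return StreamCrossTab(rows, tuple(class_order), counts)


def column_percentages(ct: StreamCrossTab) -> tuple:
    """Class composition of all sorted olives, percent to one decimal."""
    if ct.grand_total == 0:
        raise ValueError("cross-tab is empty")
    return tuple(
        _round_half_away(t / ct.grand_total * 100.0, 1) for t in ct.col_totals
    )


def _stream_color(stream_id: str) -> str:
    head = stream_id.split()[0].split("-")[0].lower()
    if head not in ("black", "green"):
        raise ValueError(
            f"cannot infer nominal colour of stream {stream_id!r}; "
            "expected an id starting with Black or Green"
        )
    return head


def stream_purity(
    ct: StreamCrossTab,
    groups: ColorGroupMap | None = None,
    stream_id: str = "",
    nominal_color: str | None = None,
) -> int:
    """Share of a stream falling in its nominal colour group, integer percent.

    The nominal colour defaults to the stream id's leading word
    (``"Black slow"`` -> black) and can be overridden via ``nominal_color``.
    """
    groups = groups or ColorGroupMap()
    row = ct.row(stream_id)
    color = nominal_color or _stream_color(stream_id)
    total = row.sum()
    if total == 0:
        raise ValueError(f"stream {stream_id!r} is empty")
    matched = sum(
        int(row[i]) for i, cls in enumerate(ct.cols) if groups[cls] == color
    )
    return int(_round_half_away(matched / total * 100.0))


def blend_fraction(ct: StreamCrossTab, spec: BlendSpec) -> int:
    """Share of all olives in the blend's class subset, integer percent."""
    if ct.grand_total == 0:
        raise ValueError("cross-tab is empty")
    included = sum(
        int(t)
        for cls, t in zip(ct.cols, ct.col_totals)
        if cls in spec.included_classes
    )
    return int(_round_half_away(included / ct.grand_total * 100.0))


STANDARD_BLENDS = (
    BlendSpec("superior EVOO", ("Top Green",)),
    BlendSpec("high quality green", ("Top Green", "Good Green")),
    BlendSpec("high quality", ("Top Green", "Good Green", "Good Black")),
)


def evaluation_report(
    ct: StreamCrossTab,
    groups: ColorGroupMap | None = None,
    blends=STANDARD_BLENDS,
    stated_row_totals: dict | None = None,
) -> dict:
    """Full stream evaluation: percentages, purities, blends, marginal checks.

    ``stated_row_totals`` are the totals printed alongside an ingested table;
    any disagreement with the recomputed marginals is flagged, not fatal.
    """
    groups = groups or ColorGroupMap()
    flags = {}
    if stated_row_totals:
        for stream, stated in stated_row_totals.items():
            actual = int(ct.row(stream).sum())
            if actual != int(stated):
                flags[stream] = {"stated": int(stated), "computed": actual}
    return {
        "class_order": list(ct.cols),
        "streams": list(ct.rows),
        "counts": ct.counts.tolist(),
        "grand_total": ct.grand_total,
        "column_percentages": list(column_percentages(ct)),
        "stream_purity_percent": {
            s: stream_purity(ct, groups, s) for s in ct.rows if ct.row(s).sum() > 0
        },
        "blend_fraction_percent": {b.name: blend_fraction(ct, b) for b in blends},
        "marginal_mismatches": flags,
    }


def lot_totals(weights_kg: dict) -> dict:
    """Sum per-colour lot weights into a total per sorting speed.

    ``weights_kg`` maps speed -> {colour group -> kg}.
    """
    return {speed: float(sum(groups.values())) for speed, groups in weights_kg.items()}


def read_crosstab_csv(path):
    """Read a table-layout CSV: header of classes, one row per stream,
    trailing Total column.  Returns ``(StreamCrossTab, stated_row_totals)``."""
    df = pd.read_csv(path, index_col=0)
    has_total = df.columns[-1].strip().lower() == "total"
    classes = tuple(c.strip() for c in (df.columns[:-1] if has_total else df.columns))
    counts = df.iloc[:, : len(classes)].to_numpy(dtype=int)
    stated = (
        {str(r): int(t) for r, t in zip(df.index, df.iloc[:, -1])} if has_total else None
    )
    return StreamCrossTab(tuple(str(r) for r in df.index), classes, counts), stated


def write_crosstab_csv(ct: StreamCrossTab, path) -> None:
    df = pd.DataFrame(ct.counts, index=list(ct.rows), columns=list(ct.cols))
    df["Total"] = ct.row_totals
    df.to_csv(path)
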