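"""Thin-plate-spline (TPS) colour calibration against a 24-patch reference chart.

A ColorChecker-style chart with published sRGB patch values is imaged in-frame.
The measured patch colours are treated as control points of a vector-valued
thin-plate spline over RGB space; fitting the spline warps measured colours
onto their reference coordinates, and applying it to a whole frame corrects
every pixel.

The map for each output channel is

    f(x) = a0 + a . x + sum_i w_i * phi(|x - c_i|)

with the standard TPS side conditions (kernel weights sum to zero and are
orthogonal to the control-point coordinates).  Two radial kernels are offered:
``r3d`` (phi(r) = r, the biharmonic fundamental solution in three dimensions,
the default for the 3-D RGB domain) and ``r2logr`` (phi(r) = r^2 log r, the
classical 2-D TPS kernel, for fidelity to 2-D-derived code).  With
regularization lambda = 0 the spline interpolates the control points exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import yaml

__all__ = [
    "COLORCHECKER_CLASSIC_SRGB",
    "PATCH_NAMES",
    "ChartReference",
    "ChartObservation",
    "TPSColorMap",
    "CalibrationReport",
    "DegenerateGeometryError",
    "classic_reference",
    "extract_patch_colors",
    "fit_tps",
    "apply_tps",
    "calibration_report",
    "load_chart_rois",
]

# Classic (pre-2014) ColorChecker sRGB values, row-major chart layout:
# patch 1 = dark skin, patch 24 = black.
COLORCHECKER_CLASSIC_SRGB = np.array(
    [
        [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
        [133, 128, 177], [103, 189, 170], [214, 126, 44], [80, 91, 166],
        [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
        [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
        [187, 86, 149], [8, 133, 161], [243, 243, 242], [200, 200, 200],
        [160, 160, 160], [122, 122, 121], [85, 85, 85], [52, 52, 52],
    ],
    dtype=float,
)

PATCH_NAMES = (
    "dark skin", "light skin", "blue sky", "foliage", "blue flower",
    "bluish green", "orange", "purplish blue", "moderate red", "purple",
    "yellow green", "orange yellow", "blue", "green", "red", "yellow",
    "magenta", "cyan", "white", "neutral 8", "neutral 6.5", "neutral 5",
    "neutral 3.5", "black",
)


class DegenerateGeometryError(ValueError):
    """Control-point geometry does not support an exact TPS fit."""


@dataclass(frozen=True)
class ChartReference:
    """Published sRGB coordinates of the 24 chart patches, in chart order."""

    patch_rgb: np.ndarray  # (24, 3) float, components in [0, 255]
    edition_tag: str = "classic"

    def __post_init__(self) -> None:
        rgb = np.asarray(self.patch_rgb, dtype=float)
        if rgb.shape != (24, 3):
            raise ValueError(f"expected 24 RGB patches, got shape {rgb.shape}")
        if rgb.min() < 0 or rgb.max() > 255:
            raise ValueError("patch components must lie in [0, 255]")
        object.__setattr__(self, "patch_rgb", rgb)


def classic_reference() -> ChartReference:
    """The default pre-2014 ColorChecker sRGB value set."""
    return ChartReference(COLORCHECKER_CLASSIC_SRGB.copy(), edition_tag="classic")


@dataclass(frozen=True)
class ChartObservation:
    """Measured patch colours paired with their reference values.

    ``measured_rgb`` holds the per-patch mean colour over each ROI;
    ``patch_rois`` the ``(x, y, w, h)`` pixel rectangles the means were taken
    from (``None`` when the observation comes from a generator truth record).
    """

    measured_rgb: np.ndarray  # (24, 3) float
    reference: ChartReference
    patch_rois: tuple | None = None

    def __post_init__(self) -> None:
        rgb = np.asarray(self.measured_rgb, dtype=float)
        if rgb.shape != self.reference.patch_rgb.shape:
            raise ValueError("measured_rgb must match reference patch count")
        object.__setattr__(self, "measured_rgb", rgb)


def extract_patch_colors(
    image: np.ndarray,
    patch_rois: list[tuple[int, int, int, int]],
    reference: ChartReference | None = None,
) -> ChartObservation:
    """Average each patch ROI of an image into a ChartObservation.

    ROIs are ``(x, y, w, h)`` rectangles, 0-based, half-open, in chart order.
    """
    if reference is None:
        reference = classic_reference()
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    h, w = img.shape[:2]
    if len(patch_rois) != len(reference.patch_rgb):
        raise ValueError("need one ROI per reference patch")
    means = np.empty((len(patch_rois), 3), dtype=float)
    for i, (x, y, rw, rh) in enumerate(patch_rois):
        if rw <= 0 or rh <= 0:
            raise ValueError(f"patch {i + 1}: empty ROI {rw}x{rh}")
        if x < 0 or y < 0 or x + rw > w or y + rh > h:
            raise IndexError(
                f"patch {i + 1}: ROI ({x},{y},{rw},{rh}) outside {w}x{h} image"
            )
        means[i] = img[y : y + rh, x : x + rw].reshape(-1, 3).mean(axis=0)
    return ChartObservation(means, reference, tuple(map(tuple, patch_rois)))


def _kernel(r: np.ndarray, kernel_id: str) -> np.ndarray:
    if kernel_id == "r3d":
        return r
    if kernel_id == "r2logr":
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out
    raise ValueError(f"unknown kernel_id {kernel_id!r} (use 'r3d' or 'r2logr')")


@dataclass(frozen=True)
class TPSColorMap:
    """Fitted vector-valued TPS transform of RGB space.

    ``affine`` has one row per output channel: ``[constant, cR, cG, cB]``.
    ``kernel_weights`` has one column per output channel.
    """

    control_points: np.ndarray  # (n, 3) source colours
    affine: np.ndarray          # (3, 4)
    kernel_weights: np.ndarray  # (n, 3)
    kernel_id: str = "r3d"
    regularization: float = 0.0

    def __call__(self, colors: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of RGB colours (unclipped, float)."""
        x = np.asarray(colors, dtype=float)
        flat = x.reshape(-1, 3)
        d = np.linalg.norm(flat[:, None, :] - self.control_points[None, :, :], axis=2)
        out = (
            self.affine[:, 0][None, :]
            + flat @ self.affine[:, 1:].T
            + _kernel(d, self.kernel_id) @ self.kernel_weights
        )
        return out.reshape(x.shape)


def fit_tps(
    obs: ChartObservation,
    kernel_id: str = "r3d",
    regularization: float = 0.0,
) -> TPSColorMap:
    """Fit the TPS colour map sending measured patch colours to reference ones.

    Solves the standard TPS linear system (kernel block plus affine block with
    side conditions) once, with shared geometry across the three output
    channels.  With ``regularization == 0`` the map interpolates exactly.
    """
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    src = np.asarray(obs.measured_rgb, dtype=float)
    dst = np.asarray(obs.reference.patch_rgb, dtype=float)
    n = src.shape[0]
    if n < 5:
        raise DegenerateGeometryError("need at least 5 control points in RGB space")

    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    if regularization == 0.0:
        iu, ju = np.triu_indices(n, k=1)
        dup = d[iu, ju] < 1e-9
        if dup.any():
            pairs = [f"{iu[k] + 1}&{ju[k] + 1}" for k in np.flatnonzero(dup)]
            raise DegenerateGeometryError(
                "coincident measured control points (patches "
                + ", ".join(pairs)
                + "); use regularization > 0"
            )
        sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
        if sv[2] < 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError(
                "measured control points are coplanar in RGB space; "
                "the affine block is singular with regularization 0"
            )

    K = _kernel(d, kernel_id) + regularization * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])  # (n, 4)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    try:
        sol = scipy.linalg.solve(A, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateGeometryError(f"singular TPS system: {exc}") from exc
    w = sol[:n]           # (n, 3)
    a = sol[n:]           # (4, 3), rows: constant, R, G, B coefficient
    return TPSColorMap(
        control_points=src,
        affine=a.T.copy(),
        kernel_weights=w,
        kernel_id=kernel_id,
        regularization=float(regularization),
    )


def apply_tps(
    tps: TPSColorMap,
    image: np.ndarray,
    chunk: int = 1 << 16,
    return_clip_fraction: bool = False,
):
    """Correct a whole H x W x 3 image through the colour map.

    Output is clipped to [0, 255] and returned as uint8.  With
    ``return_clip_fraction`` the fraction of pixels with at least one clipped
    channel is returned as well.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    flat = img.reshape(-1, 3)
    out = np.empty_like(flat)
    clipped = 0
    for start in range(0, flat.shape[0], chunk):
        block = tps(flat[start : start + chunk])
        if return_clip_fraction:
            clipped += int(np.any((block < 0) | (block > 255), axis=1).sum())
        out[start : start + chunk] = np.clip(block, 0.0, 255.0)
    corrected = np.rint(out).astype(np.uint8).reshape(img.shape)
    if return_clip_fraction:
        return corrected, clipped / flat.shape[0]
    return corrected


@dataclass(frozen=True)
class CalibrationReport:
    """Control-point residuals of a fitted map, plus clipping statistics."""

    per_patch_residual: np.ndarray  # (n,) Euclidean distance in RGB units
    rmse: float
    clipped_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "per_patch_residual": [float(r) for r in self.per_patch_residual],
            "rmse": float(self.rmse),
            "clipped_fraction": self.clipped_fraction,
        }


def calibration_report(
    tps: TPSColorMap,
    obs: ChartObservation,
    image: np.ndarray | None = None,
) -> CalibrationReport:
    """Evaluate the fitted map at its control points.

    When ``image`` is given, it is corrected as well and the fraction of
    clipped pixels reported.
    """
    if tps.control_points.shape[0] != obs.measured_rgb.shape[0]:
        raise ValueError("map and observation have different control-point counts")
    mapped = tps(obs.measured_rgb)
    resid = np.linalg.norm(mapped - obs.reference.patch_rgb, axis=1)
    clipped = None
    if image is not None:
        _, clipped = apply_tps(tps, image, return_clip_fraction=True)
    return CalibrationReport(
        per_patch_residual=resid,
        rmse=float(np.sqrt(np.mean(resid**2))),
        clipped_fraction=clipped,
    )


def load_chart_rois(path) -> list[tuple[int, int, int, int]]:
    """Read a chart-ROI YAML file: a list of 24 ``[x, y, w, h]`` rectangles."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    rois = [tuple(int(v) for v in rect) for rect in data]
    if len(rois) != 24 or any(len(r) != 4 for r in rois):
        raise ValueError("chart ROI file must list 24 [x, y, w, h] rectangles")
    return rois
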