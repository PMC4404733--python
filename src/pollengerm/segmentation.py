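"""ImageJ-style measurement chain for pollen tube time-lapse stacks.

Mirrors the classical workflow: z-projection, stack-histogram thresholding
(one gray value per tube, pooled over all of its frames), binarization,
subtraction of the (frozen) pollen-grain area, extraction of the tube region,
and shape descriptors. The shape threshold selects the brightest 70% and the
peak threshold the brightest 0.5% of above-background pixels; the background
floor is set by Otsu's method on the pooled histogram.

All reported lengths and areas are converted to micrometers via the pixel
size. Coordinates are pixel-centered, 0-based, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_opening
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

__all__ = [
    "StackThresholds",
    "RegionMeasurement",
    "project",
    "stack_threshold",
    "compute_thresholds",
    "binarize_and_extract",
    "extract_grain_mask",
    "measure_region",
]


@dataclass(frozen=True)
class StackThresholds:
    """Gray values derived from one tube's pooled stack histogram."""

    shape_gray: float  # brightest `shape_fraction` of signal pixels
    peak_gray: float  # brightest `peak_fraction` of signal pixels
    background_floor: float
    shape_fraction: float = 0.70
    peak_fraction: float = 0.005

    def __post_init__(self) -> None:
        if not (0 < self.peak_fraction < self.shape_fraction <= 1):
            raise ValueError("require 0 < peak_fraction < shape_fraction <= 1")
        if self.peak_gray < self.shape_gray:
            raise ValueError("peak gray value must be >= shape gray value")


@dataclass
class RegionMeasurement:
    """Shape descriptors of one frame's tube region.

    ``roundness`` is 4*area/(pi*major_axis^2) with the major axis taken from
    the moments-equivalent (best-fit) ellipse; it is NaN (missing) for an
    empty mask, never 0.
    """

    frame_index: int = -1
    area: float = 0.0  # um^2
    major_axis: float = 0.0  # um
    roundness: float = float("nan")
    junction_width: float = float("nan")  # um
    tube_length: float = 0.0  # um
    centroid: tuple[float, float] = (float("nan"), float("nan"))  # (row, col) px


def project(stack: np.ndarray, mode: str = "max") -> np.ndarray:
    """Project a (T, Z, Y, X) stack across Z. ``mode`` is 'max' or 'sum'."""
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError(f"expected a T,Z,Y,X stack, got shape {stack.shape}")
    if mode == "max":
        return stack.max(axis=1)
    if mode == "sum":
        return stack.sum(axis=1, dtype=np.float64)
    raise ValueError(f"unknown projection mode {mode!r}")


def stack_threshold(images: np.ndarray, fraction: float) -> float:
    """Gray value selecting the brightest ``fraction`` of signal pixels.

    All frames of one tube are pooled into a single histogram. Pixels at or
    below a global Otsu floor count as background; among the remaining signal
    pixels the returned value g is the smallest gray value such that the
    proportion with intensity > g is at most ``fraction``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    values = np.asarray(images).ravel()
    if values.size == 0 or not np.any(values > 0):
        raise ValueError("all-zero stack: cannot compute a signal threshold")
    floor = _background_floor(values)
    signal = values[values > floor]
    if signal.size == 0:
        signal = values[values > 0]
        floor = 0.0
    if fraction >= 1.0:
        return float(floor)
    g = float(np.quantile(signal, 1.0 - fraction, method="higher"))
    return max(g, float(floor))


def _background_floor(values: np.ndarray) -> float:
    """Gray value separating camera background from fluorescence signal.

    Otsu's split is computed in the log domain: fluorescence histograms span
    orders of magnitude, and compressing the bright tail keeps a small
    population of very bright pixels (intensity peaks, tip accumulation)
    from dragging the background/signal boundary away from the dim
    cytoplasmic baseline.
    """
    if np.ptp(values) == 0:
        return float(values.flat[0]) - 1.0
    try:
        t = threshold_otsu(
            np.log1p(np.maximum(np.asarray(values, dtype=np.float64), 0.0))
        )
        return float(np.expm1(t))
    except ValueError:
        return 0.0


def compute_thresholds(
    images: np.ndarray, shape_fraction: float = 0.70, peak_fraction: float = 0.005
) -> StackThresholds:
    """Shape (70%) and peak (0.5%) gray values from one tube's pooled stack."""
    values = np.asarray(images).ravel()
    if values.size == 0 or not np.any(values > 0):
        raise ValueError("all-zero stack: cannot compute thresholds")
    floor = _background_floor(values)
    return StackThresholds(
        shape_gray=stack_threshold(images, shape_fraction),
        peak_gray=stack_threshold(images, peak_fraction),
        background_floor=floor,
        shape_fraction=shape_fraction,
        peak_fraction=peak_fraction,
    )


def extract_grain_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Pollen-grain mask: largest connected component of the binary image.

    Taken from a frame at or before germination and then frozen, so it can be
    subtracted from all frames of the tube.
    """
    binary = np.asarray(image) > threshold
    labels = cc_label(binary)
    if labels.max() == 0:
        return np.zeros_like(binary)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def binarize_and_extract(
    image: np.ndarray, threshold: float, grain_mask: np.ndarray, despeckle: bool = True
) -> np.ndarray:
    """Threshold a frame, subtract the grain, and keep the tube component.

    The tube is the largest connected component of the grain-subtracted
    binary image that touches the (1-px dilated) grain boundary; detached
    debris is discarded and, with ``despeckle``, single-pixel noise chains
    are removed by a 3x3 morphological opening (replacing the manual
    curation of an interactive workflow). Returns an empty mask if nothing
    touches the grain.
    """
    binary = np.asarray(image) > threshold
    binary &= ~grain_mask
    if despeckle:
        binary = binary_opening(binary, np.ones((3, 3), dtype=bool))
    labels = cc_label(binary)
    if labels.max() == 0:
        return np.zeros_like(binary)
    border = binary_dilation(grain_mask) & ~grain_mask
    touching = np.unique(labels[border & (labels > 0)])
    if touching.size == 0:
        return np.zeros_like(binary)
    counts = np.bincount(labels.ravel())
    best = touching[np.argmax(counts[touching])]
    return labels == best


def _junction_width(mask: np.ndarray, grain_mask: np.ndarray, pixel_size: float) -> float:
    """Width of the tube/grain interface: maximal extent of the tube pixels
    lying in the 1-px band just outside the grain."""
    band = binary_dilation(grain_mask) & ~grain_mask
    pts = np.argwhere(mask & band)
    if len(pts) == 0:
        return 0.0
    if len(pts) == 1:
        return pixel_size
    if len(pts) > 4000:  # cap the pairwise computation
        pts = pts[:: len(pts) // 4000 + 1]
    return float(pdist(pts.astype(float)).max() + 1.0) * pixel_size


def _skeleton_length(mask: np.ndarray, pixel_size: float) -> float:
    """Geodesic length of the longest path through the morphological skeleton."""
    skel = skeletonize(mask)
    pts = np.argwhere(skel)
    n = len(pts)
    if n == 0:
        return 0.0
    if n == 1:
        return pixel_size
    index = -np.ones(skel.shape, dtype=np.int64)
    index[tuple(pts.T)] = np.arange(n)
    rows_i, rows_j, weights = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        w = pixel_size * float(np.hypot(dr, dc))
        src = pts
        dst = pts + (dr, dc)
        ok = (
            (dst[:, 0] >= 0)
            & (dst[:, 0] < skel.shape[0])
            & (dst[:, 1] >= 0)
            & (dst[:, 1] < skel.shape[1])
        )
        j = np.full(n, -1, dtype=np.int64)
        j[ok] = index[tuple(dst[ok].T)]
        valid = j >= 0
        rows_i.append(np.arange(n)[valid])
        rows_j.append(j[valid])
        weights.append(np.full(valid.sum(), w))
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(weights)
    graph = coo_matrix((w, (i, j)), shape=(n, n))
    # tree-diameter style double sweep: farthest node from node 0, then from it
    d0 = dijkstra(graph, directed=False, indices=0)
    d0[~np.isfinite(d0)] = -1
    far = int(np.argmax(d0))
    d1 = dijkstra(graph, directed=False, indices=far)
    d1[~np.isfinite(d1)] = -1
    return float(d1.max()) + pixel_size


def measure_region(
    mask: np.ndarray,
    pixel_size: float,
    grain_mask: np.ndarray | None = None,
    frame_index: int = -1,
    tube_length: bool = True,
) -> RegionMeasurement:
    """Shape descriptors of a binary tube mask.

    Area is pixel count times ``pixel_size**2``; the major axis comes from the
    moments-equivalent ellipse (same normalized second central moments as the
    mask); roundness is 4*area/(pi*major^2); junction width is the extent of
    the mask within a 1-px dilation of the grain boundary (requires
    ``grain_mask``); tube length is the geodesic length of the morphological
    skeleton (skipped when ``tube_length`` is False to save time).

    An empty mask yields an all-zero measurement with roundness reported as
    NaN (missing), never 0.
    """
    mask = np.asarray(mask).astype(bool)
    n_px = int(mask.sum())
    if n_px == 0:
        return RegionMeasurement(frame_index=frame_index)
    props = regionprops(mask.astype(np.uint8))[0]
    area = n_px * pixel_size**2
    major_px = float(props.axis_major_length)
    major = major_px * pixel_size
    roundness = float(4.0 * area / (np.pi * major**2)) if major > 0 else float("nan")
    roundness = min(roundness, 1.0) if np.isfinite(roundness) else roundness
    junction = (
        _junction_width(mask, grain_mask, pixel_size)
        if grain_mask is not None
        else float("nan")
    )
    length = _skeleton_length(mask, pixel_size) if tube_length else 0.0
    return RegionMeasurement(
        frame_index=frame_index,
        area=area,
        major_axis=major,
        roundness=roundness,
        junction_width=junction,
        tube_length=length,
        centroid=tuple(float(c) for c in props.centroid),
    )
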