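"""Histogram-based multilevel thresholding with PSNR model selection.

An 8-bit channel is segmented by ``n`` intensity thresholds computed
iteratively from its histogram: starting from the occupied intensity range,
each interval (processed in order of pixel mass) emits sub-thresholds at
``μ ± w·σ`` of its occupancy-weighted intensity distribution and recursion
continues on the outer sub-intervals until ``n`` thresholds exist.  The
piecewise-constant reconstruction assigns every pixel its segment's mean
intensity — the RMSE-minimizing representative for fixed thresholds — and is
scored by PSNR = 20·log10(255/RMSE).  The optimal ``n`` is the smallest one
whose PSNR gain over ``n − 1`` drops below ``epsilon_db`` (elbow rule);
7–12 thresholds are typical for multichannel fluorescence material.

Cell extraction takes the union over channels of pixels above each
channel's lowest threshold as foreground, labels connected components, and
reports per cell the (unweighted) centroid and the mean intensity per
channel over the cell's FWHM core — the pixels at or above half of the
cell's maximum across channels.  Measuring over the half-max core makes the
measured/nominal intensity ratio independent of cell brightness, so the
quantizer downstream sees undistorted level spacing.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "DegenerateHistogramError",
    "Histogram",
    "ThresholdSet",
    "SegmentedImage",
    "ThresholdSearch",
    "DetectionConfig",
    "compute_histogram",
    "select_thresholds",
    "reconstruct",
    "psnr",
    "choose_optimal_n",
    "detect_cells",
    "INFINITE_PSNR",
]

#: Sentinel for the PSNR of a lossless reconstruction; compares above every
#: finite PSNR value.
INFINITE_PSNR = math.inf


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied intensity values."""


@dataclass(frozen=True)
class Histogram:
    """Exact value counts of an 8-bit channel."""

    counts: np.ndarray  # length 256
    n_pixels: int

    def __post_init__(self) -> None:
        if len(self.counts) != 256:
            raise ValueError("histogram must cover 256 intensity values")
        if int(self.counts.sum()) != self.n_pixels:
            raise ValueError("histogram counts do not sum to the pixel count")


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered intensity thresholds for one channel plus reconstruction PSNR."""

    n: int
    thresholds: tuple[int, ...]
    psnr_db: float | None = None

    def __post_init__(self) -> None:
        if self.n != len(self.thresholds):
            raise ValueError("n must equal len(thresholds)")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.thresholds and not (
            0 < self.thresholds[0] and self.thresholds[-1] < 255
        ):
            raise ValueError("thresholds must lie in (0, 255)")


@dataclass(frozen=True)
class SegmentedImage:
    """Per-pixel segment indices with per-segment representative intensities."""

    labels: np.ndarray  # int segment index in {0..n}
    representatives: np.ndarray  # length n+1, segment mean intensities
    thresholds: tuple[int, ...]

    @property
    def reconstruction(self) -> np.ndarray:
        """Piecewise-constant image: every pixel at its segment mean."""
        return self.representatives[self.labels]


def compute_histogram(channel_image: np.ndarray) -> Histogram:
    img = np.asarray(channel_image)
    if img.dtype != np.uint8:
        raise TypeError(f"expected an 8-bit (uint8) channel, got {img.dtype}")
    counts = np.bincount(img.ravel(), minlength=256)
    return Histogram(counts=counts, n_pixels=int(img.size))


def _interval_stats(counts: np.ndarray, lo: int, hi: int) -> tuple[float, float, int]:
    vals = np.arange(lo, hi + 1)
    c = counts[lo : hi + 1]
    tot = int(c.sum())
    mu = float((vals * c).sum() / tot)
    sd = float(np.sqrt(((vals - mu) ** 2 * c).sum() / tot))
    return mu, sd, tot


def select_thresholds(hist: Histogram, n: int, w: float = 1.0) -> ThresholdSet:
    """Compute up to ``n`` thresholds by iterative histogram subdivision.

    Intervals are processed in decreasing order of pixel mass; each emits
    thresholds at ``μ − w·σ`` and ``μ + w·σ`` (just ``μ`` when ``w == 0``),
    clipped inside the interval, and the outer sub-intervals re-enter the
    worklist.  A candidate colliding with an existing threshold is shifted up
    by one intensity unit.  Deterministic for fixed inputs; returns fewer
    than ``n`` thresholds only when the histogram cannot support more.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if w < 0:
        raise ValueError("w must be >= 0")
    counts = hist.counts
    occ = np.flatnonzero(counts)
    if occ.size < 2:
        raise DegenerateHistogramError(
            "histogram with < 2 occupied values cannot be thresholded"
        )
    thresholds: set[int] = set()
    lo0, hi0 = int(occ[0]), int(occ[-1])
    # heap entries: (-pixel mass, lo, hi); lo breaks ties deterministically
    heap: list[tuple[int, int, int]] = []

    def push(lo: int, hi: int) -> None:
        if hi <= lo:
            return
        if np.count_nonzero(counts[lo : hi + 1]) < 2:
            return
        mass = int(counts[lo : hi + 1].sum())
        heapq.heappush(heap, (-mass, lo, hi))

    push(lo0, hi0)
    while heap and len(thresholds) < n:
        _, lo, hi = heapq.heappop(heap)
        mu, sd, _ = _interval_stats(counts, lo, hi)
        candidates = [mu] if w == 0 else [mu - w * sd, mu + w * sd]
        placed: list[int] = []
        for c in candidates:
            t = int(np.floor(c))
            t = min(max(t, lo, 1), hi - 1, 254)
            while t in thresholds and t < min(hi - 1, 254):
                t += 1  # collision: shift up one intensity unit
            if t in thresholds:
                continue
            thresholds.add(t)
            placed.append(t)
            if len(thresholds) >= n:
                break
        if placed:
            push(lo, min(placed))
            push(max(placed) + 1, hi)
    out = tuple(sorted(thresholds))
    return ThresholdSet(n=len(out), thresholds=out)


def reconstruct(channel_image: np.ndarray, ts: ThresholdSet) -> SegmentedImage:
    """Segment an image by ``ts`` and represent each segment by its mean.

    Segment ``k`` holds the pixels with ``t_k < value <= t_{k+1}`` (with
    virtual outer bounds); an empty segment falls back to its interval
    midpoint, which never occurs in the reconstruction of its own image.
    """
    img = np.asarray(channel_image)
    t = np.asarray(ts.thresholds)
    labels = np.digitize(img, t, right=True)
    n_seg = len(t) + 1
    reps = np.empty(n_seg, dtype=float)
    flat_img, flat_lab = img.ravel(), labels.ravel()
    sums = np.bincount(flat_lab, weights=flat_img.astype(float), minlength=n_seg)
    cnts = np.bincount(flat_lab, minlength=n_seg)
    edges = np.concatenate(([0], t + 1, [256]))
    for k in range(n_seg):
        if cnts[k]:
            reps[k] = sums[k] / cnts[k]
        else:
            reps[k] = 0.5 * (edges[k] + edges[k + 1] - 1)
    return SegmentedImage(labels=labels, representatives=reps, thresholds=ts.thresholds)


def psnr(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Peak signal-to-noise ratio on the 8-bit scale, 20·log10(255/RMSE), dB.

    Identical inputs return :data:`INFINITE_PSNR`.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(reconstructed, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return INFINITE_PSNR
    return 20.0 * math.log10(255.0 / math.sqrt(mse))


@dataclass(frozen=True)
class ThresholdSearch:
    """Result of the PSNR-driven search for the number of thresholds."""

    threshold_set: ThresholdSet
    psnr_by_n: dict[int, float]

    @property
    def selected_n(self) -> int:
        return self.threshold_set.n


def choose_optimal_n(
    channel_image: np.ndarray,
    n_range: tuple[int, int] = (2, 15),
    epsilon_db: float = 1.0,
    w: float = 1.0,
) -> ThresholdSearch:
    """Pick the number of thresholds by the PSNR elbow rule.

    Scans ``n`` upward through ``n_range`` and returns the smallest ``n``
    whose PSNR gain over ``n − 1`` falls below ``epsilon_db``; the search
    also stops when the reconstruction becomes lossless or when the
    histogram saturates (no further threshold can be placed).  The full PSNR
    curve is returned alongside the selection.  A constant image yields the
    degenerate single-segment result ``n = 0`` with a warning.
    """
    if epsilon_db <= 0:
        raise ValueError("epsilon_db must be > 0")
    lo_n, hi_n = n_range
    if lo_n < 1 or hi_n < lo_n:
        raise ValueError(f"invalid n_range {n_range}")
    img = np.asarray(channel_image)
    hist = compute_histogram(img)
    if np.count_nonzero(hist.counts) < 2:
        warnings.warn("degenerate (constant) image: returning n = 0", stacklevel=2)
        ts = ThresholdSet(n=0, thresholds=(), psnr_db=INFINITE_PSNR)
        return ThresholdSearch(ts, {0: INFINITE_PSNR})

    curve: dict[int, float] = {}
    sets: dict[int, ThresholdSet] = {}
    chosen: ThresholdSet | None = None
    prev_psnr: float | None = None
    start = max(1, lo_n - 1)  # baseline below the range to seed the gain
    for n_ in range(start, hi_n + 1):
        ts = select_thresholds(hist, n_, w)
        if ts.n < n_:  # histogram saturated; keep the largest realized set
            chosen = sets.get(n_ - 1, ts)
            break
        p = psnr(img, reconstruct(img, ts).reconstruction)
        curve[n_] = p
        sets[n_] = ts
        if p == INFINITE_PSNR:
            chosen = ts
            break
        if prev_psnr is not None and (p - prev_psnr) < epsilon_db and n_ >= lo_n:
            chosen = ts
            break
        prev_psnr = p
    if chosen is None:
        chosen = sets[max(sets)]
    final = ThresholdSet(
        n=chosen.n, thresholds=chosen.thresholds,
        psnr_db=curve.get(chosen.n, INFINITE_PSNR),
    )
    return ThresholdSearch(final, curve)


@dataclass(frozen=True)
class DetectionConfig:
    """Cell-extraction parameters."""

    pixel_size: float = 1.0  # μm per pixel
    min_area: int = 10  # px; smaller components are discarded as speckle
    n_range: tuple[int, int] = (2, 15)
    epsilon_db: float = 1.0
    w: float = 1.0
    core_fraction: float = 0.5  # intensity fraction defining the FWHM core


def detect_cells(
    multichannel_image: np.ndarray,
    cfg: DetectionConfig = DetectionConfig(),
    threshold_sets: list[ThresholdSet] | None = None,
) -> tuple[pd.DataFrame, list[ThresholdSearch]]:
    """Extract cells from a (C, H, W) or (H, W) 8-bit image.

    Foreground is the union over channels of pixels strictly above the
    channel's lowest threshold; connected components (8-connectivity) of at
    least ``min_area`` pixels become cells.  Per cell: unweighted centroid in
    μm and mean intensity per channel over the half-max core.  Returns the
    cell table and the per-channel threshold searches.
    """
    img = np.asarray(multichannel_image)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3:
        raise ValueError("expected a (C, H, W) or (H, W) image")
    n_ch = img.shape[0]

    searches: list[ThresholdSearch] = []
    fg = np.zeros(img.shape[1:], dtype=bool)
    for c in range(n_ch):
        if threshold_sets is not None:
            ts = threshold_sets[c]
            search = ThresholdSearch(ts, {})
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search = choose_optimal_n(
                    img[c], n_range=cfg.n_range, epsilon_db=cfg.epsilon_db, w=cfg.w
                )
            ts = search.threshold_set
        searches.append(search)
        if ts.thresholds:
            fg |= img[c] > ts.thresholds[0]

    cols = ["cell_id", "x_um", "y_um"] + [f"ch{i + 1}" for i in range(n_ch)] + [
        "area_px"
    ]
    rows = []
    labels = measure.label(fg, connectivity=2)
    for prop in measure.regionprops(labels):
        if prop.area < cfg.min_area:
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        stack = img[:, rr, cc].astype(float)  # (C, n_px)
        maxproj = stack.max(axis=0)
        core = maxproj >= cfg.core_fraction * maxproj.max()
        means = stack[:, core].mean(axis=1)
        cy, cx = prop.centroid
        rows.append(
            [len(rows), cx * cfg.pixel_size, cy * cfg.pixel_size]
            + [float(m) for m in means]
            + [int(prop.area)]
        )
    return pd.DataFrame(rows, columns=cols), searches
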