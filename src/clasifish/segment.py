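"""ImageJ-dialect cell segmentation for unmixed channel images.

Reproduces the classic FIJI quantification chain: a 3x3 median filter, a
global IsoData or local Bernsen threshold per channel, watershed "segmented
particles" seeded at intensity maxima of a given prominence, boundary pasting
to split touching cells, and small-object removal.

IsoData here is the iterative intermeans threshold: t converges to the mean
of the two class means.  On float images a 256-bin histogram quantization is
used (the ImageJ dialect); integer images iterate on exact values.  Bernsen
thresholds each pixel at the local mid-gray (max+min)/2 over a disk window,
with a contrast floor below which the window resolves uniformly by comparing
the mid-gray against half the dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = [
    "SegmentationParams",
    "median3x3",
    "threshold_isodata",
    "threshold_bernsen",
    "maxima_particles",
    "split_and_label",
    "segment_channel",
    "robust_noise_sd",
]


@dataclass
class SegmentationParams:
    """Per-channel segmentation settings.

    ``channel_method`` maps a taxon-channel name to "bernsen" or "isodata";
    unlisted channels default to "isodata".  Bernsen radius/contrast default
    to the common FIJI Auto Local Threshold values.  ``maxima_prominence``
    of None means 2x the channel's robust noise SD, estimated at call time.
    ``min_object_area_um2`` implements the small-object ("noise") removal.
    """

    bernsen_radius_px: int = 9
    bernsen_contrast: float = 15.0
    maxima_prominence: float | None = None
    min_object_area_um2: float = 0.05
    channel_method: dict[str, str] = field(
        default_factory=lambda: {"Alphaproteobacteria": "bernsen"}
    )
    channel_prominence_multiplier: dict[str, float] = field(
        default_factory=lambda: {"Granulosicoccus": 0.75}
    )

    def prominence_multiplier_for(self, channel: str) -> float:
        return self.channel_prominence_multiplier.get(channel, 2.0)

    def __post_init__(self) -> None:
        if self.bernsen_radius_px < 1:
            raise ValueError("bernsen_radius_px must be >= 1")
        if self.maxima_prominence is not None and self.maxima_prominence <= 0:
            raise ValueError("maxima_prominence must be > 0")
        if self.min_object_area_um2 < 0:
            raise ValueError("min_object_area_um2 must be >= 0")

    def method_for(self, channel: str) -> str:
        return self.channel_method.get(channel, "isodata")


@dataclass
class LabelImage:
    """Connected-component labels (0 = background) with physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas_um2(self) -> np.ndarray:
        counts = np.bincount(self.labels.ravel())[1:]
        return counts * self.pixel_size_um**2


def median3x3(channel: np.ndarray) -> np.ndarray:
    """3x3 median filter with replicate edge padding (noise removal,
    edge preserving)."""
    channel = np.asarray(channel)
    if channel.ndim != 2 or min(channel.shape) < 3:
        raise ValueError("channel must be 2-D with H, W >= 3")
    return ndimage.median_filter(channel, size=3, mode="nearest")


def threshold_isodata(channel: np.ndarray, nbins: int = 256):
    """Iterative intermeans (IsoData) threshold.

    Iterates t <- (mean(values <= t) + mean(values > t)) / 2 from the global
    mean until convergence; returns ``(mask, t)`` with mask = values > t.
    Integer inputs iterate on exact values; float inputs are quantized to
    ``nbins`` histogram bins first.
    """
    channel = np.asarray(channel)
    values = channel.ravel().astype(float)
    if np.ptp(values) == 0:
        raise ValueError("constant image has no IsoData threshold")
    if not np.issubdtype(channel.dtype, np.integer):
        lo, hi = values.min(), values.max()
        # quantize to bin centers, threshold mapped back to original scale
        width = (hi - lo) / nbins
        values = lo + (np.clip((values - lo) / width, 0, nbins - 1) + 0.5) * width
    t = values.mean()
    for _ in range(500):
        low = values[values <= t]
        high = values[values > t]
        if low.size == 0 or high.size == 0:
            break
        t_new = 0.5 * (low.mean() + high.mean())
        if abs(t_new - t) < 1e-12 * max(1.0, abs(t)):
            t = t_new
            break
        t = t_new
    return channel > t, float(t)


def threshold_bernsen(
    channel: np.ndarray, radius: int = 15, contrast_threshold: float = 15.0
) -> np.ndarray:
    """Bernsen local threshold over a disk neighborhood.

    Where local contrast (max - min) meets the contrast threshold, a pixel is
    foreground iff it is at or above the local mid-gray (max+min)/2.  In
    low-contrast windows the whole window resolves uniformly: foreground iff
    the mid-gray is at or above half the image's dynamic range.
    """
    channel = np.asarray(channel, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (yy**2 + xx**2) <= radius**2
    local_max = ndimage.maximum_filter(channel, footprint=disk, mode="nearest")
    local_min = ndimage.minimum_filter(channel, footprint=disk, mode="nearest")
    midgray = 0.5 * (local_max + local_min)
    contrast = local_max - local_min
    half_range = 0.5 * (float(channel.max()) + float(channel.min()))
    high_contrast = contrast >= contrast_threshold
    return np.where(high_contrast, channel >= midgray, midgray >= half_range)


def robust_noise_sd(channel: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (robust to cells)."""
    channel = np.asarray(channel, dtype=float)
    med = np.median(channel)
    return float(1.4826 * np.median(np.abs(channel - med)))


def maxima_particles(channel: np.ndarray, prominence: float) -> np.ndarray:
    """Find-maxima "segmented particles": watershed lines between maxima.

    Regional maxima whose prominence (height above the highest saddle leading
    to a higher maximum; the morphological *dynamics*) is at least
    ``prominence`` seed a watershed of the inverted image; the returned
    boolean mask marks the watershed boundary lines (one particle per
    retained maximum, empty mask for a single maximum).
    """
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    channel = np.asarray(channel, dtype=float)
    seeds = h_maxima(channel, prominence)
    markers, n = ndimage.label(seeds)
    if n <= 1:
        return np.zeros(channel.shape, dtype=bool)
    ws = watershed(-channel, markers=markers, watershed_line=True)
    return ws == 0


def split_and_label(
    threshold_mask: np.ndarray,
    boundary_mask: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> LabelImage:
    """Paste watershed boundaries into the thresholded mask and label cells.

    Boundary pixels are forced to background, connected components are
    labeled with 4-connectivity (so 1-px watershed lines separate particles),
    components smaller than ``min_object_area_um2`` are dropped, and labels
    are renumbered contiguously 1..K.
    """
    threshold_mask = np.asarray(threshold_mask, dtype=bool)
    boundary_mask = np.asarray(boundary_mask, dtype=bool)
    if threshold_mask.shape != boundary_mask.shape:
        raise ValueError("mask shapes differ")
    mask = threshold_mask & ~boundary_mask
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    if n:
        areas = np.bincount(labels.ravel())[1:] * pixel_size_um**2
        keep = np.flatnonzero(areas >= params.min_object_area_um2) + 1
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
    return LabelImage(labels=labels, pixel_size_um=pixel_size_um)


def segment_channel(
    channel: np.ndarray,
    method: str,
    params: SegmentationParams,
    pixel_size_um: float,
) -> tuple[LabelImage, dict]:
    """Full per-channel chain: median -> threshold -> maxima split -> label.

    Returns the label image and a report dict (method, threshold, prominence).
    """
    filtered = median3x3(channel)
    if method == "bernsen":
        # the configured contrast is a floor; on float channels the working
        # contrast must clear the channel's own noise spread or pure-noise
        # windows count as "high contrast"
        contrast = max(params.bernsen_contrast, 6.0 * robust_noise_sd(filtered))
        mask = threshold_bernsen(filtered, params.bernsen_radius_px, contrast)
        threshold = None
    elif method == "isodata":
        mask, threshold = threshold_isodata(filtered)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    prominence = params.maxima_prominence
    if prominence is None:
        prominence = max(2.0 * robust_noise_sd(filtered), 1e-6)
    boundaries = maxima_particles(filtered, prominence)
    labels = split_and_label(mask, boundaries, params, pixel_size_um)
    report = {
        "method": method,
        "threshold": threshold,
        "maxima_prominence": float(prominence),
        "n_objects": labels.n_labels,
    }
    return labels, report
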