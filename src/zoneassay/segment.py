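"""Cell-free-area segmentation of brightfield monolayer images.

The measurement chain converts one RGB well image into a calibrated cell-free
area.  It exploits the fact that a confluent monolayer is rich in intensity
edges (cell borders) while the cell-free zone is smooth: after Sobel edge
enhancement, a maximum-entropy (Kapur) threshold separates edge pixels from
smooth pixels, and the smooth, non-edge region is taken as the cell-free
candidate.  Binary erosion, hole filling and a calibrated particle-size
filter then isolate the zone itself.

Fixed stage order::

    to_grayscale -> crop -> find_edges -> max_entropy_threshold -> binarize
        -> erode -> fill_holes -> extract_cellfree

Polarity contract: in every :class:`BinaryMask` produced here, ``True``
(foreground) means *cell-free*.  The original interactive workflow expressed
this via a display-level LUT inversion; here it is an explicit complement
inside :func:`binarize` so that all subsequent morphology is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "RGBFrame",
    "GrayFrame",
    "BinaryMask",
    "AreaResult",
    "PipelineParams",
    "to_grayscale",
    "crop",
    "center_crop",
    "find_edges",
    "max_entropy_threshold",
    "binarize",
    "erode",
    "fill_holes",
    "extract_cellfree",
    "run_pipeline",
]

# 8-connected structuring element shared by erosion and particle labelling.
_SE8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RGBFrame:
    """8-bit, 3-channel well image with its pixel calibration (px per um)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    pixel_scale_px_per_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB data, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixel data, got {px.dtype}")
        if not self.pixel_scale_px_per_um > 0:
            raise ValueError("pixel_scale_px_per_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GrayFrame:
    """8-bit single-channel image with pixel calibration."""

    pixels: np.ndarray  # (H, W) uint8
    pixel_scale_px_per_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D grayscale data, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixel data, got {px.dtype}")
        if not self.pixel_scale_px_per_um > 0:
            raise ValueError("pixel_scale_px_per_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Boolean grid; ``True`` = cell-free (module-wide polarity contract)."""

    foreground: np.ndarray  # (H, W) bool
    pixel_scale_px_per_um: float

    def __post_init__(self) -> None:
        fg = np.asarray(self.foreground)
        if fg.ndim != 2 or fg.dtype != bool:
            raise ValueError("foreground must be a 2-D boolean array")
        if not self.pixel_scale_px_per_um > 0:
            raise ValueError("pixel_scale_px_per_um must be > 0")
        object.__setattr__(self, "foreground", fg)

    @property
    def shape(self) -> tuple[int, int]:
        return self.foreground.shape

    def area_um2(self) -> float:
        """Calibrated foreground area: pixel count / scale^2."""
        return float(self.foreground.sum()) / self.pixel_scale_px_per_um**2


@dataclass(frozen=True)
class AreaResult:
    """Calibrated cell-free area of one frame plus component bookkeeping."""

    area_um2: float
    n_components_in_range: int
    component_mask: BinaryMask
    warnings: tuple[str, ...] = ()
    stages: Optional[dict] = field(default=None, compare=False, repr=False)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    @property
    def equivalent_diameter_mm(self) -> float:
        """Diameter of the circle with the measured area, in mm."""
        return 2.0 * float(np.sqrt(self.area_mm2 / np.pi))


@dataclass(frozen=True)
class PipelineParams:
    """Shared parameter set for the segmentation chain.

    ``crop_fraction`` is the side of the centred square crop as a fraction of
    the shorter image side (1.0 disables cropping).  Size-filter bounds are in
    calibrated um^2: the defaults 1e5–7e8 correspond to 0.1–700 mm^2, i.e. at
    0.3525 px/um a minimum particle of ~12.4 kpx.
    """

    pixel_scale_px_per_um: float = 0.3525
    crop_fraction: float = 0.8
    erode_iterations: int = 1
    min_um2: float = 1e5
    max_um2: float = 7e8
    dark_background: bool = True
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        if not self.pixel_scale_px_per_um > 0:
            raise ValueError("pixel_scale_px_per_um must be > 0")
        if not 0 < self.crop_fraction <= 1:
            raise ValueError("crop_fraction must be in (0, 1]")
        if self.erode_iterations < 0:
            raise ValueError("erode_iterations must be >= 0")
        if self.min_um2 < 0 or self.max_um2 < self.min_um2:
            raise ValueError("size filter bounds must satisfy 0 <= min <= max")


def to_grayscale(rgb: RGBFrame) -> GrayFrame:
    """Convert RGB to 8-bit gray as the unweighted channel mean, truncated.

    (r + g + b) // 3 per pixel — the plain average without luminance
    weighting, matching the behaviour the measurement chain was calibrated
    against.
    """
    sums = rgb.pixels.astype(np.uint16).sum(axis=2)
    gray = (sums // 3).astype(np.uint8)
    return GrayFrame(gray, rgb.pixel_scale_px_per_um)


def crop(frame: GrayFrame, top: int, left: int, height: int, width: int) -> GrayFrame:
    """Rectangular crop in pixels; the pixel scale is preserved."""
    h, w = frame.shape
    if height <= 0 or width <= 0:
        raise ValueError("crop height and width must be positive")
    if top < 0 or left < 0 or top + height > h or left + width > w:
        raise ValueError(
            f"crop ({top},{left},{height},{width}) exceeds frame bounds {h}x{w}"
        )
    return GrayFrame(
        frame.pixels[top : top + height, left : left + width].copy(),
        frame.pixel_scale_px_per_um,
    )


def center_crop(frame: GrayFrame, fraction: float) -> GrayFrame:
    """Centred square crop with side = fraction * min(H, W)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    h, w = frame.shape
    side = int(round(fraction * min(h, w)))
    side = max(side, 1)
    top = (h - side) // 2
    left = (w - side) // 2
    return crop(frame, top, left, side, side)


def find_edges(frame: GrayFrame) -> GrayFrame:
    """3x3 Sobel gradient magnitude, clipped to [0, 255] and truncated.

    Border rows/columns use the replicated-edge convention, which produces no
    spurious response along the image frame.
    """
    h, w = frame.shape
    if h < 3 or w < 3:
        raise ValueError(f"frame must be at least 3x3 for Sobel, got {h}x{w}")
    img = frame.pixels.astype(np.float32)
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    out = np.clip(mag, 0, 255).astype(np.uint8)  # astype truncates
    return GrayFrame(out, frame.pixel_scale_px_per_um)


def max_entropy_threshold(histogram: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of a 256-bin histogram.

    Scans every candidate threshold T and returns the one maximising
    psi(T) = H_low(T) + H_high(T), the sum of Shannon entropies of the
    below/above-threshold class distributions (each renormalised by its own
    class probability).  Candidates leaving either class empty are skipped;
    exact ties resolve to the lowest T.

    Raises ``ValueError`` for degenerate histograms with fewer than two
    occupied bins, where no split exists.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"histogram must have 256 bins, got shape {hist.shape}")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if int((hist > 0).sum()) < 2:
        raise ValueError("histogram has fewer than two occupied bins; no threshold exists")
    p = hist / total

    best_t = -1
    best_psi = -np.inf
    # psi(T) only changes when T crosses an occupied bin, and the lowest T of
    # each constant run is an occupied bin itself, so scanning occupied bins
    # (except the last, whose high class is empty) realises the lowest-tie
    # rule exactly.
    occupied = np.flatnonzero(hist > 0)
    for t in occupied[:-1]:
        low = p[: t + 1]
        high = p[t + 1 :]
        p_low = float(np.sum(low))
        p_high = float(np.sum(high))
        ql = low[low > 0] / p_low
        qh = high[high > 0] / p_high
        psi = float(-np.sum(ql * np.log(ql)) - np.sum(qh * np.log(qh)))
        if psi > best_psi:
            best_psi = psi
            best_t = int(t)
    return best_t


def binarize(frame: GrayFrame, threshold: int, dark_background: bool = True) -> BinaryMask:
    """Threshold an edge image into the cell-free-candidate mask.

    With ``dark_background`` (the normal case for an edge image), pixels with
    intensity strictly above the threshold are provisional edge/cell pixels.
    The returned mask is polarity-normalised to the module contract
    (foreground = cell-free), i.e. the complement of the edge set.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in 0..255")
    if dark_background:
        edge = frame.pixels > threshold
    else:
        edge = frame.pixels <= threshold
    return BinaryMask(~edge, frame.pixel_scale_px_per_um)


def erode(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Binary erosion with the full 3x3 (8-connected) structuring element.

    Pixels on the image border are treated as adjacent to background, so a
    foreground region touching the border is eroded there too.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.foreground.copy(), mask.pixel_scale_px_per_um)
    out = ndimage.binary_erosion(
        mask.foreground, structure=_SE8, iterations=iterations, border_value=0
    )
    return BinaryMask(out, mask.pixel_scale_px_per_um)


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill enclosed background: components not 4-connected to the border."""
    out = ndimage.binary_fill_holes(mask.foreground)
    return BinaryMask(out, mask.pixel_scale_px_per_um)


def extract_cellfree(
    mask: BinaryMask,
    min_um2: float = 1e5,
    max_um2: float = 7e8,
) -> AreaResult:
    """Particle analysis: keep 8-connected components within the size range.

    Each component's pixel count is calibrated to um^2 via count/scale^2;
    components outside [min_um2, max_um2] are discarded and the surviving
    components are unioned.  An empty survivor set yields a zero-area result
    carrying a warning (the frame stays in its series as area 0).
    """
    scale = mask.pixel_scale_px_per_um
    labels, n = ndimage.label(mask.foreground, structure=_SE8)
    warns: list[str] = []
    if n == 0:
        warns.append("no foreground components found; reporting area 0")
        empty = BinaryMask(np.zeros(mask.shape, dtype=bool), scale)
        return AreaResult(0.0, 0, empty, tuple(warns))
    counts = np.bincount(labels.ravel())[1:]  # skip background label 0
    areas_um2 = counts / scale**2
    keep = (areas_um2 >= min_um2) & (areas_um2 <= max_um2)
    n_kept = int(keep.sum())
    if n_kept == 0:
        warns.append(
            f"no component within size range [{min_um2:g}, {max_um2:g}] um^2; "
            "reporting area 0"
        )
        empty = BinaryMask(np.zeros(mask.shape, dtype=bool), scale)
        return AreaResult(0.0, 0, empty, tuple(warns))
    kept_labels = np.flatnonzero(keep) + 1
    union = np.isin(labels, kept_labels)
    total_um2 = float(areas_um2[keep].sum())
    return AreaResult(total_um2, n_kept, BinaryMask(union, scale), tuple(warns))


def run_pipeline(rgb: RGBFrame, params: PipelineParams | None = None) -> AreaResult:
    """Run the full measurement chain on one RGB frame.

    Stage order is fixed (see module docstring).  A degenerate threshold
    (e.g. a perfectly uniform edge image) is downgraded to a zero-area result
    with a warning so that batch runs are robust.  With
    ``params.keep_intermediates`` the returned result carries every
    intermediate frame under ``stages`` for debugging.
    """
    if params is None:
        params = PipelineParams(pixel_scale_px_per_um=rgb.pixel_scale_px_per_um)
    gray = to_grayscale(rgb)
    cropped = center_crop(gray, params.crop_fraction)
    edges = find_edges(cropped)
    hist = np.bincount(edges.pixels.ravel(), minlength=256)
    stages = (
        {"gray": gray, "cropped": cropped, "edges": edges}
        if params.keep_intermediates
        else None
    )
    try:
        threshold = max_entropy_threshold(hist)
    except ValueError as exc:
        warnings.warn(f"degenerate threshold: {exc}; reporting area 0", stacklevel=2)
        empty = BinaryMask(np.zeros(edges.shape, dtype=bool), edges.pixel_scale_px_per_um)
        return AreaResult(
            0.0, 0, empty, (f"degenerate threshold: {exc}",), stages
        )
    mask = binarize(edges, threshold, dark_background=params.dark_background)
    eroded = erode(mask, params.erode_iterations)
    filled = fill_holes(eroded)
    result = extract_cellfree(filled, params.min_um2, params.max_um2)
    if stages is not None:
        stages.update(
            {"threshold": threshold, "binary": mask, "eroded": eroded, "filled": filled}
        )
        result = replace(result, stages=stages)
    return result
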