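"""Fluorescence SBR quantification and simplified marker segmentation.

The signal-to-background ratio (SBR) of a target is measured on an RGB frame
recorded in fluorescence mode: saturated (near-white) reflections of the
excitation light are first excluded with an HSV mask, then the signal is the
mean green-channel value inside a rectangular region of interest around the
target, and the background is the mean of three adjacent background ROIs
(nearest non-target lid locations in practice).  SBR = signal / background.

Also provided: colour/shape segmentation of the rectangular instrument marker
(yellow on the forceps shaft), a luminance/green-dominance classifier of the
imaging mode, and an approximate monocular depth estimate from the apparent
marker size (pinhole model with known marker width; no stereo calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops

# Default saturation mask: pixels with HSV saturation below S_MAX and value
# above V_MIN (normalized) are treated as specular white and excluded.
SATURATION_S_MAX = 0.15
SATURATION_V_MIN = 0.9


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned rectangular region of interest, pixel units.

    ``center`` is (x, y) with 0-based indexing, top-left origin, row-major
    images; ``width``/``height`` are extents in pixels.
    """

    center: tuple[float, float]
    width: int
    height: int

    @classmethod
    def from_xywh(cls, x: int, y: int, w: int, h: int) -> "RoiSpec":
        """Build from a top-left (x, y, width, height) rectangle."""
        return cls(center=(x + w / 2, y + h / 2), width=w, height=h)

    def slices(self, image_shape: tuple[int, ...]) -> tuple[slice, slice]:
        """(row, col) slices; raises if the ROI leaves the image."""
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must cover at least 1 pixel")
        cx, cy = self.center
        x0 = int(round(cx - self.width / 2))
        y0 = int(round(cy - self.height / 2))
        x1, y1 = x0 + self.width, y0 + self.height
        h, w = image_shape[:2]
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValueError(
                f"ROI [{x0}:{x1}) x [{y0}:{y1}) outside image of size {w} x {h}"
            )
        return slice(y0, y1), slice(x0, x1)


@dataclass
class SbrMeasurement:
    """Result of one SBR measurement."""

    signal_mean: float
    background_mean: float
    sbr: float
    n_masked_pixels: int


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    return image


# ---------------------------------------------------------------------------
# Saturation masking + SBR
# ---------------------------------------------------------------------------

def mask_saturation(
    rgb_image: np.ndarray,
    s_max: float = SATURATION_S_MAX,
    v_min: float = SATURATION_V_MIN,
) -> np.ndarray:
    """Boolean mask of saturated (near-white) pixels to exclude.

    A pixel is masked when its HSV saturation is below ``s_max`` and its value
    above ``v_min`` (both on the normalized 0-1 scale) — i.e. it is bright but
    colourless, the signature of a specular reflection rather than of the
    green fluorescence overlay.
    """
    image = _check_rgb(rgb_image)
    hsv = rgb2hsv(image)
    return (hsv[..., 1] < s_max) & (hsv[..., 2] > v_min)


def measure_sbr(
    rgb_image: np.ndarray,
    signal_roi: RoiSpec,
    background_rois: Sequence[RoiSpec],
    s_max: float = SATURATION_S_MAX,
    v_min: float = SATURATION_V_MIN,
) -> SbrMeasurement:
    """Measure the fluorescent SBR of a target.

    Signal is the mean green-channel value over unmasked pixels of the signal
    ROI; background is the average of the three background-ROI means (each
    over its own unmasked pixels).
    """
    image = _check_rgb(rgb_image).astype(float)
    if len(background_rois) != 3:
        raise ValueError(f"exactly three background ROIs required, got {len(background_rois)}")
    masked = mask_saturation(rgb_image, s_max=s_max, v_min=v_min)
    green = image[..., 1]

    def roi_mean(roi: RoiSpec, label_: str) -> tuple[float, int]:
        rows, cols = roi.slices(image.shape)
        valid = ~masked[rows, cols]
        if not np.any(valid):
            raise ValueError(f"no valid pixels: {label_} ROI is fully saturation-masked")
        return float(np.mean(green[rows, cols][valid])), int(np.sum(~valid))

    signal_mean, n_masked = roi_mean(signal_roi, "signal")
    bg_means = []
    for i, roi in enumerate(background_rois):
        m, k = roi_mean(roi, f"background {i + 1}")
        bg_means.append(m)
        n_masked += k
    background_mean = float(np.mean(bg_means))
    if background_mean == 0:
        raise ValueError("zero background: cannot form an SBR")
    return SbrMeasurement(
        signal_mean=signal_mean,
        background_mean=background_mean,
        sbr=signal_mean / background_mean,
        n_masked_pixels=n_masked,
    )


def propose_background_rois(
    target_center_px: tuple[float, float],
    candidate_centers_px: Sequence[tuple[float, float]],
    roi_width: int,
    roi_height: int,
) -> list[RoiSpec]:
    """Three background ROIs at the nearest candidate (non-target) lid centres.

    Operationalizes "adjacent locations": of the supplied candidates (typically
    every lid centre not holding a target), the three closest to the target
    are used.
    """
    if len(candidate_centers_px) < 3:
        raise ValueError("need at least three candidate background locations")
    tx, ty = target_center_px
    dists = [np.hypot(cx - tx, cy - ty) for cx, cy in candidate_centers_px]
    order = np.argsort(dists, kind="stable")[:3]
    return [
        RoiSpec(center=tuple(candidate_centers_px[i]), width=roi_width, height=roi_height)
        for i in order
    ]


# ---------------------------------------------------------------------------
# Marker segmentation
# ---------------------------------------------------------------------------

@dataclass
class MarkerDetection:
    """Segmented instrument marker: centroid (x, y) px and bounding box."""

    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    area: int


@dataclass
class ShapeParams:
    """Shape filter for marker candidates."""

    min_area: int = 50
    max_area: int = 100_000
    min_rectangularity: float = 0.8  # filled area / bounding-box area


def segment_marker(
    rgb_image: np.ndarray,
    hsv_low: tuple[float, float, float],
    hsv_high: tuple[float, float, float],
    shape_params: ShapeParams | None = None,
) -> MarkerDetection | None:
    """Find the instrument marker by colour and shape.

    Pixels inside the HSV range (normalized 0-1 channels) are labelled into
    connected components; components are filtered by area bounds and
    rectangularity (extent = area / bbox area), and the largest survivor wins.
    Returns None when nothing passes — absence is a valid result (marker
    occluded or out of frame).
    """
    image = _check_rgb(rgb_image)
    shape_params = shape_params or ShapeParams()
    hsv = rgb2hsv(image)
    low = np.asarray(hsv_low)
    high = np.asarray(hsv_high)
    in_range = np.all((hsv >= low) & (hsv <= high), axis=-1)
    if not np.any(in_range):
        return None
    labels = label(in_range)
    best: MarkerDetection | None = None
    for region in regionprops(labels):
        if not (shape_params.min_area <= region.area <= shape_params.max_area):
            continue
        if region.extent < shape_params.min_rectangularity:
            continue
        if best is None or region.area > best.area:
            cy, cx = region.centroid
            best = MarkerDetection(
                centroid=(float(cx), float(cy)),
                bbox=tuple(int(v) for v in region.bbox),
                area=int(region.area),
            )
    return best


def estimate_depth_mm(
    detection: MarkerDetection,
    marker_width_mm: float,
    focal_length_px: float,
) -> float:
    """Approximate monocular depth from apparent marker width.

    Pinhole model: z = f * W / w_px with known physical marker width W.  This
    is a rough scale cue only — no lens distortion, no stereo, and it degrades
    with marker tilt; treat the result as indicative.
    """
    min_row, min_col, max_row, max_col = detection.bbox
    w_px = max(max_col - min_col, 1)
    return focal_length_px * marker_width_mm / w_px


# ---------------------------------------------------------------------------
# Imaging-mode classification
# ---------------------------------------------------------------------------

def classify_mode(
    rgb_image: np.ndarray,
    luminance_max: float = 120.0,
    dominance_min: float = 1.2,
) -> str:
    """Classify a frame as ``firefly`` or ``white_light``.

    Fluorescence mode shows green signal on a dark background, so a frame is
    called ``firefly`` when the mean luminance is below ``luminance_max``
    (8-bit scale) and the mean green channel is at least ``dominance_min``
    times the mean of red and blue.  An all-black frame satisfies both
    comparisons degenerately (0 >= 1.2 * 0) and is classified ``firefly`` —
    the documented dark-default tie rule.
    """
    raw = _check_rgb(rgb_image)
    image = raw.astype(float)
    if np.issubdtype(raw.dtype, np.floating) and image.max() <= 1.0:
        image = image * 255.0
    r = float(np.mean(image[..., 0]))
    g = float(np.mean(image[..., 1]))
    b = float(np.mean(image[..., 2]))
    luminance = 0.2126 * r + 0.7152 * g + 0.0722 * b
    if luminance < luminance_max and g >= dominance_min * (r + b) / 2:
        return "firefly"
    return "white_light"
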