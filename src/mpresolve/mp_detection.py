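"""Per-frame macropinosome detection.

The detector mirrors a fixed recipe: maximum z-projection, histogram
truncation to the 15th-95th percentile band, cell segmentation from an
inverse-Gaussian-gradient map (alpha=100, sigma=5, below-30th-percentile
threshold), multiscale difference-of-Gaussians blob proposal (kernel sd
1-15 px, response floor 0.01), and per-candidate refinement in a 50x50 px
crop: Canny edges (sigma=4, hysteresis thresholds 0/100 on 16-bit-scaled
data) followed by a circular Hough transform over radii 3-35 px.  The five
strongest Hough peaks are inspected; a candidate is accepted only if at
least two of the five circle centres fall within 5 px of the crop centre,
and its radius is the 95th percentile of those qualifying radii.

Coordinates are 0-based (row, col) floats; radii in float pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure
from skimage.feature import blob_dog, canny
from skimage.segmentation import inverse_gaussian_gradient
from skimage.transform import hough_circle

__all__ = [
    "DetectionConfig",
    "MPCandidate",
    "MPDetection",
    "max_project",
    "truncate_histogram",
    "segment_cells",
    "detect_blobs",
    "refine_circle",
    "detect_frame",
    "detect_movie",
]


@dataclass
class DetectionConfig:
    """All tunables of the detection chain (defaults are the study recipe)."""

    truncate_low_pct: float = 15.0
    truncate_high_pct: float = 95.0
    igg_alpha: float = 100.0
    igg_sigma: float = 5.0
    cell_threshold_pct: float = 30.0
    threshold_on_filtered: bool = True  # percentile taken on the gradient map
    blob_min_sigma: float = 1.0
    blob_max_sigma: float = 15.0
    blob_threshold: float = 0.01
    crop_size: int = 50
    canny_sigma: float = 4.0
    canny_low: float = 0.0
    canny_high: float = 100.0
    hough_radii: tuple[int, int] = (3, 35)
    n_hough_peaks: int = 5
    center_tolerance_px: float = 5.0
    min_qualifying: int = 2
    radius_percentile: float = 95.0
    use_cell_mask: bool = True


@dataclass
class MPCandidate:
    center: tuple[float, float]  # (row, col)
    scale: float                 # blob kernel sd, px


@dataclass
class MPDetection:
    center: tuple[float, float]
    radius: float
    frame: int = 0
    n_qualifying: int = 0


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum projection along the z axis of a Z x Y x X stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty Z x Y x X stack")
    return stack.max(axis=0)


def truncate_histogram(image: np.ndarray, low_pct: float = 15.0,
                       high_pct: float = 95.0) -> np.ndarray:
    """Clip intensities to the image's own [p_low, p_high] percentile band."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(image, [low_pct, high_pct])
    return np.clip(image, lo, hi)


def segment_cells(image: np.ndarray, config: DetectionConfig | None = None
                  ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cell mask and peripheral contours from an inverse-gradient map.

    Strong-gradient pixels (inverse map below its 30th percentile) trace the
    cell peripheries; filling those traces yields the cell regions.  Returns
    (boolean mask, contours); a blank image yields an empty mask.
    """
    config = config or DetectionConfig()
    image = np.asarray(image, dtype=float)
    span = image.max() - image.min()
    if span == 0:
        return np.zeros(image.shape, bool), []
    norm = (image - image.min()) / span
    igg = inverse_gaussian_gradient(norm, alpha=config.igg_alpha,
                                    sigma=config.igg_sigma)
    ref = igg if config.threshold_on_filtered else norm
    edges = ref < np.percentile(ref, config.cell_threshold_pct)
    mask = binary_fill_holes(edges)
    contours = measure.find_contours(mask.astype(float), 0.5)
    return mask, contours


def detect_blobs(masked_image: np.ndarray,
                 config: DetectionConfig | None = None) -> list[MPCandidate]:
    """Difference-of-Gaussians scale-space maxima as MP candidates."""
    config = config or DetectionConfig()
    image = np.asarray(masked_image, dtype=float)
    span = image.max() - image.min()
    if span == 0:
        return []
    norm = (image - image.min()) / span
    blobs = blob_dog(norm, min_sigma=config.blob_min_sigma,
                     max_sigma=config.blob_max_sigma,
                     threshold=config.blob_threshold)
    return [MPCandidate(center=(float(b[0]), float(b[1])), scale=float(b[2]))
            for b in blobs]


def _crop(image: np.ndarray, center, size: int):
    """size x size window centred on ``center``, zero-padded at borders."""
    ny, nx = image.shape
    half = size // 2
    cy, cx = int(round(center[0])), int(round(center[1]))
    out = np.zeros((size, size), dtype=float)
    y0, y1 = cy - half, cy - half + size
    x0, x1 = cx - half, cx - half + size
    sy0, sy1 = max(y0, 0), min(y1, ny)
    sx0, sx1 = max(x0, 0), min(x1, nx)
    out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out, (y0, x0)


def _top_circle_peaks(hspaces: np.ndarray, radii: np.ndarray,
                      n_peaks: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strongest accumulator peaks, one circle per centre pixel.

    Descending accumulator value; ties broken by smaller radius, then
    row-major centre order.  Concentric circles at the *same* centre pixel
    are suppressed, so the peak list can hold near-concentric circles at
    adjacent centres — the structure the 2-of-5 acceptance rule relies on.
    """
    k = min(hspaces.size, max(n_peaks * 50, 500))
    flat = hspaces.ravel()
    cand = np.argpartition(flat, -k)[-k:]
    ri, yi, xi = np.unravel_index(cand, hspaces.shape)
    order = np.lexsort((xi, yi, ri, -flat[cand]))
    seen: set[tuple[int, int]] = set()
    ys, xs, rs = [], [], []
    for idx in order:
        key = (int(yi[idx]), int(xi[idx]))
        if key in seen:
            continue
        seen.add(key)
        ys.append(int(yi[idx]))
        xs.append(int(xi[idx]))
        rs.append(int(radii[ri[idx]]))
        if len(ys) == n_peaks:
            break
    return np.array(ys), np.array(xs), np.array(rs)


def refine_circle(candidate: MPCandidate, image: np.ndarray,
                  config: DetectionConfig | None = None,
                  frame: int = 0) -> MPDetection | None:
    """Hough-confirm one blob candidate; returns None on rejection.

    The 2-of-5 rule: of the five strongest Hough circles in the crop, at
    least two centres must lie within 5 px of the crop centre.  The reported
    radius is the 95th percentile of the qualifying radii.
    """
    config = config or DetectionConfig()
    crop, (oy, ox) = _crop(image, candidate.center, config.crop_size)
    span = crop.max() - crop.min()
    if span == 0:
        return None
    # scale to a 16-bit-like range so the 0/100 hysteresis thresholds bite
    scaled = (crop - crop.min()) / span * 65535.0
    edges = canny(scaled, sigma=config.canny_sigma,
                  low_threshold=config.canny_low,
                  high_threshold=config.canny_high)
    if not edges.any():
        return None
    radii = np.arange(config.hough_radii[0], config.hough_radii[1] + 1)
    hspaces = hough_circle(edges, radii)
    cy, cx, rr = _top_circle_peaks(hspaces, radii, config.n_hough_peaks)
    if len(rr) == 0:
        return None
    # crop centre in crop coordinates is the candidate centre minus the origin
    ccy, ccx = candidate.center[0] - oy, candidate.center[1] - ox
    d = np.hypot(cy - ccy, cx - ccx)
    qual = d <= config.center_tolerance_px
    if qual.sum() < config.min_qualifying:
        return None
    radius = float(np.percentile(rr[qual].astype(float),
                                 config.radius_percentile))
    qy = float(np.mean(cy[qual])) + oy
    qx = float(np.mean(cx[qual])) + ox
    return MPDetection(center=(qy, qx), radius=radius, frame=frame,
                       n_qualifying=int(qual.sum()))


def detect_frame(stack_frame: np.ndarray,
                 config: DetectionConfig | None = None,
                 frame: int = 0) -> list[MPDetection]:
    """Full per-frame chain: project, truncate, mask cells, propose, refine."""
    config = config or DetectionConfig()
    proj = max_project(stack_frame)
    trunc = truncate_histogram(proj, config.truncate_low_pct,
                               config.truncate_high_pct)
    if config.use_cell_mask:
        mask, _ = segment_cells(trunc, config)
        work = np.where(mask, trunc, 0.0)
    else:
        work = trunc
    detections = []
    # blob proposal runs on the cell-masked image; the Hough confirmation
    # crops the unmasked truncated projection (a zeroed surround would
    # out-compete the vesicle ring in the edge detector)
    for cand in detect_blobs(work, config):
        det = refine_circle(cand, trunc, config, frame=frame)
        if det is not None:
            detections.append(det)
    return _dedupe(detections, config.center_tolerance_px)


def _dedupe(detections: list[MPDetection], tol: float) -> list[MPDetection]:
    """Merge detections closer than ``tol`` px (keep most qualifying circles)."""
    kept: list[MPDetection] = []
    for det in sorted(detections, key=lambda d: -d.n_qualifying):
        if all(math.hypot(det.center[0] - k.center[0],
                          det.center[1] - k.center[1]) > tol for k in kept):
            kept.append(det)
    return kept


def detect_movie(movie: np.ndarray,
                 config: DetectionConfig | None = None) -> list[list[MPDetection]]:
    """Apply detect_frame to every timepoint of a T x Z x Y x X movie."""
    return [detect_frame(movie[f], config, frame=f)
            for f in range(movie.shape[0])]
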