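"""Track linking, volume/intensity measurement and ratiometric pH.

Tracking runs backward in time: tracks are anchored on the detections of the
*last* frame (where shrunken MPs are brightest and most reliably found) and
extended frame by frame toward earlier timepoints, linking each track to the
nearest detection no farther than 30 px (3.3 um at 0.11 um/px).  Volume
assumes a perfectly spherical MP, V = (4/3)*pi*r^3.  Intensity is the mean
over an inner circle of half the fitted radius, measured on the original
(untruncated) projection.  Ratiometric pH divides the background-subtracted
pH-sensitive (ex 515 nm) signal by the pH-insensitive (ex 445 nm) signal,
with the per-frame background taken as the 2nd percentile of the whole
projected image, and converts ratio to pH through an ionophore-clamped
calibration curve fitted with a four-parameter logistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .mp_detection import MPDetection, max_project

__all__ = [
    "MPTrack",
    "PhCalibration",
    "link_tracks",
    "measure_intensity",
    "volume_from_radius",
    "measure_track_volumes",
    "measure_ratio",
    "fit_calibration",
    "ratio_to_ph",
    "tracks_to_frame",
]

LINK_GATE_PX = 30.0  # max centre displacement between consecutive frames


@dataclass
class MPTrack:
    """One MP followed through time (frame index -> detection)."""

    track_id: int
    detections: dict[int, MPDetection] = field(default_factory=dict)
    volumes_um3: dict[int, float] = field(default_factory=dict)
    intensities: dict[int, float] = field(default_factory=dict)
    ratios: dict[int, float] = field(default_factory=dict)
    ph: dict[int, float] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return sorted(self.detections)

    def __len__(self) -> int:
        return len(self.detections)


def link_tracks(detections_by_frame: list[list[MPDetection]],
                gate_px: float = LINK_GATE_PX) -> list[MPTrack]:
    """Backward nearest-neighbour linking with a displacement gate.

    Tracks are seeded from the final frame only.  Walking backward, every
    (track, earlier-detection) pair within the gate is considered in
    ascending distance order; each detection may extend at most one track
    (no merging).  Detections never claimed by the backward pass are
    discarded.
    """
    if not detections_by_frame:
        raise ValueError("need at least one frame of detections")
    n_frames = len(detections_by_frame)
    tracks = [MPTrack(track_id=i, detections={n_frames - 1: det})
              for i, det in enumerate(detections_by_frame[n_frames - 1])]
    active = list(tracks)
    for frame in range(n_frames - 2, -1, -1):
        dets = detections_by_frame[frame]
        pairs = []
        for ti, tr in enumerate(active):
            ref = tr.detections[frame + 1]
            for di, det in enumerate(dets):
                d = math.hypot(ref.center[0] - det.center[0],
                               ref.center[1] - det.center[1])
                if d <= gate_px:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        survivors = []
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti].detections[frame] = dets[di]
            survivors.append(active[ti])
        # tracks that found no partner terminate (they keep their later frames)
        active = survivors
    return tracks


def measure_intensity(projection: np.ndarray, detection: MPDetection) -> float:
    """Mean intensity in the inner circle of radius half the MP radius."""
    inner = detection.radius / 2.0
    if inner < 1.0:
        raise ValueError("inner circle smaller than one pixel")
    ny, nx = projection.shape
    cy, cx = detection.center
    y0, y1 = max(0, int(cy - inner) - 1), min(ny, int(cy + inner) + 2)
    x0, x1 = max(0, int(cx - inner) - 1), min(nx, int(cx + inner) + 2)
    if y0 >= y1 or x0 >= x1:
        raise ValueError("detection outside image")
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = np.hypot(yy - cy, xx - cx) < inner
    if not sel.any():
        raise ValueError("empty inner circle")
    return float(projection[y0:y1, x0:x1][sel].mean())


def volume_from_radius(radius_px: float, pixel_size_um: float) -> float:
    """Sphere volume in um^3 from a radius in pixels."""
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    return 4.0 / 3.0 * math.pi * (radius_px * pixel_size_um) ** 3


def measure_track_volumes(tracks: list[MPTrack], movie: np.ndarray,
                          pixel_size_um: float) -> None:
    """Fill per-frame volume and intensity series of every track in place.

    ``movie`` is the original T x Z x Y x X stack; intensities are measured
    on its untruncated maximum projections.
    """
    projections = {f: max_project(movie[f]) for f in range(movie.shape[0])}
    for tr in tracks:
        for f, det in tr.detections.items():
            tr.volumes_um3[f] = volume_from_radius(det.radius, pixel_size_um)
            tr.intensities[f] = measure_intensity(projections[f], det)


def measure_ratio(stack515: np.ndarray, stack445: np.ndarray,
                  tracks: list[MPTrack],
                  background_percentile: float = 2.0) -> None:
    """Background-corrected 515/445 excitation ratio per track frame.

    Backgrounds are the 2nd percentile of each frame's own projection,
    channel by channel.  Frames whose corrected 445 signal is not positive
    are flagged invalid and left out of the ratio series.
    """
    if stack515.shape != stack445.shape:
        raise ValueError("channel stacks must share a shape")
    for f in range(stack515.shape[0]):
        p515 = max_project(stack515[f])
        p445 = max_project(stack445[f])
        bg515 = np.percentile(p515, background_percentile)
        bg445 = np.percentile(p445, background_percentile)
        for tr in tracks:
            det = tr.detections.get(f)
            if det is None:
                continue
            s515 = measure_intensity(p515, det) - bg515
            s445 = measure_intensity(p445, det) - bg445
            if s445 <= 0:
                continue
            tr.ratios[f] = float(s515 / s445)


# ---------------------------------------------------------------------------
# pH calibration
# ---------------------------------------------------------------------------

def _logistic(ph, bottom, top, ph_mid, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (ph_mid - ph)))


@dataclass
class PhCalibration:
    """Fitted monotone ratio(pH) curve and its inverse.

    Four-parameter logistic: ratio rises from ``bottom`` in acid to ``top``
    in base with midpoint ``ph_mid`` and Hill-type ``slope`` (decades/pH).
    """

    bottom: float
    top: float
    ph_mid: float
    slope: float
    points: pd.DataFrame | None = None
    residuals: np.ndarray | None = None

    def ratio(self, ph: float) -> float:
        return _logistic(ph, self.bottom, self.top, self.ph_mid, self.slope)

    def ph(self, ratio: float) -> float:
        if not self.bottom < ratio < self.top:
            raise ValueError("ratio outside the calibrated range")
        frac = (self.top - self.bottom) / (ratio - self.bottom) - 1.0
        return self.ph_mid - math.log10(frac) / self.slope


def fit_calibration(points) -> PhCalibration:
    """Least-squares 4-parameter logistic through (pH, median ratio) points.

    Needs at least four distinct pH values spanning two units or more, and
    an overall increasing trend (alkaline ratios above acidic ones).
    """
    df = pd.DataFrame(points, columns=["ph", "ratio"])
    ph = df["ph"].to_numpy(float)
    ratio = df["ratio"].to_numpy(float)
    if len(np.unique(ph)) < 4:
        raise ValueError("need >= 4 distinct pH points")
    if ph.max() - ph.min() < 2.0:
        raise ValueError("calibration must span >= 2 pH units")
    order = np.argsort(ph)
    lo, hi = ratio[order][:2].mean(), ratio[order][-2:].mean()
    if not hi > lo:
        raise ValueError("calibration ratios are not increasing with pH")
    p0 = [ratio.min(), ratio.max(), float(np.median(ph)), 1.0]
    popt, _ = curve_fit(_logistic, ph, ratio, p0=p0, maxfev=20000)
    bottom, top, ph_mid, slope = popt
    if slope <= 0 or top <= bottom:
        raise ValueError("fitted calibration is not monotone increasing")
    resid = ratio - _logistic(ph, *popt)
    return PhCalibration(float(bottom), float(top), float(ph_mid),
                         float(slope), points=df, residuals=resid)


def ratio_to_ph(calibration: PhCalibration, ratio: float) -> float | None:
    """Invert the calibration; out-of-range ratios map to None (missing)."""
    try:
        return calibration.ph(ratio)
    except ValueError:
        return None


def apply_calibration(tracks: list[MPTrack], calibration: PhCalibration) -> None:
    """Convert every track's ratio series to pH in place."""
    for tr in tracks:
        for f, r in tr.ratios.items():
            ph = ratio_to_ph(calibration, r)
            if ph is not None:
                tr.ph[f] = ph


def tracks_to_frame(tracks: list[MPTrack]) -> pd.DataFrame:
    """Long-format table: one row per (track, frame)."""
    rows = []
    for tr in tracks:
        for f in tr.frames:
            det = tr.detections[f]
            rows.append({
                "track_id": tr.track_id, "frame": f,
                "y_px": det.center[0], "x_px": det.center[1],
                "radius_px": det.radius,
                "volume_um3": tr.volumes_um3.get(f, np.nan),
                "intensity": tr.intensities.get(f, np.nan),
                "ratio": tr.ratios.get(f, np.nan),
                "pH": tr.ph.get(f, np.nan),
            })
    return pd.DataFrame(rows)
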