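"""Ground-truthed synthetic time-lapse generator.

Emulates the statistical structure of spinning-disc z-stack movies of
dextran-filled macropinosomes inside macrophages: shrinking spherical
vesicles with conserved dye (so luminal concentration, and hence intensity,
rises as volume falls), a cytoplasmic background confined to cell-shaped
regions, Gaussian-PSF blur, and Poisson + read noise.  A dual-excitation
mode renders a pH reporter (one pH-insensitive channel, one channel scaled
by a sigmoid of luminal pH), and a separate generator produces wound-healing
("scratch") sequences with cells entering a cleared band at a Poisson rate.

Every generator is deterministic under a fixed seed and returns the ground
truth alongside the rendered frames, so the detection/tracking/measurement
stages can be scored without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ImagingConfig",
    "VesicleTruth",
    "Timelapse",
    "make_drifting_truths",
    "make_separated_truths",
    "render_benchmark",
    "render_timelapse",
    "render_ph_pair",
    "render_scratch_sequence",
    "simulate_then_render",
    "reporter_response",
]


@dataclass
class ImagingConfig:
    """Acquisition geometry and noise model for the synthetic microscope.

    Defaults mirror the imaging protocol the analysis was designed around:
    0.11 um pixels, 0.6 um z-steps, one frame per minute over the 5-15 min
    observation window (11 frames).
    """

    shape: tuple[int, int] = (256, 256)   # (Y, X) px
    pixel_size: float = 0.11              # um/px
    z_step: float = 0.6                   # um
    n_z: int = 7
    frame_interval: float = 60.0          # s
    n_frames: int = 11
    psf_sigma: float = 1.5                # px, isotropic Gaussian PSF
    background_level: float = 20.0        # counts
    cell_cytoplasm_level: float = 40.0    # counts above background
    poisson_gain: float = 1.0             # counts per photon; 0 disables shot noise
    read_noise_sd: float = 2.0            # counts; 0 disables read noise
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.shape) < 1 or self.n_z < 1 or self.n_frames < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.poisson_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class VesicleTruth:
    """Per-vesicle ground truth: trajectory, size, dye content, optional pH."""

    vesicle_id: int
    centers: np.ndarray        # (n_frames, 2) float px, (row, col)
    radii_px: np.ndarray       # (n_frames,)
    dye_amount: float = 1.0    # arbitrary units, conserved
    ph: np.ndarray | None = None  # (n_frames,) luminal pH, dual-channel mode

    def concentration(self, frame: int, pixel_size: float) -> float:
        r_um = self.radii_px[frame] * pixel_size
        return self.dye_amount / (4.0 / 3.0 * math.pi * r_um ** 3)


@dataclass
class Timelapse:
    """Rendered stack with calibration metadata.

    ``data`` has axes T x Z x Y x X, or T x C x Z x Y x X when ``channels``
    is set (dual-excitation mode).
    """

    data: np.ndarray
    pixel_size: float
    z_step: float
    frame_interval: float
    channels: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def make_drifting_truths(config: ImagingConfig, n_vesicles: int, *,
                         r0_px: float = 10.0,
                         shrink_fraction: float = 0.2,
                         max_step_px: float = 5.0,
                         dye_amount: float = 1.0,
                         margin_px: float = 40.0,
                         rng: np.random.Generator | None = None) -> list[VesicleTruth]:
    """Random vesicle truths: bounded random walk plus geometric shrinkage.

    Radii interpolate so that the final volume is ``shrink_fraction`` of the
    initial one; motion is a uniform random walk clipped to ``max_step_px``
    per frame (well inside the 30-px tracking gate).
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    ny, nx = config.shape
    truths = []
    t = np.arange(config.n_frames) / max(config.n_frames - 1, 1)
    radius_scale = (1.0 + (shrink_fraction ** (1.0 / 3.0) - 1.0) * t)
    for i in range(n_vesicles):
        c0 = rng.uniform([margin_px, margin_px], [ny - margin_px, nx - margin_px])
        steps = rng.uniform(-max_step_px, max_step_px, size=(config.n_frames, 2))
        steps[0] = 0.0
        centers = np.clip(c0 + np.cumsum(steps, axis=0),
                          margin_px / 2, [ny - margin_px / 2, nx - margin_px / 2])
        truths.append(VesicleTruth(
            vesicle_id=i, centers=centers,
            radii_px=r0_px * radius_scale, dye_amount=dye_amount))
    return truths


def make_separated_truths(config: ImagingConfig, n_vesicles: int, *,
                          r0_px: float = 12.0,
                          min_separation_px: float = 42.0,
                          shrink_fraction: float = 0.2,
                          max_step_px: float = 3.0,
                          margin_px: float = 25.0,
                          rng: np.random.Generator | None = None
                          ) -> list[VesicleTruth]:
    """Non-overlapping vesicle truths (rejection-sampled centres).

    Suited to detector/tracker benchmarking, where a unique nearest-truth
    match per detection is wanted.
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    ny, nx = config.shape
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n_vesicles:
        p = rng.uniform([margin_px, margin_px], [ny - margin_px, nx - margin_px])
        if all(np.hypot(*(p - q)) >= min_separation_px for q in pts):
            pts.append(p)
        attempts += 1
        if attempts > 100000:
            raise ValueError("cannot place that many separated vesicles")
    t = np.arange(config.n_frames) / max(config.n_frames - 1, 1)
    radii = r0_px * (1.0 + (shrink_fraction ** (1.0 / 3.0) - 1.0) * t)
    truths = []
    for i, p in enumerate(pts):
        steps = rng.uniform(-max_step_px, max_step_px, (config.n_frames, 2))
        steps[0] = 0.0
        centers = np.clip(p + np.cumsum(steps, axis=0), margin_px / 2,
                          [ny - margin_px / 2, nx - margin_px / 2])
        truths.append(VesicleTruth(i, centers, radii.copy()))
    return truths


def render_benchmark(n_vesicles: int = 20, snr: float = 5.0, *,
                     seed: int = 7, shape: tuple[int, int] = (300, 300),
                     r0_px: float = 12.0, n_frames: int = 1,
                     max_step_px: float = 3.0,
                     shrink_fraction: float = 0.2,
                     read_noise_sd: float = 2.0
                     ) -> tuple[Timelapse, pd.DataFrame, ImagingConfig]:
    """Standard detection/tracking benchmark movie.

    ``snr`` is the initial vesicle contrast over the cytoplasm divided by
    the cytoplasmic noise standard deviation (shot plus read noise); dye is
    conserved, so later frames get brighter as vesicles shrink.
    """
    config = ImagingConfig(shape=shape, n_frames=n_frames, rng_seed=seed,
                           background_level=100.0, cell_cytoplasm_level=100.0,
                           read_noise_sd=read_noise_sd)
    rng = np.random.default_rng(seed)
    truths = make_separated_truths(config, n_vesicles, r0_px=r0_px,
                                   max_step_px=max_step_px,
                                   shrink_fraction=shrink_fraction, rng=rng)
    level = config.background_level + config.cell_cytoplasm_level
    noise_sd = math.sqrt(level) + config.read_noise_sd
    conc0 = 1.0 / (4.0 / 3.0 * math.pi * (r0_px * config.pixel_size) ** 3)
    for tr in truths:
        tr.dye_amount = snr * noise_sd / conc0
    tl, truth = render_timelapse(config, truths)
    return tl, truth, config


def _cell_mask(config: ImagingConfig, rng: np.random.Generator,
               n_cells: int = 3) -> np.ndarray:
    """Smooth random blobby regions standing in for cell cytoplasm."""
    ny, nx = config.shape
    field_ = np.zeros((ny, nx))
    for _ in range(n_cells):
        cy, cx = rng.uniform(0.2, 0.8, 2) * (ny, nx)
        r = rng.uniform(0.25, 0.4) * min(ny, nx)
        yy, xx = np.mgrid[0:ny, 0:nx]
        field_ += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (r / 2) ** 2)))
    mask = gaussian_filter(field_, 8.0) > 0.25
    return mask


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_plane(shape, center, disc_r, amplitude):
    """Anti-aliased homogeneous disc (one z-section through a sphere)."""
    ny, nx = shape
    cy, cx = center
    if disc_r <= 0:
        return np.zeros(shape)
    r_int = int(math.ceil(disc_r)) + 2
    y0, y1 = max(0, int(cy) - r_int), min(ny, int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(nx, int(cx) + r_int + 1)
    out = np.zeros(shape)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    out[y0:y1, x0:x1] = amplitude * np.clip(disc_r - dist + 0.5, 0.0, 1.0)
    return out


def _check_inside(config: ImagingConfig, truths) -> None:
    ny, nx = config.shape
    bad = [t.vesicle_id for t in truths
           if (t.centers[:, 0] - t.radii_px < 0).any()
           or (t.centers[:, 1] - t.radii_px < 0).any()
           or (t.centers[:, 0] + t.radii_px > ny - 1).any()
           or (t.centers[:, 1] + t.radii_px > nx - 1).any()]
    if bad:
        raise ValueError(f"vesicles outside the frame: {bad}")


def _truth_table(config: ImagingConfig, truths) -> pd.DataFrame:
    rows = []
    for tr in truths:
        for f in range(config.n_frames):
            row = {
                "vesicle_id": tr.vesicle_id, "frame": f,
                "y_px": tr.centers[f, 0], "x_px": tr.centers[f, 1],
                "radius_px": tr.radii_px[f],
                "radius_um": tr.radii_px[f] * config.pixel_size,
                "volume_um3": 4.0 / 3.0 * math.pi
                              * (tr.radii_px[f] * config.pixel_size) ** 3,
                "dye_amount": tr.dye_amount,
                "concentration": tr.concentration(f, config.pixel_size),
            }
            if tr.ph is not None:
                row["pH"] = tr.ph[f]
                row["ratio_truth"] = reporter_response(tr.ph[f])
            rows.append(row)
    return pd.DataFrame(rows)


def _render_frames(config: ImagingConfig, truths, scale_fn, rng,
                   with_cells: bool = True) -> np.ndarray:
    """Core renderer; ``scale_fn(truth, frame)`` scales the dye concentration."""
    ny, nx = config.shape
    cells = (_cell_mask(config, rng) if with_cells
             else np.zeros((ny, nx), bool))
    base = config.background_level + config.cell_cytoplasm_level * cells
    half_span = (np.arange(config.n_z) - (config.n_z - 1) / 2) * config.z_step
    movie = np.empty((config.n_frames, config.n_z, ny, nx))
    for f in range(config.n_frames):
        for iz, dz_um in enumerate(half_span):
            plane = base.copy()
            for tr in truths:
                r_um = tr.radii_px[f] * config.pixel_size
                if abs(dz_um) >= r_um:
                    continue
                disc_r_px = math.sqrt(r_um ** 2 - dz_um ** 2) / config.pixel_size
                amp = tr.concentration(f, config.pixel_size) * scale_fn(tr, f)
                plane += _render_plane((ny, nx), tr.centers[f], disc_r_px, amp)
            plane = gaussian_filter(plane, config.psf_sigma)
            if config.poisson_gain > 0:
                plane = rng.poisson(np.maximum(plane, 0.0) /
                                    config.poisson_gain) * config.poisson_gain
            if config.read_noise_sd > 0:
                plane = plane + rng.normal(0.0, config.read_noise_sd, plane.shape)
            movie[f, iz] = np.maximum(plane, 0.0)
    return movie


def render_timelapse(config: ImagingConfig, truths,
                     *, intensity_per_concentration: float = 1.0,
                     with_cells: bool = True) -> tuple[Timelapse, pd.DataFrame]:
    """Render a single-channel movie plus its ground-truth table.

    Vesicles are homogeneous spheres of intensity proportional to dye
    concentration, sectioned into z-planes, PSF-blurred, composited over
    cytoplasm/background and corrupted by Poisson and Gaussian read noise.
    """
    config.validate()
    _check_inside(config, truths)
    rng = np.random.default_rng(config.rng_seed)
    movie = _render_frames(config, truths,
                           lambda tr, f: intensity_per_concentration,
                           rng, with_cells)
    tl = Timelapse(movie, config.pixel_size, config.z_step,
                   config.frame_interval,
                   meta={"synthetic": True, "seed": config.rng_seed})
    return tl, _truth_table(config, truths)


def reporter_response(ph: float, pka: float = 4.7, hill: float = 1.0) -> float:
    """Fractional brightness of the pH-sensitive excitation channel.

    Monotone sigmoid in pH with midpoint at the reporter pKa; 0.5 exactly at
    the pKa, approaching 1 in alkaline and 0 in acidic media.
    """
    return 1.0 / (1.0 + 10.0 ** (hill * (pka - ph)))


def render_ph_pair(config: ImagingConfig, truths, *, pka: float = 4.7,
                   hill: float = 1.0, gain_515: float = 1.0,
                   gain_445: float = 1.0,
                   with_cells: bool = True) -> tuple[Timelapse, pd.DataFrame]:
    """Dual-excitation rendering of a pH reporter (ex515 sensitive, ex445 not).

    The truth table's ``ratio_truth`` column holds the noise-free
    515/445 ratio for unit gains, i.e. the reporter sigmoid at the frame pH.
    """
    config.validate()
    _check_inside(config, truths)
    if any(tr.ph is None for tr in truths):
        raise ValueError("per-frame pH required for dual-channel rendering")
    rng = np.random.default_rng(config.rng_seed)
    m515 = _render_frames(
        config, truths,
        lambda tr, f: gain_515 * reporter_response(tr.ph[f], pka, hill),
        rng, with_cells)
    m445 = _render_frames(config, truths, lambda tr, f: gain_445,
                          rng, with_cells)
    data = np.stack([m515, m445], axis=1)  # T x C x Z x Y x X
    tl = Timelapse(data, config.pixel_size, config.z_step,
                   config.frame_interval, channels=("ex515", "ex445"),
                   meta={"synthetic": True, "seed": config.rng_seed,
                         "pka": pka, "hill": hill})
    return tl, _truth_table(config, truths)


# ---------------------------------------------------------------------------
# scratch assay
# ---------------------------------------------------------------------------

def render_scratch_sequence(shape: tuple[int, int] = (500, 500), *,
                            n_frames: int = 13,
                            band: tuple[int, int] = (150, 370),
                            influx_rate: float = 5.0,
                            pixel_size: float = 0.55,
                            cell_sigma_px: float = 5.0,
                            cell_amplitude: float = 60.0,
                            background_level: float = 30.0,
                            texture_sd: float = 6.0,
                            read_noise_sd: float = 2.0,
                            seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Wound-healing frames: confluent textured field with a cleared band.

    Cells are bright Gaussian spots (size inside the 5-30 px detector band).
    From frame 1 on, new cells enter the band at a Poisson rate per frame and
    persist.  Returns (frames, truth) where truth lists cumulative entrants
    per frame and the band area; frame 0 has no cells inside the band.
    """
    ny, nx = shape
    x0, x1 = band
    if not (0 <= x0 < x1 <= nx):
        raise ValueError("band must lie inside the frame")
    if influx_rate < 0:
        raise ValueError("influx_rate must be >= 0")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:ny, 0:nx]

    def add_cell(img, cy, cx):
        img += cell_amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * cell_sigma_px ** 2))

    # confluent field outside the band
    outside = np.zeros((ny, nx))
    n_out = int(ny * nx / 900)
    for _ in range(n_out):
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, x0) if rng.random() < x0 / (x0 + nx - x1) \
            else rng.uniform(x1, nx)
        add_cell(outside, cy, cx)
    texture = gaussian_filter(rng.normal(0, texture_sd, (ny, nx)), 1.0)
    texture[:, x0:x1] = 0.0  # the freshly cleared band is smooth

    frames = np.empty((n_frames, ny, nx))
    entrants: list[tuple[float, float]] = []
    truth_rows = []
    cum = 0
    for f in range(n_frames):
        if f > 0:
            k = rng.poisson(influx_rate)
            for _ in range(k):
                # cells exclude each other: resample until clear of neighbours
                for _attempt in range(200):
                    p = (rng.uniform(cell_sigma_px * 2, ny - cell_sigma_px * 2),
                         rng.uniform(x0 + cell_sigma_px * 2,
                                     x1 - cell_sigma_px * 2))
                    if all(math.hypot(p[0] - q[0], p[1] - q[1])
                           > 3.0 * cell_sigma_px for q in entrants):
                        break
                entrants.append(p)
            cum += k
        img = background_level + outside + texture
        for cy, cx in entrants:
            add_cell(img, cy, cx)
        img = img + rng.normal(0, read_noise_sd, (ny, nx))
        frames[f] = np.maximum(img, 0.0)
        truth_rows.append({"frame": f, "cumulative_entrants": cum,
                           "band_area_px2": (x1 - x0) * ny,
                           "band_area_um2": (x1 - x0) * ny * pixel_size ** 2})
    return frames, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# model -> movie coupling
# ---------------------------------------------------------------------------

def simulate_then_render(scenario, config: ImagingConfig, *,
                         n_vesicles: int = 8, r0_px: float = 12.0,
                         max_step_px: float = 3.0, snr: float = 8.0,
                         with_ph: bool = False):
    """Run the vesicle model and render the predicted shrinkage as a movie.

    Radii follow the simulated volume fraction (radius ratio equals the cube
    root of the volume fraction); dye is conserved so intensity tracks the
    inverse volume.  ``snr`` sets the initial vesicle contrast over the
    cytoplasm in units of the cytoplasmic noise standard deviation.  With
    ``with_ph`` a dual-channel reporter movie is rendered using the
    simulated luminal pH.  Returns (timelapse, truth, trajectory).
    """
    from .vesicle_model import simulate

    traj = simulate(scenario)
    sample_t = np.arange(config.n_frames) * config.frame_interval
    sample_t = np.clip(sample_t, 0, traj.t[-1])
    vfrac = np.interp(sample_t, traj.t, traj.volume_fraction)
    ph = np.interp(sample_t, traj.t, traj.pH)
    rng = np.random.default_rng(config.rng_seed)
    truths = make_separated_truths(config, n_vesicles, r0_px=r0_px,
                                   max_step_px=max_step_px, rng=rng)
    level = config.background_level + config.cell_cytoplasm_level
    noise_sd = math.sqrt(level) + config.read_noise_sd
    conc0 = 1.0 / (4.0 / 3.0 * math.pi * (r0_px * config.pixel_size) ** 3)
    for tr in truths:
        tr.radii_px = r0_px * vfrac ** (1.0 / 3.0)
        tr.dye_amount = snr * noise_sd / conc0
        if with_ph:
            tr.ph = ph.copy()
    if with_ph:
        tl, truth = render_ph_pair(config, truths)
    else:
        tl, truth = render_timelapse(config, truths)
    tl.meta["scenario"] = scenario.name
    return tl, truth, traj
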