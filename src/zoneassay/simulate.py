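"""Synthetic exclusion-zone assay: time-lapse renders with known ground truth.

Emulates the raw data of an insert-based migration assay: a textured
confluent monolayer (polygonal cell mosaic with bright borders, the edge-rich
appearance of brightfield epithelial sheets) surrounding a smooth, darker
circular cell-free zone.  Over the series the front at radius

    r(t) = max(0, r0 - v * max(0, t - lag))

advances inward (v > 0, closure under migration promoters) or retreats
(v < 0, zone growth under inhibitors, where dying cells round up and detach
at the margin).  Optional nuisance terms exercise the measurement chain:
debris specks inside the zone, a lateral illumination gradient, and additive
Gaussian pixel noise.

Every frame's true mask (the disc of radius r(t)) and the derived true areas
and percentages form the ground-truth channel against which segmentation and
kinetics are validated.  All randomness flows from the single ``rng_seed``.

Treatment presets map the five assay conditions to signed front velocities
chosen so a default 5 mm zone reaches the characteristic 96 h endpoint
percentages (DMEM 88.8, FBS 78.1, EGF 48.9, colchicine 103.3, doxorubicin
110.7) after a 24 h response lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .segment import BinaryMask, RGBFrame
from .tracking import Track

__all__ = [
    "SimConfig",
    "GroundTruth",
    "WellSeries",
    "TREATMENT_PRESETS",
    "TREATMENT_CELL_SPEED_UM_PER_H",
    "preset_config",
    "render_frame",
    "simulate_timelapse",
    "simulate_tracks",
    "simulate_area_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic well.

    Distances in mm/um as named; times in hours; ``front_velocity_um_per_h``
    is signed (positive = closure).  ``lag_h`` delays the onset of front
    motion (0 disables it; treatment presets use 24 h, the delay before
    treated monolayers respond).  ``image_margin_mm`` is monolayer border
    around the zone on each side; it must keep the zone inside the frame.
    """

    zone_diameter_mm: float = 5.0
    pixel_scale_px_per_um: float = 0.3525
    frame_interval_h: float = 3.0
    duration_h: float = 96.0
    front_velocity_um_per_h: float = 0.0
    lag_h: float = 0.0
    texture_cell_diameter_um: float = 30.0
    texture_contrast: float = 0.6
    front_ramp_cell_diameters: float = 2.0
    debris_density_per_mm2: float = 2.0
    illumination_gradient: float = 0.1
    noise_sd: float = 2.0
    image_margin_mm: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.zone_diameter_mm > 0:
            raise ValueError("zone_diameter_mm must be > 0")
        if not self.pixel_scale_px_per_um > 0:
            raise ValueError("pixel_scale_px_per_um must be > 0")
        if not self.frame_interval_h > 0 or not self.duration_h >= 0:
            raise ValueError("frame_interval_h must be > 0 and duration_h >= 0")
        n_steps = self.duration_h / self.frame_interval_h
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                "duration_h must be an integer multiple of frame_interval_h"
            )
        if not self.texture_cell_diameter_um > 0:
            raise ValueError("texture_cell_diameter_um must be > 0")
        if not 0 <= self.texture_contrast <= 1:
            raise ValueError("texture_contrast must be in [0, 1]")
        if self.debris_density_per_mm2 < 0 or self.noise_sd < 0:
            raise ValueError("debris_density_per_mm2 and noise_sd must be >= 0")
        if not 0 <= self.illumination_gradient <= 1:
            raise ValueError("illumination_gradient must be in [0, 1]")
        if self.image_margin_mm < 0:
            raise ValueError("image_margin_mm must be >= 0")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        # the rendered frame must contain the full zone plus margin
        if self.image_size_px < self.zone_diameter_mm * 1000 * self.pixel_scale_px_per_um:
            raise ValueError("image does not contain the full zone")

    @property
    def zone_radius_um(self) -> float:
        return self.zone_diameter_mm * 1000.0 / 2.0

    @property
    def image_size_px(self) -> int:
        side_mm = self.zone_diameter_mm + 2.0 * self.image_margin_mm
        return int(round(side_mm * 1000.0 * self.pixel_scale_px_per_um))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.frame_interval_h)) + 1

    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h

    def front_radius_um(self, time_h: float) -> float:
        """True zone radius at time t (um): r0 - v*(t - lag), floored at 0."""
        moving = max(0.0, time_h - self.lag_h)
        return max(0.0, self.zone_radius_um - self.front_velocity_um_per_h * moving)


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel of a simulated series.

    Areas are pixel-count based (foreground pixels / scale^2), consistent
    with the calibration used by the measurement chain, so truth and
    measurement are directly comparable.  ``true_percent_area`` is
    normalised to the first frame (100 at t=0 by construction).
    """

    times_h: np.ndarray
    radius_um: np.ndarray
    true_area_mm2: np.ndarray
    true_percent_area: np.ndarray
    masks: tuple[BinaryMask, ...] = field(default=(), repr=False)
    true_tracks: tuple[Track, ...] = ()


class _Scene:
    """Precomputed static parts of a well render (texture, geometry)."""

    def __init__(self, config: SimConfig):
        self.config = config
        n = config.image_size_px
        scale = config.pixel_scale_px_per_um
        c = (n - 1) / 2.0
        y = (np.arange(n, dtype=np.float32) - c) / scale  # um from centre
        self.dist_um = np.hypot(y[:, None], y[None, :]).astype(np.float32)
        self.texture = self._render_texture()
        self.background = np.float32(70.0)  # smooth low-intensity zone floor
        # lateral illumination ramp, mean 1
        g = config.illumination_gradient
        ramp = 1.0 - g / 2.0 + g * (np.arange(n, dtype=np.float32) / max(n - 1, 1))
        self.illumination = ramp[None, :]

    def _render_texture(self) -> np.ndarray:
        """Seeded jittered-grid Voronoi mosaic with bright cell borders."""
        cfg = self.config
        n = cfg.image_size_px
        rng = np.random.default_rng([cfg.rng_seed, 1])
        s = cfg.texture_cell_diameter_um * cfg.pixel_scale_px_per_um  # px
        ncells = int(np.ceil(n / s)) + 2
        jitter = rng.uniform(-0.45, 0.45, size=(2, ncells, ncells)).astype(np.float32)
        # grid cell g = array index - 1 (one pad cell per side); each cell owns
        # exactly one seed strictly inside it, so a pixel's nearest seeds are
        # found in its 3x3 cell neighbourhood.
        base = np.arange(ncells, dtype=np.float32) - 1.0
        seed_y = (base[:, None] + 0.5 + jitter[0]) * s
        seed_x = (base[None, :] + 0.5 + jitter[1]) * s
        shade = rng.uniform(0.0, 1.0, size=(ncells, ncells)).astype(np.float32)

        coords = np.arange(n, dtype=np.float32)
        ci = np.minimum((coords / s).astype(np.intp) + 1, ncells - 2)
        d1 = np.full((n, n), np.inf, dtype=np.float32)
        d2 = np.full((n, n), np.inf, dtype=np.float32)
        sh = np.zeros((n, n), dtype=np.float32)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                # gather per-pixel candidate seed coordinates
                row = ci + di
                col = ci + dj
                cand_y = seed_y[row[:, None], col[None, :]]
                cand_x = seed_x[row[:, None], col[None, :]]
                d = (coords[:, None] - cand_y) ** 2 + (coords[None, :] - cand_x) ** 2
                closer = d < d1
                d2 = np.where(closer, d1, np.minimum(d2, d))
                sh = np.where(closer, shade[row[:, None], col[None, :]], sh)
                d1 = np.where(closer, d, d1)
        d1 = np.sqrt(d1)
        d2 = np.sqrt(d2)
        edge_width = max(1.5, 0.05 * s)  # px
        edge = np.exp(-(((d2 - d1) / edge_width) ** 2)).astype(np.float32)
        contrast = cfg.texture_contrast
        interior = 120.0 + 60.0 * contrast * (sh - 0.5)
        bright = 235.0
        tex = interior + (bright - interior) * (0.4 + 0.6 * contrast) * edge
        return tex.astype(np.float32)

    def truth_mask(self, time_h: float) -> np.ndarray:
        r = self.config.front_radius_um(time_h)
        if r <= 0:  # fully closed: no cell-free pixel, not even the centre
            return np.zeros_like(self.dist_um, dtype=bool)
        return self.dist_um <= r

    def render(self, time_h: float) -> np.ndarray:
        """Render the uint8 RGB frame at time t."""
        cfg = self.config
        r = cfg.front_radius_um(time_h)
        ramp_um = cfg.front_ramp_cell_diameters * cfg.texture_cell_diameter_um
        if ramp_um > 0:
            a = np.clip((self.dist_um - r) / ramp_um + 0.5, 0.0, 1.0)
            alpha = a * a * (3.0 - 2.0 * a)  # smoothstep centred on r(t)
        else:
            alpha = (self.dist_um > r).astype(np.float32)
        img = self.background + (self.texture - self.background) * alpha

        frame_key = int(round(time_h * 1000.0))
        if cfg.debris_density_per_mm2 > 0 and r > 0:
            rng = np.random.default_rng([cfg.rng_seed, 2, frame_key])
            zone_mm2 = math.pi * (r / 1000.0) ** 2
            n_debris = rng.poisson(cfg.debris_density_per_mm2 * zone_mm2)
            self._add_debris(img, rng, n_debris, r)
        img = img * self.illumination
        if cfg.noise_sd > 0:
            rng = np.random.default_rng([cfg.rng_seed, 3, frame_key])
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape).astype(np.float32)
        gray = np.clip(img, 0, 255).astype(np.uint8)
        return np.repeat(gray[:, :, None], 3, axis=2)

    def _add_debris(self, img: np.ndarray, rng: np.random.Generator, n_debris: int, r_um: float) -> None:
        """Stamp small bright Gaussian specks uniformly inside the zone."""
        cfg = self.config
        scale = cfg.pixel_scale_px_per_um
        n = img.shape[0]
        c = (n - 1) / 2.0
        sigma_px = max(1.0, 3.0 * scale)  # ~3 um specks, far below size filter
        half = int(math.ceil(4 * sigma_px))
        win = np.arange(-half, half + 1, dtype=np.float32)
        bump = np.exp(-(win[:, None] ** 2 + win[None, :] ** 2) / (2 * sigma_px**2))
        for _ in range(n_debris):
            rho = r_um * 0.95 * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            py = int(round(c + rho * math.cos(theta) * scale))
            px = int(round(c + rho * math.sin(theta) * scale))
            amp = rng.uniform(50.0, 90.0)
            y0, y1 = max(0, py - half), min(n, py + half + 1)
            x0, x1 = max(0, px - half), min(n, px + half + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            img[y0:y1, x0:x1] += amp * bump[
                y0 - (py - half) : y1 - (py - half),
                x0 - (px - half) : x1 - (px - half),
            ]


@dataclass
class WellSeries:
    """Lazily rendered time-lapse of one synthetic well."""

    config: SimConfig
    _scene: _Scene = field(repr=False)

    @property
    def times_h(self) -> np.ndarray:
        return self.config.times_h()

    def __len__(self) -> int:
        return self.config.n_frames

    def frame(self, index: int) -> RGBFrame:
        times = self.times_h
        if not 0 <= index < len(times):
            raise IndexError(f"frame index {index} out of range 0..{len(times) - 1}")
        return RGBFrame(
            self._scene.render(float(times[index])), self.config.pixel_scale_px_per_um
        )

    def __iter__(self) -> Iterator[RGBFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def save(self, directory: str | Path, well_id: str = "A1", write_masks: bool = False) -> list[Path]:
        """Write frames as 24-bit RGB TIFFs named ``<well>_t<index>.tif``.

        With ``write_masks``, truth masks are written alongside as bilevel
        TIFFs (``<well>_t<index>_truth.tif``).
        """
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i in range(len(self)):
            path = directory / f"{well_id}_t{i:03d}.tif"
            tifffile.imwrite(path, self.frame(i).pixels, photometric="rgb")
            if write_masks:
                mpath = directory / f"{well_id}_t{i:03d}_truth.tif"
                mask = self._scene.truth_mask(float(self.times_h[i]))
                tifffile.imwrite(mpath, mask)
            paths.append(path)
        return paths


def render_frame(config: SimConfig, time_h: float) -> tuple[RGBFrame, BinaryMask]:
    """Render one frame and its truth mask at an arbitrary in-series time."""
    if not 0 <= time_h <= config.duration_h:
        raise ValueError(f"time_h must be in [0, {config.duration_h}], got {time_h}")
    scene = _Scene(config)
    rgb = RGBFrame(scene.render(time_h), config.pixel_scale_px_per_um)
    mask = BinaryMask(scene.truth_mask(time_h), config.pixel_scale_px_per_um)
    return rgb, mask


def simulate_timelapse(config: SimConfig, keep_masks: bool = False) -> tuple[WellSeries, GroundTruth]:
    """Build the full series at t = 0, dt, ..., duration and its truth channel.

    Identical config (including seed) gives bit-identical pixel output.
    Truth areas are pixel counts of the truth masks divided by scale^2.
    """
    scene = _Scene(config)
    series = WellSeries(config, scene)
    times = config.times_h()
    scale = config.pixel_scale_px_per_um
    counts = np.empty(len(times))
    radii = np.empty(len(times))
    masks = []
    for i, t in enumerate(times):
        m = scene.truth_mask(float(t))
        counts[i] = m.sum()
        radii[i] = config.front_radius_um(float(t))
        if keep_masks:
            masks.append(BinaryMask(m, scale))
    area_mm2 = counts / scale**2 / 1e6
    if counts[0] == 0:
        raise ValueError("initial truth mask is empty; zone not rendered")
    percent = 100.0 * counts / counts[0]
    truth = GroundTruth(times, radii, area_mm2, percent, tuple(masks))
    return series, truth


def simulate_tracks(
    n_cells: int,
    speed_um_per_h: float,
    duration_h: float,
    interval_h: float,
    jitter_sd_um: float = 0.0,
    seed: int = 0,
    field_spacing_um: float = 100.0,
) -> list[Track]:
    """Ground-truth single-cell tracks: fixed random headings plus jitter.

    Each cell starts near a jittered grid site (spacing ``field_spacing_um``,
    keeping cells well separated), then advances ``speed * interval`` um per
    step along its own fixed heading with isotropic Gaussian positional
    jitter.  Positions are in um, times in hours.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if speed_um_per_h < 0:
        raise ValueError("speed_um_per_h must be >= 0")
    if interval_h <= 0:
        raise ValueError("interval_h must be > 0")
    if jitter_sd_um < 0:
        raise ValueError("jitter_sd_um must be >= 0")
    rng = np.random.default_rng([seed, 4])
    n_steps = int(round(duration_h / interval_h))
    times = np.arange(n_steps + 1) * interval_h
    side = int(math.ceil(math.sqrt(n_cells)))
    tracks = []
    for k in range(n_cells):
        gy, gx = divmod(k, side)
        start = np.array([gy, gx], dtype=float) * field_spacing_um
        start = start + rng.uniform(-0.2, 0.2, size=2) * field_spacing_um
        heading = rng.uniform(0, 2 * math.pi)
        step = speed_um_per_h * interval_h * np.array(
            [math.cos(heading), math.sin(heading)]
        )
        drift = start[None, :] + np.arange(n_steps + 1)[:, None] * step[None, :]
        noise = rng.normal(0.0, jitter_sd_um, size=(n_steps + 1, 2))
        xy = drift + noise
        tracks.append(Track(cell_id=f"cell{k:02d}", times_h=times.copy(), xy_um=xy))
    return tracks


# 96 h endpoint percent cell-free area characteristic of each treatment.
_PRESET_ENDPOINT_PERCENT = {
    "dmem": 88.8,
    "fbs": 78.1,
    "egf": 48.9,
    "colchicine": 103.3,
    "doxorubicin": 110.7,
}

#: Typical single-cell speeds (um/h) per treatment for track simulation.
TREATMENT_CELL_SPEED_UM_PER_H = {
    "dmem": 0.15,
    "fbs": 0.52,
    "egf": 0.69,
    "colchicine": 0.04,
    "doxorubicin": 0.05,
}

_PRESET_LAG_H = 24.0
_PRESET_DURATION_H = 96.0


def _preset_velocity(endpoint_percent: float, zone_radius_um: float = 2500.0) -> float:
    """Front velocity reaching the endpoint percent at 96 h after a 24 h lag.

    From percent = 100 * (r(T)/r0)^2 with r(T) = r0 - v*(T - lag).
    """
    ratio = math.sqrt(endpoint_percent / 100.0)
    return zone_radius_um * (1.0 - ratio) / (_PRESET_DURATION_H - _PRESET_LAG_H)


#: Treatment name -> (front_velocity_um_per_h, lag_h) for a 5 mm zone.
TREATMENT_PRESETS: dict[str, tuple[float, float]] = {
    name: (_preset_velocity(pct), _PRESET_LAG_H)
    for name, pct in _PRESET_ENDPOINT_PERCENT.items()
}


def preset_config(treatment: str, rng_seed: int = 0, **overrides) -> SimConfig:
    """SimConfig for one of the five treatment presets.

    The front velocity is derived from the preset's characteristic 96 h
    endpoint percentage for the *configured* zone size, so a scaled-down
    zone follows the same percent-area trajectory.
    """
    import dataclasses

    key = treatment.lower()
    if key not in TREATMENT_PRESETS:
        raise ValueError(
            f"unknown treatment {treatment!r}; choose from {sorted(TREATMENT_PRESETS)}"
        )
    kwargs = dict(lag_h=_PRESET_LAG_H, rng_seed=rng_seed)
    kwargs.update(overrides)
    base = SimConfig(**kwargs)
    v = _preset_velocity(_PRESET_ENDPOINT_PERCENT[key], base.zone_radius_um)
    return dataclasses.replace(base, front_velocity_um_per_h=v)


def simulate_area_table(
    treatments: Sequence[str],
    n_replicates: int = 3,
    times_h: Sequence[float] = (0.0, 24.0, 48.0, 72.0, 96.0),
    area_noise_cv: float = 0.04,
    seed: int = 0,
    zone_radius_um: float = 2500.0,
) -> "pd.DataFrame":
    """Per-well area series from the radial truth model, without rendering.

    Emulates a replicated plate for statistical analysis: each well's area is
    pi*r(t)^2 under its treatment's preset front kinetics, perturbed by
    multiplicative measurement noise with coefficient of variation
    ``area_noise_cv`` (matching the few-percent replicate scatter typical of
    the assay).  Returns a long-format DataFrame (well_id, treatment, time_h,
    area_mm2).
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 5])
    rows = []
    for treatment in treatments:
        v, lag = TREATMENT_PRESETS[treatment.lower()]
        for rep in range(n_replicates):
            well = f"{treatment}-{rep + 1}"
            for t in times_h:
                r = max(0.0, zone_radius_um - v * max(0.0, t - lag))
                area_mm2 = math.pi * (r / 1000.0) ** 2
                area_mm2 *= 1.0 + rng.normal(0.0, area_noise_cv)
                rows.append(
                    {
                        "well_id": well,
                        "treatment": treatment,
                        "time_h": float(t),
                        "area_mm2": area_mm2,
                    }
                )
    return pd.DataFrame(rows)
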