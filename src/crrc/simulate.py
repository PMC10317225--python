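"""Synthetic paired transmitted-light / fluorescence time-lapse generator.

The generator emulates a monolayer of non-overlapping motile cells whose
intracellular fluorescence decays exponentially, imaged with alternating
transmitted-light and fluorescence acquisitions: the transmitted frame of
pair *j* is taken at ``j * t2`` and the matching fluorescence frame ``t1``
seconds later (``t1 << t2``).  Each cell carries its own efflux rate
constant ``k`` (min^-1), radius (um) and migration speed (um/h); the full
ground truth (masks, centroids, rate constants) is returned alongside the
rendered stacks so every downstream stage can be validated.

Units: lengths in micrometres, times in seconds at rest, speeds in um/h
and rate constants in min^-1 at the interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import optimize, stats

__all__ = [
    "SpeedDistribution",
    "SimulationConfig",
    "ImageStack",
    "GroundTruth",
    "SimulationResult",
    "sample_speeds",
    "step_positions",
    "render_frames",
    "simulate_timelapse",
    "write_ground_truth",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6744897...


class ConfigurationError(ValueError):
    """Raised for physically impossible or inconsistent generator settings."""


@dataclass(frozen=True)
class SpeedDistribution:
    """Log-normal migration-speed distribution parameterized by its mode and IQR.

    Cell speeds are right-skewed and strictly positive; a log-normal is the
    simplest two-parameter family matching a reported mode and interquartile
    range.  Draws are truncated at ``max_speed`` (rejection sampling).

    mode_um_h : peak of the density, um/h
    iqr_um_h  : interquartile range, um/h; 0 collapses to a point mass at the mode
    max_um_h  : hard upper truncation, um/h
    """

    mode_um_h: float = 150.0
    iqr_um_h: float = 40.0
    max_um_h: float = 400.0

    def __post_init__(self) -> None:
        if self.iqr_um_h == 0:
            # point mass (degenerate limit); mode 0 = immobile population
            if self.mode_um_h < 0 or self.max_um_h < self.mode_um_h:
                raise ConfigurationError("point-mass speed needs 0 <= mode <= max")
            return
        if self.mode_um_h <= 0 or self.iqr_um_h < 0:
            raise ConfigurationError(
                f"speed distribution needs mode > 0 and IQR >= 0, got "
                f"mode={self.mode_um_h}, IQR={self.iqr_um_h}"
            )
        if self.max_um_h <= self.mode_um_h:
            raise ConfigurationError("max speed must exceed the mode")

    def lognorm_params(self) -> tuple[float, float]:
        """Return (mu, sigma) of ln(speed) matching the configured mode and IQR.

        mode = exp(mu - sigma^2) and IQR = exp(mu) * 2 sinh(sigma * z75) give
        IQR(sigma) = mode * exp(sigma^2) * 2 sinh(sigma * z75), monotone in
        sigma, solved by bisection.
        """
        if self.iqr_um_h == 0:
            return np.log(self.mode_um_h), 0.0

        def iqr_of(sigma: float) -> float:
            return self.mode_um_h * np.exp(sigma**2) * 2.0 * np.sinh(sigma * _Z75)

        sigma = optimize.brentq(lambda s: iqr_of(s) - self.iqr_um_h, 1e-12, 5.0)
        mu = np.log(self.mode_um_h) + sigma**2
        return mu, sigma

    def frozen(self) -> stats._distn_infrastructure.rv_frozen:
        """The untruncated scipy log-normal with these parameters."""
        mu, sigma = self.lognorm_params()
        return stats.lognorm(s=max(sigma, 1e-300), scale=np.exp(mu))


@dataclass(frozen=True)
class KDistribution:
    """Log-normal distribution of per-cell efflux rate constants (min^-1)."""

    median_per_min: float = 0.05
    sigma_log: float = 0.4

    def __post_init__(self) -> None:
        if self.median_per_min <= 0 or self.sigma_log < 0:
            raise ConfigurationError("k distribution needs median > 0 and sigma >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of one synthetic CRRC time-lapse.

    Timing follows the alternating acquisition scheme: pairs every
    ``frame_interval_s`` (t2) with the fluorescence image ``channel_gap_s``
    (t1) after its transmitted partner.  Defaults reproduce a one-hour
    acquisition at one pair per minute of ~200 motile ovarian-cancer-like
    cells (diameter 13 +/- 3 um, speed mode 150 um/h, IQR 40 um/h, fastest
    400 um/h) in a 512 x 512 px field at 0.65 um/px.
    """

    n_cells: int = 200
    field_size: tuple[int, int] = (512, 512)  # (rows, cols), px
    pixel_size: float = 0.65  # um/px
    n_frames: int = 61
    frame_interval_s: float = 60.0  # t2
    channel_gap_s: float = 3.0  # t1
    cell_radius_mean_um: float = 6.5
    cell_radius_sd_um: float = 1.5
    cell_radius_clip_um: tuple[float, float] = (3.0, 12.0)
    speed: SpeedDistribution = field(default_factory=SpeedDistribution)
    motion_persistence: float = 0.9  # 1 = ballistic, 0 = uncorrelated walk
    k: KDistribution = field(default_factory=KDistribution)
    initial_intensity: float = 600.0  # per-pixel fluorescence amplitude A, a.u.
    intensity_offset: float = 20.0  # residual per-pixel fluorescence y0, a.u.
    tl_foreground: float = 300.0  # transmitted-light cell brightness over background
    background_level: float = 100.0  # both channels, a.u.
    noise_sd: float = 30.0  # additive Gaussian read noise, a.u.
    poisson_scale: float = 0.0  # photons per a.u.; 0 disables shot noise
    min_separation_um: float = 2.0  # extra center-distance margin beyond touching
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if not self.channel_gap_s < self.frame_interval_s:
            raise ConfigurationError("channel gap t1 must be shorter than frame interval t2")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if not 0.0 <= self.motion_persistence <= 1.0:
            raise ConfigurationError("motion_persistence must lie in [0, 1]")
        field_um = min(self.field_size) * self.pixel_size
        if 2 * self.cell_radius_clip_um[1] >= field_um:
            raise ConfigurationError("cells larger than the field")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_size[0] * self.pixel_size, self.field_size[1] * self.pixel_size)


@dataclass
class ImageStack:
    """One channel of a time-lapse: frames, per-frame timestamps, pixel size.

    frames      : float or integer array, shape (n_frames, rows, cols), >= 0
    channel     : "transmitted" or "fluorescence"
    timestamps  : seconds from efflux initiation, strictly increasing
    pixel_size  : um/px
    """

    frames: np.ndarray
    channel: str
    timestamps: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (frame, row, col)")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GroundTruth:
    """Per-cell truth of one simulation.

    cells  : DataFrame (cell_id, k_per_min, radius_um, speed_um_per_h,
             amplitude, offset) — speed is the configured draw, not the
             realized track speed.
    tracks : DataFrame (cell_id, frame, row_um, col_um, row_fl_um, col_fl_um)
             — centroids at the transmitted and fluorescence acquisitions.
    label_masks : uint16 array (n_frames, rows, cols); label = cell_id + 1,
             rendered at the transmitted-frame positions (pixel centers
             inside the true circle).
    """

    cells: pd.DataFrame
    tracks: pd.DataFrame
    label_masks: np.ndarray

    def centroids_px(self, frame: int, pixel_size: float, channel: str = "transmitted") -> np.ndarray:
        sub = self.tracks[self.tracks["frame"] == frame].sort_values("cell_id")
        cols = ["row_um", "col_um"] if channel == "transmitted" else ["row_fl_um", "col_fl_um"]
        return sub[cols].to_numpy() / pixel_size


@dataclass
class SimulationResult:
    transmitted: ImageStack
    fluorescence: ImageStack
    ground_truth: GroundTruth
    config: SimulationConfig


def sample_speeds(speed: SpeedDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` migration speeds (um/h) from the truncated log-normal.

    Rejection sampling against the ``max_um_h`` cutoff; with the default
    parameters the excluded tail mass is ~1e-6, so this costs one pass.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if speed.iqr_um_h == 0:
        return np.full(n, speed.mode_um_h)
    dist = speed.frozen()
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = dist.rvs(size=2 * (n - filled) + 16, random_state=rng)
        keep = draws[draws <= speed.max_um_h]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (single bounce suffices for small steps)."""
    pos = np.where(pos < lo, 2 * lo - pos, pos)
    pos = np.where(pos > hi, 2 * hi - pos, pos)
    return np.clip(pos, lo, hi)


def step_positions(
    positions: np.ndarray,
    headings: np.ndarray,
    speeds: np.ndarray,
    persistence: float,
    dt: float,
    field_um: tuple[float, float],
    rng: np.random.Generator,
    radii: np.ndarray | None = None,
    min_separation: float = 0.0,
    max_attempts: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance cells one step of a persistent random walk with reflecting walls.

    Each cell turns by ``(1 - persistence) * Uniform(-pi, pi)`` and advances
    ``speed * dt`` along its new heading.  At persistence 1 the walk is
    ballistic; at 0 successive directions are uncorrelated, giving the plain
    2-D random walk MSD of n * (speed * dt)^2.  A step that would bring two
    cell centers closer than the sum of their radii (plus ``min_separation``)
    is rejected and re-drawn with a fresh uniform heading, up to
    ``max_attempts`` times; if every attempt collides the cell stays put.
    Cells are updated sequentially, so collision checks see neighbours that
    have already moved this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = len(positions)
    pos = np.array(positions, dtype=float)
    hdg = np.array(headings, dtype=float)
    step_len = np.asarray(speeds, dtype=float) * dt / 3600.0  # um/h * s -> um
    if radii is None:
        radii = np.zeros(n)
    lo = np.asarray(radii)[:, None] * np.ones((n, 2))
    hi = np.asarray(field_um)[None, :] - lo

    turns = (1.0 - persistence) * rng.uniform(-np.pi, np.pi, size=n)
    for i in range(n):
        theta = hdg[i] + turns[i]
        for attempt in range(max_attempts):
            direction = np.array([np.cos(theta), np.sin(theta)])
            cand = pos[i] + step_len[i] * direction
            # specular bounce: flip the heading component along any crossed wall
            flip = (cand < lo[i]) | (cand > hi[i])
            if flip.any():
                direction = np.where(flip, -direction, direction)
                theta = float(np.arctan2(direction[1], direction[0]))
            cand = _reflect(cand, lo[i], hi[i])
            if n == 1:
                ok = True
            else:
                d = np.hypot(*(pos - cand[None, :]).T)
                d[i] = np.inf
                ok = bool(np.all(d > radii + radii[i] + min_separation))
            if ok:
                pos[i] = cand
                hdg[i] = theta
                break
            theta = rng.uniform(-np.pi, np.pi)  # reject the offending step, try anew
        # all attempts collided: cell stays, heading unchanged
    return pos, hdg


def _place_cells(config: SimulationConfig, radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping initial centers, fully inside the field."""
    n = len(radii)
    field = np.asarray(config.field_um)
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(20000):
            cand = rng.uniform(radii[i], field - radii[i])
            if i == 0:
                pos[i] = cand
                break
            d = np.hypot(*(pos[:i] - cand[None, :]).T)
            if np.all(d > radii[:i] + radii[i] + config.min_separation_um):
                pos[i] = cand
                break
        else:
            raise ConfigurationError(
                f"could not place {n} non-overlapping cells in a "
                f"{field[0]:.0f} x {field[1]:.0f} um field"
            )
    return pos


def _disk_weights(
    shape: tuple[int, int], centers_px: np.ndarray, radii_px: np.ndarray
) -> list[tuple[tuple[slice, slice], np.ndarray]]:
    """Anti-aliased disk footprints: per-pixel coverage weights in [0, 1].

    Coverage is approximated by the linear ramp clip(r + 1/2 - rho, 0, 1) in
    the pixel-center distance rho; the total weight of a disk is
    pi r^2 + pi/12 in the continuum limit, i.e. < 1% area error for r >= 3 px.
    """
    out = []
    for (cr, cc), r in zip(centers_px, radii_px):
        r0 = max(int(np.floor(cr - r - 1)), 0)
        r1 = min(int(np.ceil(cr + r + 2)), shape[0])
        c0 = max(int(np.floor(cc - r - 1)), 0)
        c1 = min(int(np.ceil(cc + r + 2)), shape[1])
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        rho = np.hypot(rows - cr, cols - cc)
        w = np.clip(r + 0.5 - rho, 0.0, 1.0)
        out.append(((slice(r0, r1), slice(c0, c1)), w))
    return out


def render_frames(
    config: SimulationConfig,
    positions_tl: np.ndarray,
    positions_fl: np.ndarray,
    radii: np.ndarray,
    k_per_min: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ImageStack, ImageStack]:
    """Render both channels from per-frame cell states.

    positions_tl / positions_fl : (n_frames, n_cells, 2) centroids in um at
    the transmitted and fluorescence acquisition times.  The fluorescence
    per-pixel intensity of cell i at time t is
    ``A * exp(-k_i * t) + y0`` (t in minutes, k in min^-1), on top of the
    common background; the transmitted channel renders constant-brightness
    disks.  Gaussian read noise (and optional Poisson shot noise) is added
    per pixel; frames are clipped at zero.
    """
    if positions_tl.shape[0] != config.n_frames:
        raise ValueError("cell states must cover all frames")
    if np.any(2 * radii >= min(config.field_um)):
        raise ConfigurationError("cells larger than field")
    shape = config.field_size
    px = config.pixel_size
    t_tl = np.arange(config.n_frames) * config.frame_interval_s
    t_fl = t_tl + config.channel_gap_s

    tl = np.full((config.n_frames,) + shape, config.background_level, dtype=float)
    fl = np.full_like(tl, config.background_level)
    radii_px = radii / px
    for j in range(config.n_frames):
        decay = config.initial_intensity * np.exp(-k_per_min * t_fl[j] / 60.0) + config.intensity_offset
        for (box, w) in _disk_weights(shape, positions_tl[j] / px, radii_px):
            tl[j][box] += config.tl_foreground * w
        for amp, (box, w) in zip(decay, _disk_weights(shape, positions_fl[j] / px, radii_px)):
            fl[j][box] += amp * w

    for arr in (tl, fl):
        if config.poisson_scale > 0:
            arr[:] = rng.poisson(np.clip(arr, 0, None) * config.poisson_scale) / config.poisson_scale
        if config.noise_sd > 0:
            arr += rng.normal(0.0, config.noise_sd, size=arr.shape)
        np.clip(arr, 0.0, None, out=arr)

    return (
        ImageStack(tl, "transmitted", t_tl, px),
        ImageStack(fl, "fluorescence", t_fl, px),
    )


def _true_label_masks(config: SimulationConfig, positions_tl: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Ground-truth label masks: pixel centers inside the true circle; label = cell_id + 1."""
    masks = np.zeros((config.n_frames,) + config.field_size, dtype=np.uint16)
    px = config.pixel_size
    for j in range(config.n_frames):
        for i, (box, w) in enumerate(_disk_weights(config.field_size, positions_tl[j] / px, radii / px)):
            view = masks[j][box]
            view[w >= 0.5] = i + 1
    return masks


def simulate_timelapse(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulationResult:
    """Run the full generator: draw cells, move them, render both channels.

    Deterministic given (config, config.rng_seed); an explicit ``rng``
    overrides the seeded one.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n = config.n_cells
    lo_r, hi_r = config.cell_radius_clip_um
    radii = np.clip(rng.normal(config.cell_radius_mean_um, config.cell_radius_sd_um, n), lo_r, hi_r)
    speeds = sample_speeds(config.speed, n, rng)
    k = stats.lognorm(s=max(config.k.sigma_log, 1e-300), scale=config.k.median_per_min).rvs(
        size=n, random_state=rng
    )
    headings = rng.uniform(-np.pi, np.pi, n)
    pos = _place_cells(config, radii, rng)

    positions_tl = np.empty((config.n_frames, n, 2))
    positions_fl = np.empty_like(positions_tl)
    fl_step = speeds * config.channel_gap_s / 3600.0
    field = np.asarray(config.field_um)
    for j in range(config.n_frames):
        positions_tl[j] = pos
        drift = fl_step[:, None] * np.stack([np.cos(headings), np.sin(headings)], axis=1)
        positions_fl[j] = np.clip(pos + drift, radii[:, None], field[None, :] - radii[:, None])
        if j < config.n_frames - 1:
            pos, headings = step_positions(
                pos,
                headings,
                speeds,
                config.motion_persistence,
                config.frame_interval_s,
                config.field_um,
                rng,
                radii=radii,
                min_separation=config.min_separation_um,
            )

    tl_stack, fl_stack = render_frames(config, positions_tl, positions_fl, radii, k, rng)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "k_per_min": k,
            "radius_um": radii,
            "speed_um_per_h": speeds,
            "amplitude": config.initial_intensity,
            "offset": config.intensity_offset,
        }
    )
    frames_idx = np.repeat(np.arange(config.n_frames), n)
    tracks = pd.DataFrame(
        {
            "cell_id": np.tile(np.arange(n), config.n_frames),
            "frame": frames_idx,
            "row_um": positions_tl[:, :, 0].ravel(),
            "col_um": positions_tl[:, :, 1].ravel(),
            "row_fl_um": positions_fl[:, :, 0].ravel(),
            "col_fl_um": positions_fl[:, :, 1].ravel(),
        }
    )
    gt = GroundTruth(cells=cells, tracks=tracks, label_masks=_true_label_masks(config, positions_tl, radii))
    return SimulationResult(tl_stack, fl_stack, gt, config)


_SCHEMA_HEADER = "# crrc schema v1\n"


def write_ground_truth(gt: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Persist ground truth as CSV tables plus a multi-page label-mask TIFF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "ground_truth_cells.csv",
        "tracks": outdir / "ground_truth_tracks.csv",
        "masks": outdir / "ground_truth_masks.tif",
    }
    for key, df in (("cells", gt.cells), ("tracks", gt.tracks)):
        with open(paths[key], "w") as fh:
            fh.write(_SCHEMA_HEADER)
            df.to_csv(fh, index=False)
    tifffile.imwrite(paths["masks"], gt.label_masks, photometric="minisblack")
    return paths


def read_ground_truth(outdir: str | Path) -> GroundTruth:
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "ground_truth_cells.csv", comment="#")
    tracks = pd.read_csv(outdir / "ground_truth_tracks.csv", comment="#")
    masks = tifffile.imread(outdir / "ground_truth_masks.tif")
    if masks.ndim == 2:
        masks = masks[None, ...]
    return GroundTruth(cells=cells, tracks=tracks, label_masks=masks)
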