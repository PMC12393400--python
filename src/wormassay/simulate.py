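"""Seeded synthetic-data generators for every stage of the assay pipeline.

The chemotaxis generator produces worm tracks in the dialect of a
video-tracker export (per-frame positions with detection gaps) by running a
run-and-tumble walk on a predicted salt field.  Gradient climbing follows
the pirouette (klinokinesis) mechanism: the worm's reorientation probability
drops while the concentration it experiences is rising, so runs up the
gradient last longer than runs down it.  Per frame of length ``dt`` the
pirouette probability is

    p = base_rate * dt * max(0, 1 - beta * dC/dt_hat)

where ``dC/dt_hat`` (mM/s) is the worm's exponentially smoothed rate of
concentration change and ``beta`` (s/mM) the chemotaxis gain; ``beta = 0``
gives an unbiased walk.  Between pirouettes the heading diffuses with
Gaussian noise, and the plate wall reflects.

Every generator draws from a worm-specific child stream spawned from the
run seed, so a worm's trajectory is reproducible and independent of how
many other worms are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gradient import ConcentrationField

__all__ = [
    "WormParams",
    "SimConfig",
    "BendSeries",
    "ExpressionSpec",
    "simulate_chemotaxis_tracks",
    "simulate_bend_series",
    "simulate_roaming_track",
    "simulate_lawn_occupancy",
    "simulate_expression_table",
]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_mm", "y_mm", "detected"]


@dataclass(frozen=True)
class WormParams:
    """Locomotion parameters of the run-and-tumble walker.

    Defaults are typical of an adult hermaphrodite crawling on food-free
    agar: ~0.15 mm/s forward speed, a pirouette every several seconds, and
    gradual heading drift between pirouettes.
    """

    speed_mm_s: float = 0.15
    heading_noise_rad_sqrt_s: float = 0.2
    base_pirouette_rate_s: float = 0.12
    chemotaxis_gain_beta: float = 0.0
    sensory_timescale_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.speed_mm_s > 0:
            raise ValueError("speed_mm_s must be positive")
        for name in (
            "heading_noise_rad_sqrt_s",
            "base_pirouette_rate_s",
            "chemotaxis_gain_beta",
            "sensory_timescale_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Recording geometry and missingness model for a simulated assay.

    The standard chemotaxis recording is 7 minutes at 3.75 fps with all
    worms released from a buffer drop at the plate center.  Detection gaps
    model tracker dropouts (worms intersecting or leaving the camera field):
    a gap starts at any frame with ``gap_probability_per_frame`` and lasts a
    geometric number of frames with the given mean; the track id is retained
    across the gap (re-detection resumes the same id).
    """

    n_worms: int = 8
    duration_s: float = 420.0
    frame_rate_fps: float = 3.75
    start_xy_mm: tuple[float, float] = (0.0, 0.0)
    rng_seed: int = 0
    gap_probability_per_frame: float = 0.0
    mean_gap_length_frames: float = 8.0

    def __post_init__(self) -> None:
        if self.n_worms < 1:
            raise ValueError("n_worms must be at least 1")
        if not 0.0 <= self.gap_probability_per_frame <= 1.0:
            raise ValueError("gap_probability_per_frame must be in [0, 1]")
        if self.mean_gap_length_frames < 1:
            raise ValueError("mean_gap_length_frames must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_fps))


def _worm_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_chemotaxis_tracks(
    config: SimConfig, worms: WormParams, field: ConcentrationField
) -> pd.DataFrame:
    """Simulate ``config.n_worms`` run-and-tumble tracks on a salt field.

    Returns a track table (columns ``track_id, frame, time_s, x_mm, y_mm,
    detected``) sorted by (track_id, frame); undetected frames carry NaN
    coordinates, mimicking the tracker export.
    """
    radius = field.plate_radius_mm
    start = np.asarray(config.start_xy_mm, dtype=float)
    if math.hypot(*start) > radius:
        raise ValueError("start position lies outside the plate")
    grid_extent = min(
        abs(field.x_mm[0]), field.x_mm[-1], abs(field.y_mm[0]), field.y_mm[-1]
    )
    if grid_extent < radius:
        raise ValueError("concentration field does not cover the plate")

    n, n_frames = config.n_worms, config.n_frames
    dt = 1.0 / config.frame_rate_fps
    streams = _worm_streams(config.rng_seed, n)

    # Pre-draw each worm's randomness from its own stream so trajectories
    # are reproducible per worm regardless of n_worms or beta.
    noise = np.empty((n, n_frames))
    tumble_u = np.empty((n, n_frames))
    tumble_angle = np.empty((n, n_frames))
    heading0 = np.empty(n)
    gap_u = np.empty((n, n_frames))
    gap_len = np.empty((n, n_frames))
    for i, rng in enumerate(streams):
        heading0[i] = rng.uniform(0.0, 2.0 * math.pi)
        noise[i] = rng.standard_normal(n_frames)
        tumble_u[i] = rng.uniform(size=n_frames)
        tumble_angle[i] = rng.uniform(0.0, 2.0 * math.pi, size=n_frames)
        gap_u[i] = rng.uniform(size=n_frames)
        gap_len[i] = rng.geometric(1.0 / config.mean_gap_length_frames, size=n_frames)

    interp = field.interpolator()
    pos = np.tile(start, (n, 1))
    heading = heading0.copy()
    smoothed = np.asarray(interp(pos), dtype=float)
    tau = max(worms.sensory_timescale_s, dt)

    xs = np.empty((n, n_frames))
    ys = np.empty((n, n_frames))
    xs[:, 0], ys[:, 0] = pos[:, 0], pos[:, 1]
    sigma = worms.heading_noise_rad_sqrt_s * math.sqrt(dt)

    for k in range(1, n_frames):
        conc = np.asarray(interp(pos), dtype=float)
        dcdt = (conc - smoothed) / tau
        smoothed += (dt / tau) * (conc - smoothed)
        p_tumble = np.clip(
            worms.base_pirouette_rate_s
            * dt
            * np.maximum(0.0, 1.0 - worms.chemotaxis_gain_beta * dcdt),
            0.0,
            1.0,
        )
        tumbling = tumble_u[:, k] < p_tumble
        heading = np.where(tumbling, tumble_angle[:, k], heading + sigma * noise[:, k])
        pos = pos + worms.speed_mm_s * dt * np.column_stack(
            (np.cos(heading), np.sin(heading))
        )
        # reflect at the plate wall: fold the radius and bounce the heading
        # off the local tangent (one reflection suffices; a step is << radius)
        r = np.hypot(pos[:, 0], pos[:, 1])
        out = r > radius
        if np.any(out):
            phi = np.arctan2(pos[out, 1], pos[out, 0])
            r_new = 2.0 * radius - r[out]
            pos[out, 0] = r_new * np.cos(phi)
            pos[out, 1] = r_new * np.sin(phi)
            heading_out = heading[out]
            heading = heading.copy()
            heading[out] = np.pi + 2.0 * phi - heading_out
        xs[:, k], ys[:, k] = pos[:, 0], pos[:, 1]

    detected = np.ones((n, n_frames), dtype=bool)
    if config.gap_probability_per_frame > 0:
        for i in range(n):
            starts = np.flatnonzero(gap_u[i, 1:] < config.gap_probability_per_frame) + 1
            for s in starts:
                detected[i, s : s + int(gap_len[i, s])] = False

    frames = np.arange(n_frames)
    tables = []
    for i in range(n):
        x = np.where(detected[i], xs[i], np.nan)
        y = np.where(detected[i], ys[i], np.nan)
        tables.append(
            pd.DataFrame(
                {
                    "track_id": i,
                    "frame": frames,
                    "time_s": frames * dt,
                    "x_mm": x,
                    "y_mm": y,
                    "detected": detected[i],
                }
            )
        )
    out_df = pd.concat(tables, ignore_index=True)
    return out_df.sort_values(["track_id", "frame"], ignore_index=True)


@dataclass(frozen=True)
class BendSeries:
    """Uniformly sampled signed midbody bend angle (rad) of a swimming worm."""

    time_s: np.ndarray
    angle_rad: np.ndarray

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.angle_rad):
            raise ValueError("time and angle arrays must have equal length")


def simulate_bend_series(
    frequency_hz: float,
    noise_sd_rad: float = 0.0,
    duration_s: float = 60.0,
    rate_fps: float = 30.0,
    seed: int = 0,
    amplitude_rad: float = 0.7,
) -> BendSeries:
    """Sinusoidal midbody bend angle plus Gaussian sampling noise.

    A swimming worm alternates its midbody bend at roughly 1 Hz, giving two
    direction reversals (thrashes) per cycle.
    """
    if frequency_hz < 0:
        raise ValueError("frequency_hz must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * rate_fps))) / rate_fps
    angle = amplitude_rad * np.sin(2.0 * math.pi * frequency_hz * t)
    if noise_sd_rad > 0:
        angle = angle + rng.normal(0.0, noise_sd_rad, size=t.shape)
    return BendSeries(time_s=t, angle_rad=angle)


def simulate_roaming_track(
    mode: str,
    duration_s: float = 16 * 3600.0,
    dt_s: float = 10.0,
    step_mm: float | None = None,
    seed: int = 0,
    arena_radius_mm: float = 25.0,
) -> pd.DataFrame:
    """Long-duration track for the roaming assay.

    ``roamer`` mode is persistent, nearly ballistic exploration (many grid
    squares); ``dweller`` mode is localized wandering near the start.  Both
    bounce off the arena wall.  ``step_mm`` overrides the per-frame step
    length (a dweller with step 0 never leaves its starting square).
    """
    if mode not in ("roamer", "dweller"):
        raise ValueError("mode must be 'roamer' or 'dweller'")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / dt_s))
    if mode == "roamer":
        step = 0.8 if step_mm is None else step_mm
        turn_sd = 0.15
    else:
        step = 0.05 if step_mm is None else step_mm
        turn_sd = 2.5
    heading = rng.uniform(0, 2 * math.pi)
    pos = np.zeros(2)
    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    for k in range(n_frames):
        xs[k], ys[k] = pos
        heading += rng.normal(0.0, turn_sd)
        cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
        if np.hypot(*cand) > arena_radius_mm:
            heading += math.pi
            cand = pos
        pos = cand
    frames = np.arange(n_frames)
    return pd.DataFrame(
        {
            "track_id": 0,
            "frame": frames,
            "time_s": frames * dt_s,
            "x_mm": xs,
            "y_mm": ys,
            "detected": True,
        }
    )


def simulate_lawn_occupancy(
    n_worms: int = 15,
    leave_rate_per_min: float = 0.002,
    return_rate_per_min: float = 0.02,
    duration_h: float = 20.0,
    frames_per_min: float = 1.0,
    seed: int = 0,
    start_outside: bool = False,
) -> np.ndarray:
    """Two-state (inside/outside lawn) Markov chain per worm.

    Returns a boolean matrix of shape (n_frames, n_worms); True marks a worm
    outside the bacterial lawn at that frame.  The standard recording is 20 h
    at 1 frame/min.
    """
    if n_worms < 1:
        raise ValueError("n_worms must be positive")
    if leave_rate_per_min < 0 or return_rate_per_min < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_h * 60.0 * frames_per_min))
    dt_min = 1.0 / frames_per_min
    p_leave = 1.0 - math.exp(-leave_rate_per_min * dt_min)
    p_return = 1.0 - math.exp(-return_rate_per_min * dt_min)
    outside = np.empty((n_frames, n_worms), dtype=bool)
    state = np.full(n_worms, start_outside)
    for k in range(n_frames):
        outside[k] = state
        u = rng.uniform(size=n_worms)
        state = np.where(state, u >= p_return, u < p_leave)
    return outside


@dataclass(frozen=True)
class ExpressionSpec:
    """Recipe for a synthetic per-neuron expression table.

    ``explicit`` assignments (neuron name -> set of expressed loci) are
    honoured exactly; ``n_background`` extra neurons each express locus L
    independently with probability ``background_probabilities[L]``.
    """

    loci: tuple[str, ...]
    explicit: dict = field(default_factory=dict)
    n_background: int = 0
    background_probabilities: dict = field(default_factory=dict)
    categories: tuple[str, ...] = ("sensory", "interneuron", "motor")
    regions: tuple[str, ...] = ("head", "midbody", "tail", "pharynx")


def simulate_expression_table(spec: ExpressionSpec, seed: int = 0) -> pd.DataFrame:
    """Generate an expression table (neuron, class, category, region, loci).

    Explicit entries may be either a set of loci or a dict with keys
    ``loci``, ``category``, ``region``; background neurons get random
    category/region labels and independent locus expression.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, entry in spec.explicit.items():
        if isinstance(entry, dict):
            loci = sorted(entry["loci"])
            cat = entry.get("category", "interneuron")
            region = entry.get("region", "head")
        else:
            loci = sorted(entry)
            cat, region = "interneuron", "head"
        rows.append(
            {
                "neuron": name,
                "class": name.rstrip("LR0123456789") or name,
                "category": cat,
                "region": region,
                "loci": ";".join(loci),
            }
        )
    for i in range(spec.n_background):
        expressed = [
            locus
            for locus in spec.loci
            if rng.uniform() < spec.background_probabilities.get(locus, 0.0)
        ]
        rows.append(
            {
                "neuron": f"BG{i:03d}",
                "class": f"BG{i:03d}",
                "category": spec.categories[int(rng.integers(len(spec.categories)))],
                "region": spec.regions[int(rng.integers(len(spec.regions)))],
                "loci": ";".join(expressed),
            }
        )
    return pd.DataFrame(rows, columns=["neuron", "class", "category", "region", "loci"])
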