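"""Agent trajectories and sensors.

The simulated agent is a differential-drive robot abstracted to a point
moving at constant speed: at every time step it advances ``speed * dt``
meters along its current heading, the heading itself performing a bounded
random walk with reflective deflection near the walls (the obstacle
avoidance loop of the physical platform).  Sensors return the true heading
corrupted by compass noise and the true step length corrupted by odometry
noise; landmarks are reported as allocentric azimuths.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import ArenaConfig

TWO_PI = 2.0 * np.pi

#: event-marker codes used in trajectory logs
EVENT_NONE = ""
EVENT_KIDNAP = "kidnap"
EVENT_RECAL = "recal"
EVENT_GOAL = "goal"


def wrap_angle(a):
    """Wrap angle(s) to [0, 2*pi)."""
    return np.mod(a, TWO_PI)


def angle_diff(a, b):
    """Signed smallest difference a - b, in (-pi, pi]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + np.pi, TWO_PI) - np.pi
    return np.where(d == -np.pi, np.pi, d) if np.ndim(d) else (np.pi if d == -np.pi else d)


@dataclass(frozen=True)
class SensorNoiseModel:
    """Compass and odometry noise.

    heading_sd : radians, white additive noise on the measured heading
        (compass accuracy of the physical platform is about 1 degree).
    step_sd_fraction : multiplicative fractional noise on the measured step
        length.  Negative noisy steps are clamped to zero (a wheel does not
        run backward during a forward command).
    heading_bias_sd : radians, stationary standard deviation of a *slowly
        varying* compass bias (AR(1) per step).  A magnetic compass in an
        indoor arena carries a spatially/temporally correlated offset of a
        few degrees on top of its white jitter; it is this correlated term,
        not the white one, that produces the minutes-scale drift of the
        uncalibrated path integrator.  0 disables it.
    heading_bias_ar : per-step AR(1) coefficient of the bias (default
        corresponds to a ~2 min correlation time at 10 Hz).
    heading_deviation_amp : radians, amplitude of a *heading-dependent*
        compass deviation ``A * sin(heading - phase)`` (the one-cycle
        deviation curve of a magnetic compass on a magnetized chassis, with
        a random but fixed phase per run).  Unlike a rotation-like offset,
        a heading-dependent deviation makes closed loops fail to close, so
        the integrator drifts linearly with path length (at about
        ``A/2 * speed`` per second) — the mechanism behind the minutes-scale
        degradation of the uncalibrated grid pattern.
    """

    heading_sd: float = 0.0
    step_sd_fraction: float = 0.0
    seed: int = 0
    heading_bias_sd: float = 0.0
    heading_bias_ar: float = 0.999167
    heading_deviation_amp: float = 0.0

    def __post_init__(self):
        if min(self.heading_sd, self.step_sd_fraction, self.heading_bias_sd,
               self.heading_deviation_amp) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.heading_bias_ar < 1:
            raise ValueError("heading_bias_ar must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sampler(self) -> "NoiseSampler":
        return NoiseSampler(self)


class NoiseSampler:
    """Stateful sensor-noise stream (carries the slow compass bias)."""

    def __init__(self, model: SensorNoiseModel, rng: np.random.Generator | None = None):
        self.model = model
        self.rng = rng if rng is not None else model.rng()
        self.bias = (
            float(self.rng.normal(0.0, model.heading_bias_sd))
            if model.heading_bias_sd > 0
            else 0.0
        )
        # fixed per-run phase of the one-cycle compass deviation
        self.deviation_phase = (
            float(self.rng.uniform(0.0, TWO_PI)) if model.heading_deviation_amp > 0 else 0.0
        )

    def sense(self, heading: float, true_step: float) -> tuple[float, float]:
        m = self.model
        if m.heading_bias_sd > 0:
            innov = m.heading_bias_sd * math.sqrt(1.0 - m.heading_bias_ar**2)
            self.bias = m.heading_bias_ar * self.bias + self.rng.normal(0.0, innov)
        h = heading + self.bias
        if m.heading_deviation_amp > 0:
            h += m.heading_deviation_amp * math.sin(heading - self.deviation_phase)
        if m.heading_sd > 0:
            h += self.rng.normal(0.0, m.heading_sd)
        s = true_step
        if m.step_sd_fraction > 0:
            s *= 1.0 + self.rng.normal(0.0, m.step_sd_fraction)
        return float(wrap_angle(h)), float(max(s, 0.0))


NOISELESS = SensorNoiseModel(0.0, 0.0, 0)


def sense(
    heading: float,
    true_step: float,
    noise: SensorNoiseModel,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Return (measured heading, measured step) under the white noise terms.

    measured heading = heading + N(0, heading_sd), wrapped; measured step =
    step * (1 + N(0, step_sd_fraction)), clamped at 0.  The slow-bias term
    needs state and is handled by :class:`NoiseSampler` (used by the
    trajectory generators); this stateless form draws the white terms only.
    A fresh generator seeded from the model is used when ``rng`` is not
    supplied.
    """
    if rng is None:
        rng = noise.rng()
    h = wrap_angle(heading + (rng.normal(0.0, noise.heading_sd) if noise.heading_sd > 0 else 0.0))
    s = true_step * (
        1.0 + (rng.normal(0.0, noise.step_sd_fraction) if noise.step_sd_fraction > 0 else 0.0)
    )
    return float(h), float(max(s, 0.0))


def landmark_azimuths(
    x: float, y: float, arena: ArenaConfig
) -> list[tuple[int, float]]:
    """Allocentric azimuth of every landmark seen from (x, y).

    Azimuths are world-referenced (counter-clockwise from +x, in [0, 2*pi)),
    as delivered by a compass-anchored visual system; a landmark due east of
    the agent has azimuth 0, due north pi/2.  Landmarks beyond the arena's
    ``visibility_range`` are dropped, and each landmark is reported under
    its appearance class (so visually identical landmarks alias).
    """
    ids, pos = arena.landmark_array()
    if len(ids) == 0:
        raise ValueError("arena has no landmarks")
    dx = pos[:, 0] - x
    dy = pos[:, 1] - y
    az = wrap_angle(np.arctan2(dy, dx))
    keep = np.ones(len(ids), dtype=bool)
    if arena.visibility_range is not None:
        keep = np.hypot(dx, dy) <= arena.visibility_range
    return [
        (arena.perceived_id(int(i)), float(a))
        for i, a, k in zip(ids, az, keep)
        if k
    ]


@dataclass
class Trajectory:
    """Timestamped poses with per-step true and measured displacements.

    Arrays all have length ``n``; ``step_true[k]`` is the displacement from
    sample ``k-1`` to ``k`` (0 at k = 0).  ``events`` holds marker strings
    ("kidnap", "recal", "goal" or "").
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    step_true: np.ndarray
    step_meas: np.ndarray
    heading_meas: np.ndarray
    events: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.t)
        for name in ("x", "y", "heading", "step_true", "step_meas", "heading_meas"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if not self.events:
            self.events = [EVENT_NONE] * n
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def path_length(self) -> float:
        return float(np.sum(self.step_true))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "heading": self.heading,
                "step_true": self.step_true,
                "step_meas": self.step_meas,
                "heading_meas": self.heading_meas,
                "event": self.events,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        events = (
            df["event"].fillna("").astype(str).tolist()
            if "event" in df.columns
            else [EVENT_NONE] * len(df)
        )
        return cls(
            t=df["t"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            heading=df["heading"].to_numpy(float),
            step_true=df["step_true"].to_numpy(float),
            step_meas=df["step_meas"].to_numpy(float),
            heading_meas=df["heading_meas"].to_numpy(float),
            events=events,
        )

    @classmethod
    def from_csv(cls, path: str) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, dt: float = 0.1, noise: SensorNoiseModel = NOISELESS
    ) -> "Trajectory":
        """Build a trajectory from a sequence of (x, y) way-samples.

        Headings are the directions of the successive displacement vectors;
        sensors are sampled with ``noise``.
        """
        positions = np.asarray(positions, dtype=float)
        n = len(positions)
        d = np.diff(positions, axis=0)
        steps = np.hypot(d[:, 0], d[:, 1])
        heads = wrap_angle(np.arctan2(d[:, 1], d[:, 0]))
        heading = np.concatenate([[heads[0] if n > 1 else 0.0], heads])
        step_true = np.concatenate([[0.0], steps])
        sampler = noise.sampler()
        hm = np.empty(n)
        sm = np.empty(n)
        for k in range(n):
            hm[k], sm[k] = sampler.sense(heading[k], step_true[k])
        return cls(
            t=np.arange(n) * dt,
            x=positions[:, 0],
            y=positions[:, 1],
            heading=heading,
            step_true=step_true,
            step_meas=sm,
            heading_meas=hm,
        )


def generate_random_walk(
    arena: ArenaConfig,
    n_steps: int,
    speed: float = 0.2,
    dt: float = 0.1,
    turn_sd: float = 0.3,
    seed: int = 0,
    noise: SensorNoiseModel = NOISELESS,
    start: tuple[float, float] | None = None,
    start_heading: float = 0.0,
    wall_margin: float = 0.4,
) -> Trajectory:
    """Random foraging walk inside the arena.

    The heading performs a Gaussian random walk (sd ``turn_sd`` per step);
    whenever the look-ahead probe at ``wall_margin`` meters leaves the
    boundary the heading is deflected toward the arena centroid, emulating
    the reflex obstacle-avoidance loop of the robot (ultrasound range 0.4 m).

    With ``turn_sd = 0`` and the agent far from walls the path is straight.
    Identical (arena, parameters, seed) give a bit-identical trajectory.
    """
    if speed <= 0 or dt <= 0:
        raise ValueError("speed and dt must be > 0")
    rng = np.random.default_rng(seed)
    sampler = noise.sampler()
    cx, cy = arena.centroid
    if start is None:
        start = (cx, cy)
    if not arena.contains(*start):
        raise ValueError("start position outside arena")
    step_len = speed * dt

    n = n_steps + 1
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    step_true = np.zeros(n)
    hm = np.empty(n)
    sm = np.empty(n)
    x[0], y[0] = start
    heading[0] = wrap_angle(start_heading)
    hm[0], sm[0] = sampler.sense(heading[0], 0.0)

    turns = rng.normal(0.0, turn_sd, size=n_steps) if turn_sd > 0 else np.zeros(n_steps)
    jitters = rng.uniform(-0.3, 0.3, size=n_steps)

    h = heading[0]
    px, py = x[0], y[0]
    for k in range(n_steps):
        h = wrap_angle(h + turns[k])
        # obstacle-avoidance reflex: probe ahead; deflect toward the centroid
        probe = (px + wall_margin * math.cos(h), py + wall_margin * math.sin(h))
        if not arena.contains(*probe):
            h = wrap_angle(math.atan2(cy - py, cx - px) + jitters[k])
        nx, ny = px + step_len * math.cos(h), py + step_len * math.sin(h)
        if not arena.contains(nx, ny):
            # walls closer than the step: turn hard toward the centroid
            h = wrap_angle(math.atan2(cy - py, cx - px))
            nx, ny = px + step_len * math.cos(h), py + step_len * math.sin(h)
            if not arena.contains(nx, ny):  # cornered: stay in place this step
                nx, ny = px, py
        moved = math.hypot(nx - px, ny - py)
        px, py = nx, ny
        x[k + 1], y[k + 1], heading[k + 1] = px, py, h
        step_true[k + 1] = moved
        hm[k + 1], sm[k + 1] = sampler.sense(h, moved)

    return Trajectory(
        t=np.arange(n) * dt,
        x=x,
        y=y,
        heading=heading,
        step_true=step_true,
        step_meas=sm,
        heading_meas=hm,
    )


def apply_kidnap(
    traj: Trajectory, index: int, new_pose: tuple[float, float], arena: ArenaConfig | None = None
) -> Trajectory:
    """Teleport the agent at sample ``index`` to ``new_pose``.

    All poses from ``index`` onward are rigidly translated so the motion
    continues from the new location; the per-step displacement records are
    left untouched, so path integration receives no information about the
    jump (the defining property of a kidnapping event).
    """
    if arena is not None and not arena.contains(*new_pose):
        raise ValueError("kidnap target outside arena boundary")
    if not 0 <= index < len(traj):
        raise IndexError("kidnap index out of range")
    dx = new_pose[0] - traj.x[index]
    dy = new_pose[1] - traj.y[index]
    x = traj.x.copy()
    y = traj.y.copy()
    x[index:] += dx
    y[index:] += dy
    events = list(traj.events)
    events[index] = EVENT_KIDNAP if events[index] == EVENT_NONE else events[index] + "+kidnap"
    return replace(traj, x=x, y=y, events=events)
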