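"""Closed sensory-motor loop: exploration, homing, recalibration, kidnap.

The runner couples the environment to the path-integration field.  The
agent forages with a heading random walk; every ``recal_period`` simulated
seconds a homing drive takes over and the place-action associations steer
it back into the goal zone, where the PI field is overwritten with the
goal profile (the zero state) — the periodic visual recalibration that
keeps the grid code anchored.  Kidnapping events teleport the agent
without informing the odometry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaConfig
from .environment import (
    EVENT_GOAL,
    EVENT_KIDNAP,
    EVENT_NONE,
    EVENT_RECAL,
    NOISELESS,
    SensorNoiseModel,
    Trajectory,
    landmark_azimuths,
    sense,
    wrap_angle,
)
from .path_integration import PIField, SIGNED
from .place_cells import LearningParams, PlaceCellBank, wta_winner


def homing_controller(
    bank: PlaceCellBank,
    x: float,
    y: float,
    arena: ArenaConfig,
    params: LearningParams,
) -> float:
    """Heading command recalled from the winning visual place cell.

    The agent observes the landmark constellation, the visual winner is
    selected, and its stored action direction is returned.  Repeated
    application from anywhere in the learned attraction field drives the
    agent into the goal zone without any metric map.
    """
    if bank.n_cells == 0:
        raise ValueError("homing requires a non-empty place-action bank")
    obs = landmark_azimuths(x, y, arena)
    vpc = bank.vpc_activity(obs, params.azimuth_sigma)
    # only place-action cells compete for the motor command (the goal cell
    # itself stores no action: arrival is signalled by the goal detector)
    has_action = np.array([a is not None for a in bank.actions])
    if not has_action.any():
        raise ValueError("no place cell stores an action direction")
    masked = np.where(has_action, vpc, -np.inf)
    m, _ = wta_winner(masked)
    return float(bank.actions[m])


def learn_homing_places(
    arena: ArenaConfig,
    pi: PIField,
    params: LearningParams,
    n_places: int = 6,
    ring_radius: float | None = None,
    n_grid_inputs: int = 1,
) -> PlaceCellBank:
    """Scripted place-action learning around the goal.

    The first cell is recruited *at* the goal with the PI zero state as its
    profile (so recognizing it later resets the integrator); ``n_places``
    further cells are recruited on a ring around the goal, each storing the
    direction pointing at the goal.  Profiles are the signed-mode
    closed-form PI states for the recruitment displacement from the goal.
    """
    gx, gy = arena.goal
    bank = PlaceCellBank(n_grid_inputs=n_grid_inputs)
    zero = np.full(pi.n, pi.zero_level)
    bank.recruit(landmark_azimuths(gx, gy, arena), zero, action_direction=None)
    if ring_radius is None:
        ring_radius = 0.35 * arena.diameter
    for k in range(n_places):
        a = 2 * math.pi * k / n_places
        px, py = gx + ring_radius * math.cos(a), gy + ring_radius * math.sin(a)
        if not arena.contains(px, py):
            continue
        profile = (
            pi.state_for_displacement(px - gx, py - gy)
            if pi.mode == SIGNED
            else zero
        )
        bank.recruit(
            landmark_azimuths(px, py, arena),
            profile,
            action_direction=wrap_angle(math.atan2(gy - py, gx - px)),
        )
    return bank


def home_from(
    arena: ArenaConfig,
    bank: PlaceCellBank,
    start: tuple[float, float],
    params: LearningParams,
    speed: float = 0.2,
    dt: float = 0.1,
    max_steps: int = 2000,
    wall_margin: float = 0.4,
) -> tuple[np.ndarray, bool]:
    """Run the homing loop from ``start``; returns (positions, reached)."""
    cx, cy = arena.centroid
    px, py = start
    pts = [(px, py)]
    for _ in range(max_steps):
        if arena.in_goal(px, py):
            return np.asarray(pts), True
        h = homing_controller(bank, px, py, arena, params)
        probe = (px + wall_margin * math.cos(h), py + wall_margin * math.sin(h))
        if not arena.contains(*probe):
            h = wrap_angle(math.atan2(cy - py, cx - px))
        nx, ny = px + speed * dt * math.cos(h), py + speed * dt * math.sin(h)
        if not arena.contains(nx, ny):
            h = wrap_angle(math.atan2(cy - py, cx - px))
            nx, ny = px + speed * dt * math.cos(h), py + speed * dt * math.sin(h)
            if not arena.contains(nx, ny):
                nx, ny = px, py
        px, py = nx, ny
        pts.append((px, py))
    return np.asarray(pts), arena.in_goal(px, py)


@dataclass
class LoopResult:
    """Closed-loop run record: trajectory, PI history, event indices."""

    trajectory: Trajectory
    d_history: np.ndarray  # (n_samples, N) PI activities after each step
    recal_steps: list[int] = field(default_factory=list)
    kidnap_steps: list[int] = field(default_factory=list)


def run_closed_loop(
    arena: ArenaConfig,
    pi: PIField,
    n_steps: int,
    dt: float = 0.1,
    speed: float = 0.2,
    turn_sd: float = 0.3,
    noise: SensorNoiseModel = NOISELESS,
    seed: int = 0,
    homing_bank: PlaceCellBank | None = None,
    params: LearningParams | None = None,
    recal_period: float | None = None,
    kidnaps: list[tuple[int, tuple[float, float]]] | None = None,
    start: tuple[float, float] | None = None,
    wall_margin: float = 0.4,
    homing_timeout_steps: int = 3000,
) -> LoopResult:
    """Exploration with optional periodic homing/recalibration and kidnaps.

    When ``recal_period`` is set, an internal drive switches the agent to
    the homing controller every ``recal_period`` seconds; on entering the
    goal zone the PI field is overwritten with the goal cell's profile and
    exploration resumes.  ``kidnaps`` is a list of (step index, new
    position): the agent is teleported and the odometry reads zero for the
    transport.  Identical arguments and seed give bit-identical results.
    """
    if params is None:
        params = LearningParams()
    if recal_period is not None and homing_bank is None:
        raise ValueError("periodic recalibration requires a homing bank")
    rng = np.random.default_rng(seed)
    sampler = noise.sampler()
    kidnap_map = dict(kidnaps or [])
    cx, cy = arena.centroid
    px, py = start if start is not None else arena.goal
    if not arena.contains(px, py):
        raise ValueError("start position outside arena")
    step_len = speed * dt

    n = n_steps + 1
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    step_true = np.zeros(n)
    hm = np.empty(n)
    sm = np.empty(n)
    events = [EVENT_NONE] * n
    d_hist = np.empty((n, pi.n))
    x[0], y[0] = px, py
    h = float(rng.uniform(0, 2 * math.pi))
    heading[0] = h
    hm[0], sm[0] = sampler.sense(h, 0.0)
    d_hist[0] = pi.d
    recal_steps: list[int] = []
    kidnap_steps: list[int] = []

    mode = "explore"
    drive_timer = 0.0
    homing_steps = 0

    for k in range(1, n):
        if k - 1 in kidnap_map:
            tx, ty = kidnap_map[k - 1]
            if not arena.contains(tx, ty):
                raise ValueError("kidnap target outside arena")
            px, py = tx, ty
            x[k], y[k], heading[k] = px, py, h
            hm[k], sm[k] = sampler.sense(h, 0.0)
            events[k] = EVENT_KIDNAP
            kidnap_steps.append(k)
            d_hist[k] = pi.d
            continue

        if recal_period is not None and mode == "explore" and drive_timer >= recal_period:
            mode = "homing"
            homing_steps = 0

        if mode == "homing":
            h = homing_controller(homing_bank, px, py, arena, params)
            homing_steps += 1
            if homing_steps > homing_timeout_steps:
                mode = "explore"
                drive_timer = 0.0
        else:
            h = wrap_angle(h + rng.normal(0.0, turn_sd)) if turn_sd > 0 else h

        probe = (px + wall_margin * math.cos(h), py + wall_margin * math.sin(h))
        if not arena.contains(*probe):
            h = wrap_angle(math.atan2(cy - py, cx - px) + rng.uniform(-0.3, 0.3))
        nx, ny = px + step_len * math.cos(h), py + step_len * math.sin(h)
        if not arena.contains(nx, ny):
            h = wrap_angle(math.atan2(cy - py, cx - px))
            nx, ny = px + step_len * math.cos(h), py + step_len * math.sin(h)
            if not arena.contains(nx, ny):
                nx, ny = px, py
        moved = math.hypot(nx - px, ny - py)
        px, py = nx, ny

        mh, ms = sampler.sense(h, moved)
        pi.update(mh, ms)
        drive_timer += dt

        x[k], y[k], heading[k] = px, py, h
        step_true[k] = moved
        hm[k], sm[k] = mh, ms
        d_hist[k] = pi.d

        if mode == "homing" and arena.in_goal(px, py):
            pi.set_profile(homing_bank.profiles[0])
            d_hist[k] = pi.d
            events[k] = EVENT_RECAL + "+" + EVENT_GOAL
            recal_steps.append(k)
            mode = "explore"
            drive_timer = 0.0

    traj = Trajectory(
        t=np.arange(n) * dt,
        x=x,
        y=y,
        heading=heading,
        step_true=step_true,
        step_meas=sm,
        heading_meas=hm,
        events=events,
    )
    return LoopResult(
        trajectory=traj, d_history=d_hist, recal_steps=recal_steps, kidnap_steps=kidnap_steps
    )
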