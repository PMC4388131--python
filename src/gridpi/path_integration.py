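"""Path integration on a 1D circular neural field.

A ring of ``N`` neurons with preferred directions ``theta_i = -2*pi*i/N``
receives the current heading through a direction-tuned input field ``V`` and
accumulates it, scaled by the displacement length, into an integrating field
``D``.  The neuron best aligned with the net displacement carries the
largest activity, and its level encodes the distance from the last reset —
the population is a homing vector.

Two accumulation modes are provided:

``as_printed``
    ``V_i = 1 + cos(phi - theta_i)`` with rectified accumulation.  The
    offset term adds the *total path length* to every neuron, so individual
    activities depend on the path taken, not only on position.

``signed_projection`` (default for grid experiments)
    ``V_i = cos(phi - theta_i)`` accumulated with sign; the stored value is
    offset by ``D_max/2`` so it stays in ``[0, D_max]``.  Each ``D_i`` is
    then an affine function of the net displacement projected on
    ``theta_i`` — a pure position code, which is the regime in which
    hexagonal grid patterns arise downstream.

Saturation is a hard clamp at ``[0, D_max]``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import Trajectory, wrap_angle

AS_PRINTED = "as_printed"
SIGNED = "signed_projection"


def preferred_directions(n: int) -> np.ndarray:
    """theta_i = -2*pi*i/N, wrapped to [0, 2*pi)."""
    return wrap_angle(-2.0 * np.pi * np.arange(n) / n)


@dataclass
class DirectionField:
    """Direction-coded input field V over N uniformly spaced neurons."""

    n: int = 60
    mode: str = AS_PRINTED

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("direction field needs at least 2 neurons")
        if self.mode not in (AS_PRINTED, SIGNED):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.theta = preferred_directions(self.n)

    def activity(self, heading: float) -> np.ndarray:
        """V_i for the given heading.

        ``1 + cos(phi - theta_i)`` (non-negative, in [0, 2]) in as-printed
        mode, or the signed projection ``cos(phi - theta_i)`` otherwise.
        The maximum sits at the neuron whose preferred direction is nearest
        the heading.
        """
        c = np.cos(heading - self.theta)
        return 1.0 + c if self.mode == AS_PRINTED else c


@dataclass
class HomeVector:
    direction: float  # radians; meaningful only if defined
    distance: float  # meters
    defined: bool = True


class PIField:
    """Integrating field D with reset and profile-overwrite recalibration.

    Parameters
    ----------
    n : neuron count (ring size).
    alpha : per-unit-step gain (0 < alpha < 1).
    d_max : field ceiling; activities are clamped to [0, d_max].
    meters_per_unit : meters corresponding to one unit of normalized step.
        Distances decode as ``(D - zero) * meters_per_unit / alpha``; the
        default is chosen so the field spans about twice a 4 m arena.
    mode : "as_printed" or "signed_projection" (see module docstring).
    """

    def __init__(
        self,
        n: int = 60,
        alpha: float = 0.01,
        d_max: float = 1.0,
        meters_per_unit: float = 0.08,
        mode: str = SIGNED,
    ):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if d_max <= 0 or meters_per_unit <= 0:
            raise ValueError("d_max and meters_per_unit must be > 0")
        self.n = n
        self.alpha = alpha
        self.d_max = d_max
        self.meters_per_unit = meters_per_unit
        self.mode = mode
        self.field_v = DirectionField(n, mode)
        self.theta = self.field_v.theta
        self.d = np.full(n, self.zero_level, dtype=float)

    @classmethod
    def for_arena(cls, arena, n: int = 60, alpha: float = 0.01, d_max: float = 1.0,
                  mode: str = SIGNED, span_factor: float = 2.0) -> "PIField":
        """Field whose range spans ``span_factor`` arena diameters."""
        mpu = span_factor * arena.diameter * alpha / d_max
        return cls(n=n, alpha=alpha, d_max=d_max, meters_per_unit=mpu, mode=mode)

    # ----------------------------------------------------------------- state
    @property
    def zero_level(self) -> float:
        """Activity encoding 'no displacement' (0, or D_max/2 in signed mode)."""
        return 0.0 if self.mode == AS_PRINTED else self.d_max / 2.0

    def reset(self) -> None:
        """Set every neuron to the zero state (binary reset signal r = 1)."""
        self.d[:] = self.zero_level

    def set_profile(self, profile: np.ndarray) -> None:
        """Overwrite D with a previously recorded profile (recalibration)."""
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (self.n,):
            raise ValueError(f"profile must have length {self.n}")
        if np.any(profile < -1e-12) or np.any(profile > self.d_max + 1e-12):
            raise ValueError("profile values must lie in [0, d_max]")
        self.d = np.clip(profile, 0.0, self.d_max)

    def snapshot(self) -> np.ndarray:
        return self.d.copy()

    # ---------------------------------------------------------------- update
    def update(self, heading: float, step_m: float) -> np.ndarray:
        """Accumulate one movement of ``step_m`` meters along ``heading``.

        The increment is ``alpha * (step/meters_per_unit) * V_i`` followed by
        rectification and the ceiling clamp; a zero step changes nothing.
        Returns the new state (a view copy).
        """
        if step_m < 0:
            raise ValueError("step must be >= 0")
        if step_m > 0:
            v = self.field_v.activity(heading)
            self.d += self.alpha * (step_m / self.meters_per_unit) * v
            np.clip(self.d, 0.0, self.d_max, out=self.d)
        return self.d.copy()

    def integrate(self, traj: Trajectory, use_measured: bool = True) -> np.ndarray:
        """Integrate a whole trajectory; returns the (n_samples, N) D history.

        Uses the measured (noisy) heading and step by default, the true ones
        otherwise.  A vectorized cumulative sum is used when no sample would
        hit the clamp; otherwise the exact sequential update is applied.
        """
        heads = traj.heading_meas if use_measured else traj.heading
        steps = traj.step_meas if use_measured else traj.step_true
        k = self.alpha / self.meters_per_unit
        c = np.cos(heads[:, None] - self.theta[None, :])
        v = 1.0 + c if self.mode == AS_PRINTED else c
        incr = k * steps[:, None] * v
        hist = self.d[None, :] + np.cumsum(incr, axis=0)
        if hist.min() >= 0.0 and hist.max() <= self.d_max:
            self.d = hist[-1].copy()
            return hist
        out = np.empty_like(hist)
        for i in range(len(steps)):
            out[i] = self.update(heads[i], steps[i])
        return out

    # --------------------------------------------------------------- readout
    def state_for_displacement(self, dx: float, dy: float) -> np.ndarray:
        """Closed-form signed-mode state after a net displacement (dx, dy).

        Valid in signed mode only (there D is a pure position code): each
        neuron holds the projection of the displacement on its preferred
        direction.  Raises if the displacement is out of the field's range.
        """
        if self.mode != SIGNED:
            raise ValueError("closed-form state is defined for signed_projection mode")
        proj = dx * np.cos(self.theta) + dy * np.sin(self.theta)
        d = self.zero_level + self.alpha * proj / self.meters_per_unit
        if d.min() < -1e-9 or d.max() > self.d_max + 1e-9:
            raise ValueError("displacement outside the range covered by d_max")
        return np.clip(d, 0.0, self.d_max)

    def readout_home_vector(self) -> HomeVector:
        """Direction and length of the net displacement since the last reset.

        The winning neuron's preferred direction gives the bearing of the
        outbound movement; its activity above the zero level decodes the
        distance.  (The home vector points opposite the returned direction.)
        """
        rel = self.d - self.zero_level
        if np.allclose(rel, rel[0]):
            return HomeVector(direction=float("nan"), distance=0.0, defined=False)
        i = int(np.argmax(rel))
        dist = max(rel[i], 0.0) * self.meters_per_unit / self.alpha
        return HomeVector(direction=float(self.theta[i]), distance=float(dist))

    # ------------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": np.arange(self.n), "theta": self.theta, "D": self.d})

    def export_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def import_csv(self, path: str) -> None:
        df = pd.read_csv(path)
        self.set_profile(df["D"].to_numpy(float))
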