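"""Place cells: visual recognition, grid-driven prediction, fusion.

Three populations share one bank of recruited cells:

* **VPC** — visual place cells, recognizing a stored landmark-azimuth
  constellation with Gaussian azimuth tuning (broad, graded fields).
* **PredVPC** — the VPC activity *predicted from grid cells* by a
  normalized least-mean-squares (NLMS) linear readout, trained online with
  the visual activity as the target; learning is gated to the
  winner-take-all visual winner and a binary neuromodulation signal.
* **MPC** — multimodal place cells, the convex combination
  ``eta * VPC + (1 - eta) * PredVPC`` (``eta = 0.5`` by default).

Each recruited cell also stores the path-integration profile observed at
recruitment; when the cell is later recognized confidently (absolute and
relative thresholds), the stored profile is written back into the PI field
— the visual recalibration that bounds integration drift.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import angle_diff

DEG = np.pi / 180.0


@dataclass
class LearningParams:
    """NLMS gating and recalibration thresholds.

    lam : base learning rate in [0, 1] (the NLMS step).
    gamma : binary neuromodulation gate (0 freezes all learning).
    thr_abs : absolute recognition threshold for recalibration.
    thr_rel : required margin over the second-best cell.
    eta : visual weight in the multimodal fusion.
    azimuth_sigma : Gaussian tuning width of the visual cells, radians.
    """

    lam: float = 0.1
    gamma: int = 1
    thr_abs: float = 0.7
    thr_rel: float = 0.15
    eta: float = 0.5
    azimuth_sigma: float = 10.0 * DEG

    def __post_init__(self):
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must be in [0, 1]")
        if self.gamma not in (0, 1):
            raise ValueError("gamma is binary")
        for t in (self.thr_abs, self.thr_rel):
            if not 0 <= t <= 1:
                raise ValueError("thresholds must be in [0, 1]")
        if not 0 <= self.eta <= 1:
            raise ValueError("eta must be in [0, 1]")


@dataclass
class PlaceCellBank:
    """Recruited place cells with their stores and NLMS weights.

    ``constellations[m]`` maps landmark id -> stored azimuth; ``profiles``
    holds one PI profile per cell (the first recruited cell's profile is the
    PI zero state when recruitment happens at the origin after a reset);
    ``weights`` is the (M, L) NLMS readout from L grid cells; ``actions``
    optionally stores a movement direction per cell (homing associations).
    """

    n_grid_inputs: int
    constellations: list[dict[int, float]] = field(default_factory=list)
    profiles: list[np.ndarray] = field(default_factory=list)
    actions: list[float | None] = field(default_factory=list)
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.zeros((0, self.n_grid_inputs))

    @property
    def n_cells(self) -> int:
        return len(self.constellations)

    def recruit(
        self,
        observation: list[tuple[int, float]],
        pi_profile: np.ndarray,
        action_direction: float | None = None,
    ) -> int:
        """Recruit a new cell storing the current constellation and PI state.

        No deduplication is attempted: recruiting twice at the same pose
        yields two cells with identical stores.  Returns the new index.
        """
        self.constellations.append({int(i): float(a) for i, a in observation})
        self.profiles.append(np.asarray(pi_profile, dtype=float).copy())
        self.actions.append(action_direction)
        self.weights = np.vstack([self.weights, np.zeros(self.n_grid_inputs)])
        return self.n_cells - 1

    # -------------------------------------------------------------- activity
    def vpc_activity(
        self, observation: list[tuple[int, float]], azimuth_sigma: float
    ) -> np.ndarray:
        """Visual activity of every cell for the observed constellation.

        Per cell: the mean over its *stored* landmarks of
        ``exp(-daz^2 / (2 sigma^2))`` where ``daz`` is the wrapped azimuth
        error of the matching landmark id; landmarks absent from the
        observation contribute 0, and a cell sharing no id with the
        observation has activity 0.
        """
        if not observation:
            raise ValueError("empty observation")
        if self.n_cells == 0:
            raise ValueError("no recruited cells")
        obs = {int(i): float(a) for i, a in observation}
        act = np.zeros(self.n_cells)
        inv2s2 = 1.0 / (2.0 * azimuth_sigma**2)
        for m, stored in enumerate(self.constellations):
            vals = [
                np.exp(-(angle_diff(obs[i], a) ** 2) * inv2s2)
                for i, a in stored.items()
                if i in obs
            ]
            act[m] = np.sum(vals) / len(stored) if vals else 0.0
        return act

    def predict_vpc(self, grid: np.ndarray) -> np.ndarray:
        """Linear NLMS readout of all cells from the grid vector (no clipping)."""
        grid = np.asarray(grid, dtype=float)
        if grid.shape != (self.n_grid_inputs,):
            raise ValueError(f"grid vector must have length {self.n_grid_inputs}")
        return self.weights @ grid

    def nlms_update(
        self, grid: np.ndarray, vpc: np.ndarray, params: LearningParams
    ) -> np.ndarray:
        """One gated NLMS step on the visual winner's weights.

        Only the winner-take-all cell learns (``beta`` gate) and only when
        the neuromodulation gate ``gamma`` is 1; the step is the prediction
        error scaled by ``lam`` and normalized by the grid input energy.
        A zero-energy grid vector produces no update.  Returns the
        prediction used for the update (pre-update weights).
        """
        pred = self.predict_vpc(grid)
        if params.gamma == 0:
            return pred
        m, _ = wta_winner(vpc)
        energy = float(np.dot(grid, grid))
        if energy > 0.0:
            self.weights[m] += params.lam * (vpc[m] - pred[m]) * grid / energy
        return pred

    # --------------------------------------------------------------- storage
    def to_dict(self) -> dict:
        return {
            "n_grid_inputs": self.n_grid_inputs,
            "constellations": [
                {str(k): v for k, v in c.items()} for c in self.constellations
            ],
            "profiles": [p.tolist() for p in self.profiles],
            "actions": [None if a is None else float(a) for a in self.actions],
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlaceCellBank":
        bank = cls(n_grid_inputs=int(d["n_grid_inputs"]))
        bank.constellations = [
            {int(k): float(v) for k, v in c.items()} for c in d["constellations"]
        ]
        bank.profiles = [np.asarray(p, dtype=float) for p in d["profiles"]]
        bank.actions = [None if a is None else float(a) for a in d["actions"]]
        bank.weights = np.asarray(d["weights"], dtype=float).reshape(
            len(bank.constellations), bank.n_grid_inputs
        )
        return bank

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "PlaceCellBank":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def wta_winner(activities: np.ndarray) -> tuple[int, np.ndarray]:
    """Winner-take-all: argmax index and its one-hot beta gate.

    Ties break to the lowest index.
    """
    a = np.asarray(activities, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one cell")
    m = int(np.argmax(a))
    beta = np.zeros(a.size)
    beta[m] = 1.0
    return m, beta


def fuse_mpc(vpc: np.ndarray, pred_vpc: np.ndarray, eta: float = 0.5) -> np.ndarray:
    """Multimodal fusion: convex combination of visual and grid predictions."""
    if not 0 <= eta <= 1:
        raise ValueError("eta must be in [0, 1]")
    return eta * np.asarray(vpc, float) + (1.0 - eta) * np.asarray(pred_vpc, float)


def recalibration_trigger(
    vpc: np.ndarray, params: LearningParams
) -> tuple[bool, int]:
    """Decide whether the visual winner is trusted enough to recalibrate.

    Fires when the winner's activity exceeds the absolute threshold AND its
    margin over the second-best cell exceeds the relative threshold (with a
    single cell, the absolute test alone applies).  On fire the caller
    overwrites the PI field with the winner's stored profile.
    """
    a = np.asarray(vpc, dtype=float)
    m, _ = wta_winner(a)
    if a.size == 1:
        return bool(a[0] >= params.thr_abs), m
    second = np.partition(a, -2)[-2]
    fire = (a[m] >= params.thr_abs) and (a[m] - second >= params.thr_rel)
    return bool(fire), m


class GridPatternBank:
    """Place cells learned from grid patterns by one-shot competitive storage.

    Each cell stores the full grid vector observed at its recruitment
    position; recognition is the normalized dot product with the stored
    pattern, followed by winner-take-all.  With L binary one-hot layers the
    activity along a path through a learned point is a descending stair with
    plateaus L/L, (L-1)/L, ..., 1/L as the layers' bin boundaries are
    crossed one by one.
    """

    def __init__(self):
        self.patterns: list[np.ndarray] = []

    @property
    def n_cells(self) -> int:
        return len(self.patterns)

    def recruit(self, grid: np.ndarray) -> int:
        self.patterns.append(np.asarray(grid, dtype=float).copy())
        return self.n_cells - 1

    def recognize(self, grid: np.ndarray) -> np.ndarray:
        """Cosine similarity of the grid vector with every stored pattern."""
        if not self.patterns:
            raise ValueError("no recruited cells")
        g = np.asarray(grid, dtype=float)
        gn = np.linalg.norm(g)
        if gn == 0:
            return np.zeros(self.n_cells)
        p = np.vstack(self.patterns)
        norms = np.linalg.norm(p, axis=1)
        out = (p @ g) / (norms * gn)
        out[norms == 0] = 0.0
        return out

    def trace_frame(self, t: np.ndarray, activities: np.ndarray) -> pd.DataFrame:
        """Long-format activity trace (t, cell, activity) for CSV export."""
        n_t, n_c = activities.shape
        return pd.DataFrame(
            {
                "t": np.repeat(t, n_c),
                "cell": np.tile(np.arange(n_c), n_t),
                "activity": activities.ravel(),
            }
        )
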