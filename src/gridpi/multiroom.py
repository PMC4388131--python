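"""Multi-room place-cell experiments: aliasing, fusion, kidnapping.

Two visually similar rooms joined by a corridor.  Room landmarks in the
second room share the *appearance* of those in the first (perceptual
aliasing: the visual system cannot tell the rooms apart, up to a small
furniture-level perturbation), while the corridor landmarks are unique.
The agent is moved passively along a learned path of regularly spaced
places; visual place cells, the NLMS grid prediction and the multimodal
fusion are recorded, with optional kidnapping events.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaConfig
from .environment import landmark_azimuths, wrap_angle
from .grid_cells import GridPopulation, default_layers
from .path_integration import PIField
from .place_cells import (
    LearningParams,
    PlaceCellBank,
    fuse_mpc,
    recalibration_trigger,
)

#: x-offset between the two visually similar rooms, meters
ROOM_OFFSET = 22.0


def multiroom_arena(alias_jitter: float = 0.8) -> ArenaConfig:
    """Two ~8 m rooms joined by a corridor, 32 x 6 m overall.

    Room-2 landmarks are room-1's constellation translated by
    ``ROOM_OFFSET`` and perturbed by ``alias_jitter`` meters, but mapped to
    the *same appearance classes*, so vision alone confuses the rooms.
    Corridor landmarks are unique.  Visibility is limited to 9 m, so each
    room is recognized from its own cues.
    """
    room1 = [(0, (2.0, 1.0)), (1, (2.0, 5.0)), (2, (8.0, 5.0)), (3, (8.0, 1.0))]
    corridor = [(10, (14.5, 1.0)), (11, (14.5, 5.0)), (12, (17.5, 5.0)), (13, (17.5, 1.0))]
    jit = alias_jitter * np.array([[1, -1], [-1, 1], [1, 1], [-1, -1]], dtype=float)
    room2 = [
        (20 + k, (p[0] + ROOM_OFFSET + jit[k, 0], p[1] + jit[k, 1]))
        for k, (_, p) in enumerate(room1)
    ]
    appearance = {20 + k: k for k in range(4)}
    return ArenaConfig(
        boundary=np.array([[0, 0], [32, 0], [32, 6], [0, 6]], dtype=float),
        landmarks=room1 + corridor + room2,
        goal=(1.0, 3.0),
        goal_radius=0.15,
        visibility_range=9.0,
        appearance=appearance,
    )


def path1_positions(
    n_places: int = 19,
    spacing: float = 1.5,
    step: float = 0.02,
    y: float = 3.0,
    x0: float = 1.0,
    y_offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """The learned multi-room path: straight, places every ``spacing`` m.

    Returns (positions (T, 2), indices of the place samples).  ``step`` is
    the distance per sample (speed x dt of the passive transport).
    """
    length = spacing * (n_places - 1)
    n = int(round(length / step)) + 1
    xs = x0 + np.arange(n) * step
    pos = np.column_stack([xs, np.full(n, y + y_offset)])
    place_idx = np.round(np.arange(n_places) * spacing / step).astype(int)
    return pos, place_idx


@dataclass
class TraceRecord:
    """Per-step population traces of one pass."""

    t: np.ndarray
    positions: np.ndarray
    vpc: np.ndarray  # (T, M)
    pred: np.ndarray
    mpc: np.ndarray
    recal_steps: list[int] = field(default_factory=list)
    kidnap_steps: list[int] = field(default_factory=list)

    def winners(self, which: str = "mpc") -> np.ndarray:
        return np.argmax(getattr(self, which), axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format activity trace with winner and recalibration flags."""
        t_n, m = self.vpc.shape
        recal = np.zeros(t_n, dtype=int)
        recal[self.recal_steps] = 1
        win = self.winners("mpc")
        rows = {
            "t": np.repeat(self.t, m),
            "cell": np.tile(np.arange(m), t_n),
            "vpc": self.vpc.ravel(),
            "predvpc": self.pred.ravel(),
            "mpc": self.mpc.ravel(),
            "winner_flag": (np.tile(np.arange(m), t_n) == np.repeat(win, m)).astype(int),
            "recal_event": np.repeat(recal, m),
        }
        return pd.DataFrame(rows)


def scripted_pass(
    arena: ArenaConfig,
    pi: PIField,
    grids: GridPopulation,
    bank: PlaceCellBank,
    params: LearningParams,
    positions: np.ndarray,
    dt: float = 0.1,
    learn: bool = False,
    recruit_at: dict[int, None] | set | None = None,
    recal_enabled: bool = True,
    kidnap_jumps: set[int] | None = None,
) -> TraceRecord:
    """Passively transport the agent along ``positions`` and record traces.

    ``recruit_at`` lists sample indices at which a new place cell is
    recruited (constellation + current PI profile).  ``kidnap_jumps`` are
    sample indices whose displacement is invisible to the odometry (the
    blindfolded transport); the PI field continues in its old frame until a
    recalibration trigger fires.  With ``learn`` the NLMS readout is
    trained on the visual winner (gamma = 1), otherwise weights are frozen.
    """
    recruit_at = set(recruit_at or ())
    kidnap_jumps = set(kidnap_jumps or ())
    n = len(positions)
    m_final = bank.n_cells + len(recruit_at)
    vpc_tr = np.zeros((n, m_final))
    pred_tr = np.zeros((n, m_final))
    mpc_tr = np.zeros((n, m_final))
    recal_steps: list[int] = []
    learn_params = params if learn else LearningParams(
        lam=params.lam, gamma=0, thr_abs=params.thr_abs, thr_rel=params.thr_rel,
        eta=params.eta, azimuth_sigma=params.azimuth_sigma,
    )

    prev = positions[0]
    for k in range(n):
        p = positions[k]
        if k > 0:
            dvec = p - prev
            stp = float(np.hypot(*dvec))
            if k in kidnap_jumps or stp == 0.0:
                pass  # lifted: odometry silent
            else:
                pi.update(float(wrap_angle(np.arctan2(dvec[1], dvec[0]))), stp)
        prev = p
        obs = landmark_azimuths(p[0], p[1], arena)
        if k in recruit_at:
            bank.recruit(obs, pi.snapshot())
        if bank.n_cells == 0:
            continue
        grid = grids.flat_activities(pi, diffused=True)
        vpc = bank.vpc_activity(obs, params.azimuth_sigma)
        pred = bank.nlms_update(grid, vpc, learn_params)
        mpc = fuse_mpc(vpc, pred, params.eta)
        mm = bank.n_cells
        vpc_tr[k, :mm] = vpc
        pred_tr[k, :mm] = pred
        mpc_tr[k, :mm] = mpc
        if recal_enabled:
            fire, winner = recalibration_trigger(vpc, params)
            if fire:
                pi.set_profile(bank.profiles[winner])
                recal_steps.append(k)

    return TraceRecord(
        t=np.arange(n) * dt,
        positions=np.asarray(positions, float),
        vpc=vpc_tr,
        pred=pred_tr,
        mpc=mpc_tr,
        recal_steps=recal_steps,
        kidnap_steps=sorted(kidnap_jumps),
    )


@dataclass
class MultiroomSetup:
    arena: ArenaConfig
    pi: PIField
    grids: GridPopulation
    bank: PlaceCellBank
    params: LearningParams
    positions: np.ndarray
    place_idx: np.ndarray


def build_multiroom(
    n_places: int = 19,
    spacing: float = 1.5,
    training_passes: int = 3,
    lam: float = 0.5,
    diffusion_sigma: float = 1.0,
    alias_jitter: float = 0.8,
    thr_abs: float = 0.85,
    n_e: int = 120,
    seed: int = 0,
) -> MultiroomSetup:
    """Learn the multi-room path: recruit places, train the NLMS readout.

    The first place is recruited at the path start right after a PI reset,
    so its stored profile is the zero state; each later place stores the PI
    profile at its recruitment.  ``training_passes`` passes of gated NLMS
    learning follow (the first pass recruits, later passes only train).
    """
    arena = multiroom_arena(alias_jitter=alias_jitter)
    positions, place_idx = path1_positions(n_places=n_places, spacing=spacing)
    pi = PIField.for_arena(arena)
    # finer discretization than the arena default: the place spacing is
    # 1.5 m and the field width scales with the discretization bin, so the
    # grid-driven place fields must resolve that spacing
    grids = GridPopulation(
        default_layers(n_pi=pi.n, n_e=n_e, diffusion_sigma=diffusion_sigma)
    )
    # a raised absolute threshold keeps the recalibration zone narrow, as
    # the recalibration mechanism requires to be effective
    params = LearningParams(lam=lam, thr_abs=thr_abs)
    bank = PlaceCellBank(n_grid_inputs=grids.n_cells)
    # recruitment pass first (learning gated off): every cell must exist
    # before associative training, otherwise early cells win spurious
    # competitions at not-yet-learned places and keep the stale weights
    pi.reset()
    scripted_pass(
        arena, pi, grids, bank, params, positions,
        learn=False, recruit_at=set(place_idx.tolist()), recal_enabled=True,
    )
    for _ in range(max(training_passes, 1)):
        pi.reset()  # transported back to the start place (cell 0 resets PI)
        scripted_pass(arena, pi, grids, bank, params, positions, learn=True)
    return MultiroomSetup(
        arena=arena, pi=pi, grids=grids, bank=bank, params=params,
        positions=positions, place_idx=place_idx,
    )


def evaluation_pass(
    setup: MultiroomSetup,
    y_offset: float = 0.0,
    kidnap_from_place: float | None = None,
    kidnap_to_place: float | None = None,
) -> TraceRecord:
    """Frozen-weights pass along (a parallel of) the learned path.

    With kidnapping, the pass follows the path up to ``kidnap_from_place``,
    then teleports to ``kidnap_to_place`` and continues along the path from
    there; the jump is invisible to the odometry.  Fractional place indices
    address points between learned places (e.g. 8.5 is halfway between
    places 8 and 9).
    """
    n_places = len(setup.place_idx)
    spacing = float(
        setup.positions[setup.place_idx[1], 0] - setup.positions[setup.place_idx[0], 0]
    )
    positions, place_idx = path1_positions(
        n_places=n_places, spacing=spacing, y_offset=y_offset
    )
    kidnaps: set[int] = set()
    if kidnap_from_place is not None:
        per_place = place_idx[1] - place_idx[0]
        i_from = int(round(kidnap_from_place * per_place))
        i_to = int(round(kidnap_to_place * per_place))
        positions = np.vstack([positions[: i_from + 1], positions[i_to:]])
        kidnaps = {i_from + 1}
    setup.pi.reset()  # pass starts at the start place (cell 0 -> zero state)
    return scripted_pass(
        setup.arena, setup.pi, setup.grids, setup.bank, setup.params,
        positions, learn=False, recal_enabled=True, kidnap_jumps=kidnaps,
    )
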