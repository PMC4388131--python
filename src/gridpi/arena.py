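"""Arena geometry: boundary polygon, landmarks, goal zone.

The reference environment is a hexagonal enclosure of 4 m diameter with a
handful of distal landmarks; a multi-room floor (two rooms joined by a
corridor) is used for place-cell experiments.  Geometry is handled by
shapely; all coordinates are in meters, world frame.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from shapely.geometry import Point, Polygon


class ArenaError(ValueError):
    """Raised for degenerate or inconsistent arena configurations."""


@dataclass
class ArenaConfig:
    """Arena boundary, landmark constellation and goal zone.

    Parameters
    ----------
    boundary : (V, 2) array-like
        Vertices of a simple polygon, meters, world frame.
    landmarks : list of (id, (x, y))
        Point landmarks visible from everywhere (distal-cue idealization).
    goal : (x, y)
        Goal / recalibration location, inside the boundary.
    goal_radius : float
        Radius of the goal-detection zone, meters.  Stands in for the
        floor-color sensor of the robot; a smaller radius emulates the
        wall-assisted precision of a corner goal.
    """

    boundary: np.ndarray
    landmarks: list[tuple[int, tuple[float, float]]] = field(default_factory=list)
    goal: tuple[float, float] = (0.0, 0.0)
    goal_radius: float = 0.15
    #: maximum distance at which a landmark is perceived (None = unlimited;
    #: finite values model room-scale occlusion in multi-room floors)
    visibility_range: float | None = None
    #: optional landmark id -> appearance class; two landmarks sharing an
    #: appearance class are indistinguishable to vision (perceptual aliasing)
    appearance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2 or len(self.boundary) < 3:
            raise ArenaError("boundary must be a (V, 2) vertex array with V >= 3")
        self._polygon = Polygon(self.boundary)
        if not self._polygon.is_valid or self._polygon.area <= 0:
            raise ArenaError("boundary must be a simple polygon with positive area")
        ids = [lid for lid, _ in self.landmarks]
        if len(ids) != len(set(ids)):
            raise ArenaError("landmark ids must be unique")
        if self.goal_radius <= 0:
            raise ArenaError("goal_radius must be > 0")
        if not self.contains(*self.goal):
            raise ArenaError("goal must lie inside the boundary")

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def diameter(self) -> float:
        """Largest extent of the bounding box, meters."""
        minx, miny, maxx, maxy = self._polygon.bounds
        return max(maxx - minx, maxy - miny)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self._polygon.centroid
        return (c.x, c.y)

    def contains(self, x, y) -> np.ndarray | bool:
        """Vectorized point-in-polygon test (boundary counts as inside)."""
        inside = shapely.contains_xy(self._polygon, x, y)
        if np.ndim(x) == 0:
            if inside:
                return True
            return bool(self._polygon.exterior.distance(Point(float(x), float(y))) < 1e-12)
        return inside

    def in_goal(self, x: float, y: float) -> bool:
        gx, gy = self.goal
        return math.hypot(x - gx, y - gy) <= self.goal_radius

    def landmark_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Landmark ids and positions as arrays ((K,), (K, 2))."""
        if not self.landmarks:
            return np.empty(0, dtype=int), np.empty((0, 2))
        ids = np.array([lid for lid, _ in self.landmarks], dtype=int)
        pos = np.array([p for _, p in self.landmarks], dtype=float)
        return ids, pos

    def perceived_id(self, landmark_id: int) -> int:
        """Appearance class reported by vision for a landmark."""
        return int(self.appearance.get(landmark_id, landmark_id))

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = {
            "boundary": self.boundary.tolist(),
            "landmarks": [[int(lid), [float(p[0]), float(p[1])]] for lid, p in self.landmarks],
            "goal": [float(self.goal[0]), float(self.goal[1])],
            "goal_radius": float(self.goal_radius),
        }
        if self.visibility_range is not None:
            d["visibility_range"] = float(self.visibility_range)
        if self.appearance:
            d["appearance"] = {str(k): int(v) for k, v in self.appearance.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        vr = d.get("visibility_range")
        return cls(
            boundary=np.asarray(d["boundary"], dtype=float),
            landmarks=[(int(lid), (float(p[0]), float(p[1]))) for lid, p in d.get("landmarks", [])],
            goal=tuple(d.get("goal", (0.0, 0.0))),
            goal_radius=float(d.get("goal_radius", 0.15)),
            visibility_range=None if vr is None else float(vr),
            appearance={int(k): int(v) for k, v in d.get("appearance", {}).items()},
        )

    def save(self, path: str) -> None:
        """Write the arena as YAML (JSON-compatible subset)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "ArenaConfig":
        with open(path) as fh:
            text = fh.read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        return cls.from_dict(d)


def hexagonal_arena(
    diameter: float = 4.0,
    n_landmarks: int = 6,
    landmark_distance: float | None = None,
    goal: tuple[float, float] = (0.0, 0.0),
    goal_radius: float = 0.15,
) -> ArenaConfig:
    """Regular hexagonal enclosure centred on the origin.

    ``diameter`` is the vertex-to-vertex distance (4 m for the reference
    enclosure).  Landmarks are placed on a ring outside the walls so that
    every landmark is visible from everywhere, mimicking distal room cues.
    """
    r = diameter / 2.0
    ang = np.arange(6) * np.pi / 3.0
    boundary = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    if landmark_distance is None:
        landmark_distance = 1.5 * r
    lm_ang = np.arange(n_landmarks) * 2 * np.pi / max(n_landmarks, 1) + np.pi / 6
    landmarks = [
        (k, (landmark_distance * math.cos(a), landmark_distance * math.sin(a)))
        for k, a in enumerate(lm_ang)
    ]
    return ArenaConfig(boundary=boundary, landmarks=landmarks, goal=goal, goal_radius=goal_radius)


def rectangular_arena(
    width: float,
    height: float,
    origin: tuple[float, float] = (0.0, 0.0),
    landmarks: list[tuple[int, tuple[float, float]]] | None = None,
    goal: tuple[float, float] | None = None,
    goal_radius: float = 0.15,
) -> ArenaConfig:
    """Axis-aligned rectangle with corner at ``origin`` (multi-room fixtures)."""
    x0, y0 = origin
    boundary = np.array(
        [[x0, y0], [x0 + width, y0], [x0 + width, y0 + height], [x0, y0 + height]]
    )
    if goal is None:
        goal = (x0 + width / 2.0, y0 + height / 2.0)
    return ArenaConfig(
        boundary=boundary,
        landmarks=landmarks or [],
        goal=goal,
        goal_radius=goal_radius,
    )
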