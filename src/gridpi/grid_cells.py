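"""Grid cells by discretization, modulo compression and conjunction.

Each grid layer reads a *pair* of path-integration neurons.  The analog
activity of each is discretized over ``N_E`` bins, the bin index is
compressed by a modulo ``MG`` (a residue code), and the conjunction of the
two residues selects exactly one cell on an ``MG x MG`` phase torus.  As
the agent moves, the active phase tiles space periodically: spacing is set
by ``MG`` times the discretization bin size, orientation by the angular
separation of the paired neurons (60 degrees yields the hexagonal lattice),
and phase by the residue index.  An optional lateral-diffusion stage blurs
the one-hot code into a graded bump on the torus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .environment import angle_diff
from .path_integration import PIField, preferred_directions


def discretize(value, n_e: int, d_max: float):
    """Bin index floor(D * N_E / D_max); the top bin is closed.

    Accepts scalars or arrays.  Values outside [0, D_max] raise (the
    integrating field's clamp should prevent them).
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < -1e-12) or np.any(v > d_max + 1e-12):
        raise ValueError("value outside [0, d_max]")
    idx = np.minimum(np.floor(v * n_e / d_max).astype(int), n_e - 1)
    idx = np.maximum(idx, 0)
    return int(idx) if np.ndim(value) == 0 else idx


def modulo_project(bin_index, mg: int):
    """Residue of the discretization bin: phase = bin mod MG."""
    return np.mod(bin_index, mg) if np.ndim(bin_index) else int(bin_index) % mg


def _one_hot(mg: int, k1: int, k2: int) -> np.ndarray:
    g = np.zeros((mg, mg))
    g[k1, k2] = 1.0
    return g


@dataclass(frozen=True)
class GridLayerSpec:
    """One grid layer: a modulo applied to a pair of PI neurons.

    ``pi_pair`` indexes the two direction-tuned neurons whose discretized
    activities are conjoined; their angular separation sets the lattice
    geometry (60 degrees -> triangular/hexagonal).
    """

    modulo: int
    pi_pair: tuple[int, int]
    n_e: int = 60
    diffusion_sigma: float = 0.0

    def __post_init__(self):
        if not 1 < self.modulo <= self.n_e:
            raise ValueError("need 1 < modulo <= n_e")
        if self.pi_pair[0] == self.pi_pair[1]:
            raise ValueError("pi_pair must index two distinct neurons")
        if self.diffusion_sigma < 0:
            raise ValueError("diffusion_sigma must be >= 0")

    def pair_separation(self, n_pi: int) -> float:
        """Absolute angular separation of the paired directions, in (0, pi)."""
        theta = preferred_directions(n_pi)
        d = abs(angle_diff(theta[self.pi_pair[0]], theta[self.pi_pair[1]]))
        if not 0 < d < np.pi + 1e-12:
            raise ValueError("paired directions must differ by an angle in (0, pi)")
        return float(d)

    def bin_size_m(self, pi: PIField) -> float:
        """Spatial extent of one discretization bin along a paired axis."""
        return (pi.d_max / self.n_e) * pi.meters_per_unit / pi.alpha

    def spacing_m(self, pi: PIField) -> float:
        """Spatial period along each paired axis: MG bins."""
        return self.modulo * self.bin_size_m(pi)


def phase_pair(spec: GridLayerSpec, pi: PIField) -> tuple[int, int]:
    """Residue phases (k1, k2) of the paired neurons' current activities."""
    i, j = spec.pi_pair
    b1 = discretize(pi.d[i], spec.n_e, pi.d_max)
    b2 = discretize(pi.d[j], spec.n_e, pi.d_max)
    return modulo_project(b1, spec.modulo), modulo_project(b2, spec.modulo)


def grid_activity(spec: GridLayerSpec, pi: PIField) -> np.ndarray:
    """One-hot MG x MG phase activity for the layer (conjunction of residues)."""
    k1, k2 = phase_pair(spec, pi)
    g = np.zeros((spec.modulo, spec.modulo))
    g[k1, k2] = 1.0
    return g


def phase_history(spec: GridLayerSpec, d_history: np.ndarray, d_max: float) -> np.ndarray:
    """Vectorized (T, 2) residue phases from a (T, N) PI history."""
    i, j = spec.pi_pair
    b = discretize(d_history[:, [i, j]], spec.n_e, d_max)
    return np.mod(b, spec.modulo)


def torus_gaussian_kernel(sigma: float, size: int) -> np.ndarray:
    """2D Gaussian kernel truncated at 3 sigma, at most the torus size."""
    half = min(int(np.ceil(3 * sigma)), size // 2)
    ax = np.arange(-half, half + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    return np.outer(k1, k1)


def diffuse(activities: np.ndarray, sigma: float) -> np.ndarray:
    """Lateral diffusion on the phase torus.

    Circular Gaussian smoothing (wrap-around convolution, kernel truncated
    at 3 sigma) followed by renormalization to peak 1, so the winner keeps
    value 1 and its torus neighbours acquire graded activity in [0, 1].
    ``sigma = 0`` is the identity.
    """
    if sigma == 0:
        return activities.copy()
    kern = torus_gaussian_kernel(sigma, min(activities.shape))
    out = convolve(activities, kern, mode="wrap")
    m = out.max()
    return out / m if m > 0 else out


def grid_from_position(p, spec: GridLayerSpec, pi: PIField) -> np.ndarray:
    """Position-based oracle: phase activity computed directly from (x, y).

    Projects the displacement-from-reset onto the two paired directions and
    applies discretization + modulo, bypassing temporal integration.  In
    signed mode this must equal :func:`grid_activity` after noise-free
    integration of any path ending at ``p``.
    """
    d = pi.state_for_displacement(p[0], p[1])
    i, j = spec.pi_pair
    k1 = modulo_project(discretize(d[i], spec.n_e, pi.d_max), spec.modulo)
    k2 = modulo_project(discretize(d[j], spec.n_e, pi.d_max), spec.modulo)
    g = np.zeros((spec.modulo, spec.modulo))
    g[k1, k2] = 1.0
    return g


def default_layers(
    moduli: tuple[int, ...] = (4, 9, 25),
    n_pi: int = 60,
    n_e: int = 60,
    separation_index: int | None = None,
    diffusion_sigma: float = 0.0,
) -> list[GridLayerSpec]:
    """Reference layer set: moduli {4, 9, 25} on 60 discretization bins.

    Pairs are separated by 60 degrees (``n_pi/6`` index steps) — the
    separation that yields hexagonal rather than square lattices — and each
    layer uses a rotated pair so place-cell plateau boundaries are staggered
    across layers.
    """
    if separation_index is None:
        separation_index = n_pi // 6
    layers = []
    for n, mg in enumerate(moduli):
        base = (2 * n) % n_pi
        layers.append(
            GridLayerSpec(
                modulo=mg,
                pi_pair=(base, (base + separation_index) % n_pi),
                n_e=n_e,
                diffusion_sigma=diffusion_sigma,
            )
        )
    return layers


class GridPopulation:
    """A set of grid layers sharing one PI field."""

    def __init__(self, layers: list[GridLayerSpec]):
        if not layers:
            raise ValueError("at least one layer required")
        self.layers = list(layers)
        # diffusing a one-hot is a translation of one template on the torus
        self._templates = [
            diffuse(_one_hot(spec.modulo, 0, 0), spec.diffusion_sigma)
            for spec in self.layers
        ]

    @property
    def n_cells(self) -> int:
        return sum(l.modulo**2 for l in self.layers)

    def activities(self, pi: PIField, diffused: bool = False) -> list[np.ndarray]:
        """Per-layer MG x MG activity (one-hot, or diffused if requested)."""
        out = []
        for spec, tmpl in zip(self.layers, self._templates):
            k1, k2 = phase_pair(spec, pi)
            if diffused and spec.diffusion_sigma > 0:
                g = np.roll(tmpl, (k1, k2), axis=(0, 1))
            else:
                g = _one_hot(spec.modulo, k1, k2)
            out.append(g)
        return out

    def flat_activities(self, pi: PIField, diffused: bool = False) -> np.ndarray:
        """All layers concatenated into one vector (length ``n_cells``)."""
        return np.concatenate([g.ravel() for g in self.activities(pi, diffused)])

    def phase_histories(self, d_history: np.ndarray, d_max: float) -> list[np.ndarray]:
        return [phase_history(spec, d_history, d_max) for spec in self.layers]


@dataclass
class RandomProjectionPopulation:
    """Generalized entorhinal cells: products of random modulo matches.

    Each cell picks ``fan_in`` PI neurons at random, assigns each a random
    scale (modulo) and a random target residue, and fires when every chosen
    neuron's discretized activity matches its target residue — a product of
    modulo match indicators.  Rate maps of such a population exhibit a
    variety of spatial patterns, including grid-like ones.
    """

    indices: list[np.ndarray]
    scales: list[np.ndarray]
    targets: list[np.ndarray]
    n_e: int = 60

    @classmethod
    def sample(
        cls,
        n_pi: int,
        n_cells: int,
        seed: int,
        fan_in: tuple[int, ...] = (2, 3),
        scale_range: tuple[int, int] = (3, 12),
        n_e: int = 60,
    ) -> "RandomProjectionPopulation":
        rng = np.random.default_rng(seed)
        idx, scl, tgt = [], [], []
        for _ in range(n_cells):
            f = int(rng.choice(fan_in))
            ii = rng.choice(n_pi, size=f, replace=False)
            ss = rng.integers(scale_range[0], scale_range[1] + 1, size=f)
            tt = np.array([rng.integers(0, s) for s in ss])
            idx.append(ii)
            scl.append(ss)
            tgt.append(tt)
        return cls(indices=idx, scales=scl, targets=tgt, n_e=n_e)

    @property
    def n_cells(self) -> int:
        return len(self.indices)

    def activities(self, d_history: np.ndarray, d_max: float) -> np.ndarray:
        """(T, n_cells) binary activities from a (T, N) PI history."""
        bins = discretize(d_history, self.n_e, d_max)
        out = np.empty((d_history.shape[0], self.n_cells))
        for c in range(self.n_cells):
            match = np.mod(bins[:, self.indices[c]], self.scales[c]) == self.targets[c]
            out[:, c] = np.all(match, axis=1)
        return out
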