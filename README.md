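# gridpi

Grid cells from modulo-compressed path integration, with visual
recalibration and multimodal place cells, in a closed-loop 2D agent
simulator.

## The problem

Grid cells of the dorsomedial entorhinal cortex fire on a hexagonal
lattice that tiles the explored environment.  Most models make grid cells
compute path integration themselves (attractor dynamics or oscillatory
interference).  `gridpi` implements the alternative hypothesis that grid
activity is a *compression* of a path-integration code maintained
elsewhere: a 1D ring of neurons accumulates heading-weighted displacement
into a homing-vector population, and grid cells arise from nothing more
than discretizing pairs of those neurons and taking residues.

The package is written for computational neuroscientists and roboticists
who want to run the full closed sensory-motor loop on a desk: arena and
trajectory synthesis with configurable compass/odometry noise, the
path-integration field, the residue grid code, visual place cells that
recalibrate the integrator, multimodal place-cell fusion, homing from
place-action associations, kidnapping protocols, and the standard
rate-map / autocorrelogram / gridness analysis pipeline.

## The model

**Path integration.**  A ring of `N = 60` neurons with preferred
directions `θᵢ = −2πi/N` receives the heading `ϕ(t)` through a cosine
input field, `Vᵢ = 1 + cos(ϕ − θᵢ)`, and accumulates it into an
integrating field with gain `α` and rectification,
`Dᵢ(t) = [Dᵢ(t−1) + α·Vᵢ]⁺`, clamped at `D_max`.  Because the `1+` offset
adds total path length to every neuron, the package also provides a
*signed-projection* mode (`Vᵢ = cos(ϕ − θᵢ)`, stored with offset
`D_max/2`) in which each `Dᵢ` is a pure function of the net displacement
— the regime in which the hexagonal patterns below are attainable.  A
binary signal resets the field, or overwrites it with a stored profile
(recalibration).

**Grid cells.**  For a pair of ring neurons `(i, j)` separated by 60°,
each activity is discretized over `N_E` bins, `e = ⌊D·N_E/D_max⌋`,
compressed by a modulo, `k = e mod MG`, and the conjunction of the two
residues activates one cell of an `MG × MG` phase torus.  Spacing is set
by `MG ×` bin size, orientation by the pair separation (60° gives the
triangular lattice), phase by the residue index.  Reference layers use
moduli {4, 9, 25} on 60 bins.  Optional lateral diffusion (a circular
Gaussian on the torus) makes the one-hot code graded.

**Place cells and recalibration.**  Visual place cells (VPC) recognize
stored landmark–azimuth constellations with Gaussian azimuth tuning.  A
normalized least-mean-squares readout predicts the visual activity from
the grid vector (`PredVPC = w·G`, winner-gated updates normalized by
`ΣG²`), and multimodal place cells fuse the two:
`MPC = η·VPC + (1−η)·PredVPC`, `η = 0.5`.  When the visual winner clears
an absolute threshold and a margin over the runner-up, its stored
path-integration profile is written back into the field — bounding the
integrator's drift at well-recognized places.

## A worked example

```bash
python examples/01_random_walk_grid_map.py
```

prints

```
path length        : 400.0 m over 2000 s
tracked phase cell : (k1, k2) = (0, 0) of the modulo-9 torus
lattice spacing    : 1.20 m along each paired axis
gridness score     : 0.83
rotational curve   : r(60)=0.84, r(90)=-0.04, r(120)=0.82
```

A 2000 s noise-free walk in the 4 m hexagonal arena drives the
signed-mode integrator; the modulo-9 layer's most-visited phase cell is
rate-mapped (5 cm bins), autocorrelated, and rotated against itself.
Rotational correlations near 0.84 at 60° and 120° against −0.04 at 90°
give gridness `min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀) = 0.83`: a clean
hexagonal lattice with the predicted 1.2 m axis period (`MG = 9` × the
0.133 m discretization bin).

The other scripts in `examples/` walk through homing
(`02_homing_attraction_basin.py`), drift versus recalibration
(`03_recalibration_vs_drift.py`), the three-step place-field stair
(`04_place_cell_stair.py`), the two-room kidnapping protocol
(`05_multiroom_kidnapping.py`), and random-projection entorhinal cells
(`06_random_projection_variety.py`).

A thin CLI wraps the experiment presets:

```bash
gridpi simulate run --preset exp2 --seed 42 --out runs/exp2
gridpi analyze gridness --in ratemap.csv
```

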