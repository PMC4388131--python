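# Methods

This note documents the model, the synthetic study conditions, the
numerical choices, and the limitations of the `gridpi` simulator.  It is
the package's own account; every number quoted here is computed by the
test suite or the example scripts.

## Path integration on a ring

Heading enters a circular field of `N = 60` neurons (preferred directions
`θᵢ = −2πi/N`) as a cosine bump and is accumulated, scaled by the step
length, into the integrating field `D`.  Two accumulation modes coexist:

* **as-printed** — `Vᵢ = 1 + cos(ϕ − θᵢ)`, rectified accumulation.  The
  non-negative offset adds the *total path length* to every neuron, so a
  single neuron's value is path-dependent.  This mode is kept because it
  is the literal rate equation of the architecture, and its readout (the
  winner's direction, and activity relative to the population floor) is
  still a valid homing vector.
* **signed-projection** (default for grid experiments) —
  `Vᵢ = cos(ϕ − θᵢ)` accumulated with sign, stored with a fixed offset
  `D_max/2` so values stay in `[0, D_max]`.  Each neuron then holds an
  affine image of the net displacement projected on its preferred
  direction: the field is a pure position code.  Closed paths return the
  field to its start to ~1e−15 (tested at 1e−9), and the incremental code
  agrees with the closed-form position code on 100 random paths.

The tension between the two is intrinsic to the rate equation: the
documented behaviour ("the winner's level is proportional to distance
travelled") holds exactly only in the signed variant, which is why the
hexagonal-lattice experiments run in signed mode.

Scaling: `α = 0.01`, `D_max = 1`; `meters_per_unit` is chosen per arena so
the field spans twice the arena diameter (`PIField.for_arena`), leaving
headroom for excursions from any recalibration anchor.  Saturation is a
hard clamp; distances decode as `(D − zero)·meters_per_unit/α`.

## The residue grid code

Each grid layer discretizes a *pair* of ring neurons over `N_E = 60` bins
and keeps the residues modulo `MG ∈ {4, 9, 25}`; the conjunction selects
one cell on an `MG × MG` torus.  The geometry follows from the code: bin
size `b = (D_max/N_E)·meters_per_unit/α` (0.133 m in the 4 m arena),
period `MG·b` along each paired axis, lattice constant `MG·b/sin 60°`.
The 60° pair separation is the one that yields a triangular (hexagonal)
lattice; 90° would give squares.  Each layer uses a rotated pair so that
place-cell plateau boundaries are staggered.  The top discretization bin
is closed (`D = D_max → bin N_E−1`).

Lateral diffusion is a circular Gaussian on the phase torus, truncated at
3σ and renormalized to peak 1, keeping activities in [0, 1] with the
winner preserved; unit-mass normalization was the alternative and was
rejected to keep the declared [0, 1] activity range.  Diffusing a one-hot
is implemented as a translation of a precomputed template.

The generalized variant (`RandomProjectionPopulation`) draws, per cell,
2–3 random ring neurons, scales uniform in {3, …, 12}, and a random
target residue per input; the cell is the product of the modulo match
indicators.  Screening the most active 30 of 200 such cells over a
20,000-step walk yields both positive- and negative-gridness cells.

## Sensors and the drift model

The compass model has three terms: white jitter (sd 1°, the nominal
accuracy of a magnetic compass), a slow AR(1) bias (stationary sd 2°,
correlation time ~2 min), and a *heading-dependent* one-cycle deviation
`A·sin(ϕ − ϕ₀)` with `A = 2°` and a random fixed phase per run — the
classic deviation curve of a compass on a magnetized chassis.  Odometry
has 2% multiplicative step noise, clamped at zero (a wheel does not roll
backward during a forward command).

The deviation term matters and is worth a remark.  In a bounded arena,
any *rotation-like* compass error (white, or slowly varying offset)
produces a position error bounded by `bias × arena size` — integrating
white 1° noise for 30 minutes leaves the estimate within centimeters.  A
heading-dependent deviation, in contrast, makes closed loops fail to
close, so the integrator drifts linearly with path length, at about
`(A/2)·speed` per second.  With `A = 2°` and 0.2 m/s this is ~1 m per
4–5 minutes — the horizon on which the uncalibrated grid pattern
degrades, which is the study condition the noise defaults are required to
emulate.  These magnitudes are free parameters of the simulator, fixed
once from this physical argument.

Motion: constant speed 0.2 m/s, `dt = 0.1 s`, heading random walk with
sd 0.1 rad/step, and a reflective deflection toward the arena centroid
when a 0.4 m look-ahead probe leaves the boundary (the reflex obstacle
avoidance of the 40 cm-range proximity sensors it stands in for).

## Vision, recalibration, homing

Visual place cells replace an image-processing front end with Gaussian
azimuth tuning over stored landmark constellations (σ = 10°); activity is
the mean over the cell's stored landmarks of `exp(−Δaz²/2σ²)` for
matching landmark identities.  This preserves exactly the constellation
(identity × azimuth) structure of the recognition code while skipping
pixels.  The emulated camera takes 15 views per panorama with 5 landmarks
each (75 landmarks); the synthetic arenas use 4–12 point landmarks
instead, which changes the field smoothness but not the code.

Recalibration fires when the visual winner clears both an absolute
threshold and a margin over the runner-up; the winner's stored PI profile
is written into the field.  Defaults are `thr_abs = 0.7`,
`thr_rel = 0.15`; the multi-room experiments raise `thr_abs` to 0.85
because the reset zone must be narrow for the mechanism to help — at 0.7
the zone covered about a third of the learned path and froze the
integrator there.

Homing stores one action direction per ring place cell (six places around
the goal, each pointing at it); the winner's action is the motor command,
and the goal cell itself stores no action (arrival is signalled by the
goal-zone detector, a 0.15 m radius standing in for the floor-color
sensor).  All 56 starts of a 10×10 grid reach the goal zone.

## The multi-room fixture

Two 8 m rooms joined by a corridor (32 × 6 m).  Room-2 landmarks are
room-1's constellation translated by 22 m, perturbed by 0.8 m, and mapped
to the same appearance classes, so vision confuses the rooms (twin
activity ~0.6 at the aliased location) while the *local* cell still wins
every winner-take-all along the path; corridor landmarks are unique.
Visibility is limited to 9 m so each room is seen through its own cues.
The perturbation magnitude is the one free knob of the fixture: much
smaller and the aliased twin wins competitions in the far room, which
poisons the NLMS weights (only winners update, so a spurious association
is never unlearned); much larger and the rooms stop being ambiguous.

Nineteen places at 1.5 m spacing are recruited in a first pass with
learning gated off (every cell must exist before associative training),
followed by three NLMS training passes (`λ = 0.5`).  The multi-room model
uses `N_E = 120`: the grid place fields must resolve the 1.5 m place
spacing, and field width scales with the discretization bin (the same
scaling the discretization sweep demonstrates).  Kidnap protocols lift
the agent between places (fractional place indices): kidnapping from
exactly a place centre would put the old-frame grid prediction exactly at
its trained peak, a knife-edge instant a physical transport never hits.

## Analysis pipeline

Rate maps: occupancy-normalized mean activity on 5 cm square bins,
mask-aware Gaussian smoothing (σ = 5 cm); unvisited bins are masked, not
zero.  The spatial autocorrelogram is the masked Pearson correlation at
every 2D lag (FFT-aggregated sums; lags with fewer than 20 overlapping
bins are masked); evenness, exact in exact arithmetic, is enforced
against FFT round-off by averaging with the point reflection, and the
zero-lag value is set to its analytic value 1.  The
rotational-correlation curve correlates the autocorrelogram with itself
rotated 0–180° in 1° steps over an annulus that excludes the central peak
(inner radius: first zero crossing of the radial profile; outer: map
radius); 0° is the identity and 180° is computed as an exact index flip,
so both endpoints are 1.  Gridness is
`min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀)`; a curve undefined at the probe
angles reports 0 with a degeneracy flag.  Peak detection on the curve
requires a prominence of 20% of the curve range, so sampling wiggles do
not count as lattice maxima.

Place-field width is the extent of the contiguous above-half-maximum run
containing the peak, counting one sample spacing per sample (a
rectangular pulse of extent w measures w).

## Problem sizes

The bundled experiments run at desk scale: 30 simulated minutes
(18,000 steps) for the drift studies, 50,000 steps for the
hexagonal-periodicity measurement, 20,000 steps for screenings, 19 places
over 27 m for the multi-room protocols, and a 200-cell random-projection
population screened on its 30 most active cells.  These sizes leave every
qualitative contrast (drift ordering, stair shape, kidnap recovery)
clearly resolved.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the robot's sensorium —
constellation-coded vision with perceptual aliasing, compass-anchored
azimuths, drifting odometry — but not its content: there are no images,
no ultrasound profiles, no dynamic obstacles, and landmark recognition is
error-free apart from geometry.  Passing tests therefore establish that
the architecture's mechanisms behave as documented under controlled
conditions (drift is bounded by recalibration, fusion disambiguates
aliased vision, kidnaps are recovered); they do not establish robustness
to real perception errors.  Heading is supplied directly with noise: the
dynamic-neural-field head-direction model is out of scope, as are
learned grid conjunctions, conjunctive grid × heading cells, and online
adaptation of the fusion weight η (fixed at 0.5, configurable).
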