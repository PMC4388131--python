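"""Spatial firing analysis: rate maps, autocorrelograms, gridness.

The pipeline mirrors standard rodent grid-cell analysis: bin the
trajectory into square spatial bins, occupancy-normalize the cell's
activity, smooth with a Gaussian, compute the masked Pearson spatial
autocorrelogram, rotate it against itself in 1-degree steps, and summarize
hexagonality as the gridness score
``min(r60, r120) - max(r30, r90, r150)``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.signal import fftconvolve


@dataclass
class RateMap:
    """Occupancy-normalized firing map over square spatial bins.

    ``rates`` is (ny, nx) with NaN in never-visited bins (masked, not
    zero); ``origin`` is the world position of the (0, 0) bin corner.
    """

    rates: np.ndarray
    bin_size: float
    origin: tuple[float, float]

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.rates)

    def to_csv(self, path: str) -> None:
        """Matrix CSV plus a JSON sidecar (bin size, origin, mask encoding)."""
        np.savetxt(path, self.rates, delimiter=",", fmt="%.9g")
        with open(path + ".json", "w") as fh:
            json.dump(
                {
                    "bin_size": self.bin_size,
                    "origin": list(self.origin),
                    "mask_encoding": "nan",
                },
                fh,
            )

    @classmethod
    def from_csv(cls, path: str) -> "RateMap":
        rates = np.loadtxt(path, delimiter=",", ndmin=2)
        try:
            with open(path + ".json") as fh:
                side = json.load(fh)
        except FileNotFoundError:
            side = {"bin_size": 1.0, "origin": [0.0, 0.0]}
        return cls(rates=rates, bin_size=float(side["bin_size"]), origin=tuple(side["origin"]))


def rate_map(
    x: np.ndarray,
    y: np.ndarray,
    activity: np.ndarray,
    bin_size: float = 0.05,
    smooth_sigma: float = 0.05,
    extent: tuple[float, float, float, float] | None = None,
) -> RateMap:
    """Occupancy-normalized, Gaussian-smoothed firing map.

    Each bin holds the mean activity over the samples falling in it;
    smoothing is mask-aware (the Gaussian is normalized over visited bins
    only), so a spatially constant activity yields a constant map and the
    result is invariant to uniform oversampling of the same path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    activity = np.asarray(activity, float)
    if len(x) == 0:
        raise ValueError("empty trajectory")
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_size)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size)), 1)
    ix = np.clip(((x - x0) / bin_size).astype(int), 0, nx - 1)
    iy = np.clip(((y - y0) / bin_size).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    counts = np.bincount(flat, minlength=ny * nx).reshape(ny, nx).astype(float)
    sums = np.bincount(flat, weights=activity, minlength=ny * nx).reshape(ny, nx)
    visited = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(visited, sums / np.maximum(counts, 1), 0.0)
    if smooth_sigma > 0:
        s = smooth_sigma / bin_size
        num = gaussian_filter(np.where(visited, rates, 0.0), s)
        den = gaussian_filter(visited.astype(float), s)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(visited, num / den, np.nan)
    else:
        rates = np.where(visited, rates, np.nan)
    return RateMap(rates=rates, bin_size=bin_size, origin=(x0, y0))


def spatial_autocorrelation(rmap: RateMap | np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Masked Pearson spatial autocorrelogram.

    For every 2D lag, the Pearson correlation between the map and its
    shifted copy is computed over the overlapping *visited* bins (FFT-based
    aggregation).  Lags whose overlap falls below ``min_overlap`` bins are
    NaN.  The output has extent ``2W-1`` per axis; its centre (zero lag)
    is 1, and the matrix is even (point-symmetric) — evenness, exact in
    exact arithmetic, is enforced against FFT round-off by averaging with
    the point reflection.
    """
    rates = rmap.rates if isinstance(rmap, RateMap) else np.asarray(rmap, float)
    m = np.isfinite(rates).astype(float)
    if m.sum() < 2:
        raise ValueError("need at least 2 unmasked bins")
    f = np.where(np.isfinite(rates), rates, 0.0)

    def corr(a, b):
        return fftconvolve(a, b[::-1, ::-1], mode="full")

    n = corr(m, m)
    sxy = corr(f, f)
    sx = corr(f, m)
    sy = corr(m, f)
    sxx = corr(f**2, m)
    syy = corr(m, f**2)
    n_r = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        var_x = n * sxx - sx**2
        var_y = n * syy - sy**2
        den = np.sqrt(np.maximum(var_x, 0.0) * np.maximum(var_y, 0.0))
        ac = num / den
    ac[(n_r < min_overlap) | (den <= np.finfo(float).eps * np.abs(n) * 10)] = np.nan
    ac = np.clip(ac, -1.0, 1.0)
    ac_flip = ac[::-1, ::-1]
    both = np.isfinite(ac) & np.isfinite(ac_flip)
    ac = np.where(both, 0.5 * (ac + ac_flip), np.where(np.isfinite(ac), ac, ac_flip))
    cy, cx = (np.array(ac.shape) - 1) // 2
    if np.isfinite(ac[cy, cx]):
        ac[cy, cx] = 1.0
    return ac


def _central_peak_radius(ac: np.ndarray) -> float:
    """Radius of the central peak: first zero crossing of the radial profile."""
    cy, cx = (np.array(ac.shape) - 1) // 2
    yy, xx = np.indices(ac.shape)
    r = np.hypot(yy - cy, xx - cx)
    if not np.isfinite(ac).any():
        return 1.0  # fully masked (e.g. constant map): degenerate downstream
    rmax = int(r[np.isfinite(ac)].max())
    for radius in range(1, rmax + 1):
        ring = ac[(r >= radius - 0.5) & (r < radius + 0.5)]
        ring = ring[np.isfinite(ring)]
        if ring.size and np.mean(ring) <= 0:
            return float(radius)
    return max(rmax / 4.0, 1.0)


def rotational_correlation(
    ac: np.ndarray,
    step: float = 1.0,
    inner_radius: float | None = None,
    outer_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of the rotated autocorrelogram against itself.

    Angles run from 0 to 180 degrees in ``step``-degree increments.  The
    comparison is restricted to a circular annulus excluding the central
    peak (inner radius defaults to the first zero crossing of the radial
    profile; outer radius to the map radius).  0 degrees is the identity
    (correlation 1 by construction); 180 degrees is computed as an exact
    array point reflection, so the even symmetry of the autocorrelogram
    makes it 1 to machine precision.  Other angles use bilinear
    interpolation.  Returns ``(angles_deg, correlations)``.
    """
    ac = np.asarray(ac, float)
    cy, cx = (np.array(ac.shape) - 1) / 2.0
    yy, xx = np.indices(ac.shape)
    r = np.hypot(yy - cy, xx - cx)
    if inner_radius is None:
        inner_radius = _central_peak_radius(ac)
    if outer_radius is None:
        outer_radius = min(cy, cx)
    valid = np.isfinite(ac)
    sel = valid & (r >= inner_radius) & (r <= outer_radius)
    pts_y = yy[sel].astype(float)
    pts_x = xx[sel].astype(float)
    base = ac[sel]
    filled = np.where(valid, ac, 0.0)
    vmask = valid.astype(float)

    angles = np.arange(0.0, 180.0 + 1e-9, step)
    out = np.empty(angles.size)
    flip = ac[::-1, ::-1]
    for k, a_deg in enumerate(angles):
        if a_deg == 0.0:
            out[k] = 1.0
            continue
        if a_deg == 180.0:
            rot_vals = flip[sel]
            ok = np.isfinite(rot_vals)
        else:
            a = np.deg2rad(a_deg)
            ca, sa = np.cos(a), np.sin(a)
            ry = cy + (pts_y - cy) * ca - (pts_x - cx) * sa
            rx = cx + (pts_y - cy) * sa + (pts_x - cx) * ca
            rot_vals = map_coordinates(filled, [ry, rx], order=1, cval=0.0)
            rot_ok = map_coordinates(vmask, [ry, rx], order=1, cval=0.0)
            ok = rot_ok > 0.999
        if ok.sum() < 3:
            out[k] = np.nan
            continue
        a_v = base[ok]
        b_v = rot_vals[ok]
        a_c = a_v - a_v.mean()
        b_c = b_v - b_v.mean()
        den = np.sqrt((a_c @ a_c) * (b_c @ b_c))
        out[k] = (a_c @ b_c) / den if den > 0 else np.nan
    return angles, out


@dataclass
class GridnessResult:
    autocorrelation: np.ndarray
    angles_deg: np.ndarray
    curve: np.ndarray
    score: float
    degenerate: bool = False

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle_deg": self.angles_deg, "pearson_r": self.curve})


def gridness(angles_deg: np.ndarray, curve: np.ndarray) -> tuple[float, bool]:
    """Gridness score from the rotational-correlation curve.

    ``min(r60, r120) - max(r30, r90, r150)``; positive for hexagonal
    patterns, negative for stripes (90-degree symmetry).  A curve with
    undefined values at the probe angles is degenerate and scores 0.
    """
    def at(a):
        idx = int(np.argmin(np.abs(np.asarray(angles_deg) - a)))
        return curve[idx]

    on = [at(60), at(120)]
    off = [at(30), at(90), at(150)]
    vals = on + off
    if any(not np.isfinite(v) for v in vals) or np.ptp(vals) < 1e-12:
        return 0.0, True
    return float(min(on) - max(off)), False


def gridness_from_rate_map(rmap: RateMap, step: float = 1.0) -> GridnessResult:
    """Full pipeline: autocorrelogram, rotational curve, gridness score."""
    ac = spatial_autocorrelation(rmap)
    angles, curve = rotational_correlation(ac, step=step)
    score, degenerate = gridness(angles, curve)
    return GridnessResult(
        autocorrelation=ac, angles_deg=angles, curve=curve, score=score, degenerate=degenerate
    )


def place_field_width(
    distance: np.ndarray, activity: np.ndarray, threshold: float = 0.5
) -> float:
    """Width of the field crossing at ``threshold`` x peak.

    ``distance`` is the 1D position along the path.  The width is the
    extent of the contiguous run of samples at or above the threshold that
    contains the peak (one sample-spacing per sample, so a rectangular
    pulse of extent w measures w).  Returns 0 when nothing reaches the
    threshold.
    """
    d = np.asarray(distance, float)
    a = np.asarray(activity, float)
    if a.size == 0 or np.nanmax(a) <= 0:
        return 0.0
    peak = np.nanmax(a)
    above = a >= threshold * peak
    if not above.any():
        return 0.0
    i = int(np.nanargmax(a))
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < a.size - 1 and above[hi + 1]:
        hi += 1
    spacing = np.median(np.diff(d)) if d.size > 1 else 1.0
    return float((hi - lo + 1) * spacing)
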