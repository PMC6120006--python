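"""Liquid-state observables from trajectories.

* radial distribution function g(r) of molecular centres (minimum-image
  pair histogram normalised by the ideal-gas shell count);
* velocity autocorrelation function C_v(t) = <v(t).v(0)> / <v(0)^2> of
  the centre-of-mass velocities, averaged over molecules and time origins;
* Green-Kubo self-diffusion D = (1/3) integral <v(t).v(0)> dt, with an
  independent mean-squared-displacement estimate as a cross-check.

Units: distances A, times ps, D reported in 1e-9 m^2/s (1 A^2/ps = 10 of
those).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .md import Trajectory
from .units import DIFFUSION_UNIT

__all__ = [
    "RDFResult",
    "VAFResult",
    "rdf",
    "first_peak",
    "vaf",
    "green_kubo_diffusion",
    "msd_diffusion",
]


@dataclass
class RDFResult:
    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    n_frames: int
    density: float  # number density, 1/A^3


@dataclass
class VAFResult:
    lags: np.ndarray            # ps
    c: np.ndarray               # normalised C_v
    v2: float                   # <v(0)^2>, A^2/ps^2
    n_origins: int


def rdf(trajectory: Trajectory, bin_width: float = 0.1,
        r_max: float | None = None) -> RDFResult:
    """Centre-of-mass radial distribution function.

    g(r) -> 1 at large r; the first-shell structure of the liquid shows as
    a peak near the effective potential minimum.
    """
    box = trajectory.box_edge
    if r_max is None:
        r_max = 0.5 * box
    if r_max > 0.5 * box + 1e-9:
        raise ValueError("r_max must not exceed half the box edge")
    frames = trajectory.positions
    if len(frames) < 1:
        raise ValueError("trajectory has no frames")
    n = trajectory.n_molecules
    nbins = int(round(r_max / bin_width))
    hist = np.zeros(nbins)
    iu = np.triu_indices(n, 1)
    for pos in frames:
        d = pos[iu[0]] - pos[iu[1]]
        d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(axis=1))
        h, _ = np.histogram(r, bins=nbins, range=(0.0, nbins * bin_width))
        hist += h
    volume = box**3
    rho = n / volume
    edges = np.arange(nbins + 1) * bin_width
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = shell * rho * (n - 1) / 2.0 * len(frames)
    g = hist / ideal
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(bin_centers=centers, g=g, bin_width=bin_width,
                     n_frames=len(frames), density=rho)


def first_peak(result: RDFResult, threshold: float = 1.5):
    """Height and position of the first maximum of g(r), refined by
    parabolic interpolation through the top bin and its neighbours."""
    g = result.g
    above = np.nonzero(g > threshold)[0]
    if len(above) == 0:
        raise ValueError("radial distribution function has no peak above "
                         f"{threshold}; featureless input")
    # first local maximum after the first crossing of the threshold
    i = above[0]
    while i + 1 < len(g) and g[i + 1] >= g[i]:
        i += 1
    if i == 0 or i + 1 >= len(g):
        raise ValueError("peak lies at the histogram edge")
    y0, y1, y2 = g[i - 1], g[i], g[i + 1]
    denom = y0 - 2 * y1 + y2
    dx = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    height = y1 - 0.25 * (y0 - y2) * dx
    position = result.bin_centers[i] + dx * result.bin_width
    return float(height), float(position)


def vaf(trajectory: Trajectory, max_lag: float = 0.5,
        origin_stride: int = 5) -> VAFResult:
    """Normalised centre-of-mass velocity autocorrelation function.

    Averages over all molecules and over time origins spaced
    ``origin_stride`` velocity samples apart.  C_v(0) = 1 by construction.
    """
    v = trajectory.velocities
    if v.size == 0:
        raise ValueError("trajectory carries no velocity samples")
    dt = trajectory.dt_velocities
    nlag = int(round(max_lag / dt))
    if nlag >= len(v):
        raise ValueError("max_lag exceeds the production length")
    origins = np.arange(0, len(v) - nlag, origin_stride)
    if len(origins) < 2:
        raise ValueError("too few time origins for the requested lag")
    c = np.empty(nlag + 1)
    for lag in range(nlag + 1):
        c[lag] = np.mean(np.sum(v[origins + lag] * v[origins], axis=2))
    v2 = c[0]
    return VAFResult(lags=np.arange(nlag + 1) * dt, c=c / v2, v2=float(v2),
                     n_origins=len(origins))


def green_kubo_diffusion(vaf_result: VAFResult, tail_tolerance: float = 0.05,
                         force: bool = False):
    """Self-diffusion coefficient from the Green-Kubo integral.

    D = (1/3) <v^2> integral C_v(t) dt (trapezoidal), in 1e-9 m^2/s.
    Refuses to integrate when the correlation tail has not decayed below
    ``tail_tolerance`` unless ``force`` is set.  Also returns the value at
    80% of the lag window as an upper-limit sensitivity estimate.
    """
    c = vaf_result.c
    if abs(c[-1]) > tail_tolerance and not force:
        raise ValueError(
            f"velocity correlations not decayed at the longest lag "
            f"(|C_v| = {abs(c[-1]):.3f} > {tail_tolerance}); extend the lag "
            "window or pass force=True")
    dt = vaf_result.lags[1] - vaf_result.lags[0]
    d_full = vaf_result.v2 * np.trapezoid(c, dx=dt) / 3.0 * DIFFUSION_UNIT
    i80 = max(2, int(0.8 * len(c)))
    d_80 = vaf_result.v2 * np.trapezoid(c[:i80], dx=dt) / 3.0 * DIFFUSION_UNIT
    return float(d_full), float(d_80)


def msd_diffusion(trajectory: Trajectory, t_min: float = 2.0,
                  t_max: float | None = None, origin_stride: int = 50) -> float:
    """Einstein-relation diffusion estimate from the mean-squared
    displacement slope over [t_min, t_max] ps; independent cross-check of
    the Green-Kubo route.  Returns D in 1e-9 m^2/s."""
    x = trajectory.unwrapped
    if x.size == 0:
        raise ValueError("trajectory carries no displacement samples")
    dt = trajectory.dt_velocities
    n = len(x)
    if t_max is None:
        t_max = min((n - 1) * dt / 2.0, 5 * t_min)
    imax = int(t_max / dt)
    if imax < 4 or imax >= n:
        raise ValueError("MSD window incompatible with trajectory length")
    origins = np.arange(0, n - imax, origin_stride)
    lags = np.arange(0, imax, max(1, imax // 50))
    msd = np.array([np.mean(np.sum((x[origins + i] - x[origins]) ** 2, axis=2))
                    for i in lags])
    tt = lags * dt
    sel = tt >= t_min
    if sel.sum() < 2:
        raise ValueError("no MSD points beyond t_min")
    slope = np.polyfit(tt[sel], msd[sel], 1)[0]
    return float(slope / 6.0 * DIFFUSION_UNIT)
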