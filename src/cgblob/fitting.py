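"""Effective single-site Morse parameterisation of the coarse-grained model.

The workflow mirrors how a united-atom potential is built for a molecular
liquid like C60: energy curves for a pair of molecules in fixed
face-to-face orientations are generated by exact all-atom summation of the
atomic pair potential, and a single-site Morse function

    U(R) = De [exp(-2 a (R - R0)) - 2 exp(-a (R - R0))]

scaled by N_A N_B (3600 for two C60 cages) is least-squares fitted to the
averaged curve, optionally through the truncated multipolar series (the
trial Morse supplies the radial coefficients, the molecule's moment
tensors the angular constants).  The width parameter ``alpha`` can be held
fixed; the fit window brackets the curve minimum to keep the steep
repulsive wall from dominating the unweighted residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .geometry import c60_face_axes
from .potentials import MorsePotential, PairPotential, radial_coefficient
from .quaternion import quat_from_axis_angle
from .series import (BlobState, TruncationScheme, allatom_energy,
                     angular_part_tensor, interblob_energy)
from .tensors import BlobTemplate, compute_moment_tensors, rotate_tensors

__all__ = [
    "PotentialCurve",
    "MorseFit",
    "scan_curve",
    "fit_morse",
    "series_theta_constants",
    "parameterize_cg",
]

_ORIENTATIONS = ("hex-hex", "hex-pent", "pent-pent")


@dataclass
class PotentialCurve:
    """A pair-energy curve: strictly increasing separations (A) against
    energies (kcal/mol), tagged with the orientation it was scanned in."""

    separations: np.ndarray
    energies: np.ndarray
    label: str = ""

    def __post_init__(self):
        r = np.asarray(self.separations, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if r.ndim != 1 or r.shape != e.shape:
            raise ValueError("separations and energies must be equal-length 1-D")
        if np.any(np.diff(r) <= 0):
            raise ValueError("separations must be strictly increasing")
        self.separations, self.energies = r, e

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.separations, self.energies]),
                   header=f"R(A)  E(kcal/mol)  [{self.label}]")

    @classmethod
    def load(cls, path, label: str = "") -> "PotentialCurve":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1], label=label or str(path))


@dataclass
class MorseFit:
    """Result of a Morse least-squares fit."""

    r0: float
    de: float
    alpha: float
    scale: float
    rms_residual: float
    window: tuple
    order: int | None = None
    covariance: np.ndarray | None = field(default=None, repr=False)

    def potential(self) -> MorsePotential:
        return MorsePotential(de=self.de, alpha=self.alpha, r0=self.r0)

    def report(self) -> str:
        lines = [
            "Morse fit",
            f"  R0    = {self.r0:.5f} A",
            f"  De    = {self.de:.6g} kcal/mol (x {self.scale:g} scale)",
            f"  alpha = {self.alpha:.4f} 1/A",
            f"  rms   = {self.rms_residual:.4g} kcal/mol "
            f"over window [{self.window[0]:.3f}, {self.window[1]:.3f}] A",
        ]
        if self.order is not None:
            lines.insert(1, f"  series order = {self.order}")
        return "\n".join(lines)


def _alignment_quaternion(axis: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``axis`` onto ``target``."""
    a = axis / np.linalg.norm(axis)
    b = target / np.linalg.norm(target)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(a @ b)
    if s < 1e-12:
        if c > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return quat_from_axis_angle(perp * np.pi)
    angle = np.arctan2(s, c)
    return quat_from_axis_angle(v / s * angle)


def _face_states(template_a: BlobTemplate, template_b: BlobTemplate,
                 orientation: str, r: float):
    axes = c60_face_axes()
    try:
        fa, fb = orientation.split("-")
        axis_a = axes[{"hex": "hexagon", "pent": "pentagon"}[fa]]
        axis_b = axes[{"hex": "hexagon", "pent": "pentagon"}[fb]]
    except (ValueError, KeyError):
        raise ValueError(
            f"unknown orientation {orientation!r}; expected one of {_ORIENTATIONS}")
    qa = _alignment_quaternion(axis_a, np.array([0.0, 0.0, 1.0]))
    qb = _alignment_quaternion(axis_b, np.array([0.0, 0.0, -1.0]))
    a = BlobState(template_a, [0.0, 0.0, 0.0], qa)
    b = BlobState(template_b, [0.0, 0.0, r], qb)
    return a, b


def scan_curve(template_a: BlobTemplate, template_b: BlobTemplate,
               potential: PairPotential, orientation: str,
               r_values, engine: str | TruncationScheme = "allatom"
               ) -> PotentialCurve:
    """Pair-energy curve at fixed face-to-face orientation.

    ``orientation`` is 'hex-hex', 'hex-pent' or 'pent-pent' (face of A
    pointing at face of B).  ``engine`` is 'allatom' for the exact double
    sum or a :class:`TruncationScheme` for the coarse-grained series.
    """
    r_values = np.asarray(r_values, dtype=float)
    energies = np.empty_like(r_values)
    for i, r in enumerate(r_values):
        a, b = _face_states(template_a, template_b, orientation, float(r))
        if engine == "allatom":
            energies[i] = allatom_energy(a, b, potential)
        elif isinstance(engine, TruncationScheme):
            energies[i] = interblob_energy(a, b, potential, engine)
        else:
            raise ValueError("engine must be 'allatom' or a TruncationScheme")
    tag = engine if isinstance(engine, str) else f"cg{engine.max_m}"
    return PotentialCurve(r_values, energies, label=f"{orientation}/{tag}")


def series_theta_constants(template: BlobTemplate, order: int) -> dict:
    """Angular constants Theta(mn) of a pair of identical isotropic blobs.

    Valid when the blob's moment tensors are rotation invariant (e.g. the
    icosahedral C60 cage), in which case Theta(mn) is independent of both
    orientations and of the direction of the centre line."""
    tensors = rotate_tensors(compute_moment_tensors(template, order), np.eye(3))
    if not tensors.is_isotropic(rtol=1e-6):
        raise ValueError("series_theta_constants requires an isotropic blob")
    zhat = np.array([0.0, 0.0, 1.0])
    return {(m, n): angular_part_tensor(tensors, tensors, zhat, m, n)
            for (m, n) in TruncationScheme.up_to(order)}


def _guess_minimum(curve: PotentialCurve):
    i = int(np.argmin(curve.energies))
    if i == 0 or i == len(curve.energies) - 1:
        raise ValueError("curve has no interior minimum; cannot fit a well")
    return curve.separations[i], curve.energies[i]


def fit_morse(curve: PotentialCurve, scale: float = 1.0,
              fix_alpha: float | None = None,
              window: tuple = (0.9, 1.6),
              theta: dict | None = None,
              order: int | None = None) -> MorseFit:
    """Least-squares Morse fit to a pair-energy curve.

    The model is ``scale * U_Morse(R)`` by default; when ``theta`` (the
    angular constants from :func:`series_theta_constants`) is given, the
    model is the truncated series generated by the trial Morse,
    sum_mn Theta(mn) V(mn)[U_trial](R), evaluated self-consistently.
    The unweighted residual is minimised over the window
    ``[window[0], window[1]] * R_min_guess`` bracketing the curve minimum.
    """
    if len(curve.separations) < 10:
        raise ValueError("need at least 10 curve points to fit")
    r_min_guess, e_min = _guess_minimum(curve)
    lo, hi = window[0] * r_min_guess, window[1] * r_min_guess
    sel = (curve.separations >= lo) & (curve.separations <= hi)
    r = curve.separations[sel]
    e = curve.energies[sel]
    de0 = max(-e_min / scale, 1e-12)
    alpha0 = fix_alpha if fix_alpha is not None else 1.0

    def series_model(rr, r0, de, alpha):
        pot = MorsePotential(de=de, alpha=alpha, r0=r0)
        if theta is None:
            return scale * pot(rr)
        out = np.zeros_like(rr)
        for (m, n), th in theta.items():
            if th:
                out = out + th * radial_coefficient(pot, rr, m, n)
        return out

    if fix_alpha is not None:
        def model(rr, r0, de):
            return series_model(rr, r0, abs(de), fix_alpha)
        p0 = (r_min_guess, de0)
    else:
        def model(rr, r0, de, alpha):
            return series_model(rr, r0, abs(de), abs(alpha))
        p0 = (r_min_guess, de0, alpha0)

    try:
        popt, pcov = curve_fit(model, r, e, p0=p0, maxfev=40000)
    except RuntimeError as exc:
        raise ValueError(f"Morse fit failed to converge: {exc}")
    resid = model(r, *popt) - e
    rms = float(np.sqrt(np.mean(resid**2)))
    alpha = fix_alpha if fix_alpha is not None else abs(popt[2])
    return MorseFit(r0=float(popt[0]), de=float(abs(popt[1])), alpha=float(alpha),
                    scale=scale, rms_residual=rms, window=(lo, hi),
                    order=order, covariance=pcov)


def parameterize_cg(template: BlobTemplate, atomic_potential: PairPotential,
                    order: int, r_values=None, fix_alpha: float | None = None,
                    orientations=_ORIENTATIONS) -> MorseFit:
    """Single-site Morse parameterisation of the coarse-grained model.

    Generates exact all-atom curves for the given face-to-face
    orientations, averages them with equal weights, and fits the
    order-``order`` truncated series generated by a trial single-site
    Morse to the averaged reference.  At order 0 the model is simply
    N_A N_B U_Morse(R).
    """
    if r_values is None:
        rad = 2.0 * template.radius
        r_values = np.linspace(0.8 * rad + 1.0, 2.3 * rad, 120)
    curves = [scan_curve(template, template, atomic_potential, o, r_values)
              for o in orientations]
    avg = PotentialCurve(np.asarray(r_values, dtype=float),
                         np.mean([c.energies for c in curves], axis=0),
                         label="orientation-averaged")
    theta = series_theta_constants(template, order)
    scale = float(template.n_atoms) ** 2
    return fit_morse(avg, scale=scale, fix_alpha=fix_alpha, theta=theta,
                     order=order)
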