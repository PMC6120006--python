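"""Atom-atom pair potentials with analytic high-order radial derivatives.

The multipolar series needs the radial coefficients

    V(mn) = 1 / (n! (m-n)!!) * R^n * (1/R d/dR)^((m+n)/2) U(R),

where (m, n) runs over pairs with m + n and m - n both even (n = m, m-2,
..., down to 0 or 1) and (m-n)!! is 1 when m = n.  The nested operator
(1/R d/dR)^k expands into a fixed linear combination of ordinary
derivatives,

    (1/R d/dR)^k U = sum_j c_{kj} U^(j) R^(j - 2k),

whose integer coefficients are generated once by recursion; both the Morse
and the Lennard-Jones potential supply exact derivatives of any order, so
V(mn) and its radial derivative (needed for forces) are analytic.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "PairPotential",
    "MorsePotential",
    "LennardJonesPotential",
    "radial_coefficient",
    "radial_coefficient_derivative",
    "lj_radial_closed_form",
    "valid_index_pairs",
    "double_factorial",
]


def double_factorial(n: int) -> int:
    """n!! with 0!! = (-1)!! = 1."""
    if n <= 0:
        return 1
    return math.prod(range(n, 0, -2))


def valid_index_pairs(max_m: int):
    """All (m, n) index pairs of the series with m <= max_m: n runs over
    m, m-2, ... down to 0 (m even) or 1 (m odd), so m+n and m-n are even."""
    return [(m, n) for m in range(max_m + 1) for n in range(m, -1, -2)]


@lru_cache(maxsize=None)
def _operator_coefficients(k: int):
    """Coefficients c_{kj} of (1/R d/dR)^k U = sum_j c_{kj} U^(j) R^(j-2k)."""
    coef = {0: 1.0}
    for kk in range(1, k + 1):
        nxt = {}
        for j, c in coef.items():
            nxt[j + 1] = nxt.get(j + 1, 0.0) + c
            w = j - 2 * kk + 2
            if w:
                nxt[j] = nxt.get(j, 0.0) + c * w
        coef = nxt
    return tuple(sorted(coef.items()))


class PairPotential:
    """Radial pair potential U(R) with analytic derivatives.

    Subclasses implement :meth:`derivative`; everything the series engine
    needs (radial coefficients and their gradients) is derived from it.
    """

    #: highest derivative order guaranteed analytic (arbitrary here)
    derivative_order_supported = 8

    def __call__(self, r):
        return self.derivative(r, 0)

    def derivative(self, r, order: int):  # pragma: no cover - interface
        raise NotImplementedError

    def nested_radial_operator(self, r, k: int):
        """(1/R d/dR)^k U evaluated analytically."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for j, c in _operator_coefficients(k):
            out = out + c * self.derivative(r, j) * r ** float(j - 2 * k)
        return out


class MorsePotential(PairPotential):
    """Morse potential U(R) = De [exp(-2 a (R - R0)) - 2 exp(-a (R - R0))].

    Parameters: well depth ``de`` (kcal/mol), width ``alpha`` (1/A) and
    equilibrium distance ``r0`` (A).  Every derivative is a combination of
    the same two exponentials.
    """

    kind = "morse"

    def __init__(self, de: float, alpha: float, r0: float):
        if de <= 0 or alpha <= 0 or r0 <= 0:
            raise ValueError("Morse parameters must be positive")
        self.de = float(de)
        self.alpha = float(alpha)
        self.r0 = float(r0)

    def derivative(self, r, order: int = 0):
        r = np.asarray(r, dtype=float)
        a = self.alpha
        e1 = np.exp(-a * (r - self.r0))
        return self.de * ((-2 * a) ** order * e1 * e1 - 2 * (-a) ** order * e1)

    def __repr__(self):
        return f"MorsePotential(de={self.de}, alpha={self.alpha}, r0={self.r0})"


class LennardJonesPotential(PairPotential):
    """Generalised Lennard-Jones U(R) = 4 eps [(s/R)^a - (s/R)^b], a > b > 0."""

    kind = "lennard_jones"

    def __init__(self, epsilon: float, sigma: float, exp_rep: float = 12.0,
                 exp_att: float = 6.0):
        if epsilon <= 0 or sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if not exp_rep > exp_att > 0:
            raise ValueError("exponents must satisfy a > b > 0")
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.exp_rep = float(exp_rep)
        self.exp_att = float(exp_att)

    def derivative(self, r, order: int = 0):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for sign, p in ((1.0, self.exp_rep), (-1.0, self.exp_att)):
            rising = math.prod(p + i for i in range(order))  # p(p+1)...(p+order-1)
            out = out + sign * (-1.0) ** order * rising * (self.sigma / r) ** p / r**order
        return 4.0 * self.epsilon * out

    def __repr__(self):
        return (f"LennardJonesPotential(epsilon={self.epsilon}, sigma={self.sigma},"
                f" exponents=({self.exp_rep}, {self.exp_att}))")


def _check_pair(m: int, n: int):
    if not 0 <= n <= m or (m + n) % 2 or (m - n) % 2:
        raise ValueError(f"invalid index pair (m, n) = ({m}, {n}): "
                         "m+n and m-n must both be even with 0 <= n <= m")


def radial_coefficient(potential: PairPotential, r, m: int, n: int):
    """Radial part V(mn) of the multipolar series at separation ``r`` (A).

    V(mn) = R^n / (n! (m-n)!!) * (1/R d/dR)^((m+n)/2) U(R); the leading
    coefficient V(00) is U(R) itself.  Units: energy / A^m.
    """
    _check_pair(m, n)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    k = (m + n) // 2
    pref = 1.0 / (math.factorial(n) * double_factorial(m - n))
    return pref * r ** float(n) * potential.nested_radial_operator(r, k)


def radial_coefficient_derivative(potential: PairPotential, r, m: int, n: int):
    """d V(mn) / dR, using (1/R d/dR)^{k+1} = (1/R) d/dR (1/R d/dR)^k."""
    _check_pair(m, n)
    r = np.asarray(r, dtype=float)
    k = (m + n) // 2
    pref = 1.0 / (math.factorial(n) * double_factorial(m - n))
    term = r ** float(n + 1) * potential.nested_radial_operator(r, k + 1)
    if n:
        term = term + n * r ** float(n - 1) * potential.nested_radial_operator(r, k)
    return pref * term


def lj_radial_closed_form(potential: LennardJonesPotential, r, m: int, n: int):
    """Closed-form V(mn) for the generalised Lennard-Jones potential.

    V(mn) = 4 eps (-1)^((m+n)/2) / (n! (m-n)!! R^m) *
            [ (a+m+n-2)!! / (a-2)!! (s/R)^a  -  (b+m+n-2)!! / (b-2)!! (s/R)^b ]

    where the double-factorial ratio generalises to the product
    a (a+2) ... (a+m+n-2) for non-integer or odd exponents.
    """
    _check_pair(m, n)
    r = np.asarray(r, dtype=float)
    k = (m + n) // 2
    out = np.zeros_like(r)
    for sign, p in ((1.0, potential.exp_rep), (-1.0, potential.exp_att)):
        ratio = math.prod(p + 2 * i for i in range(k))  # (p+m+n-2)!! / (p-2)!!
        out = out + sign * ratio * (potential.sigma / r) ** p
    pref = (4.0 * potential.epsilon * (-1.0) ** k
            / (math.factorial(n) * double_factorial(m - n)))
    return pref * out / r ** float(m)
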