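"""Multipolar expansion of the inter-blob interaction energy.

Two rigid blobs A and B, centres ``R_A`` and ``R_B``, interact through a
sum of identical atom-atom pair potentials U.  Expanding U about the
centre separation ``R = |R_A - R_B|`` factorises the interaction into
radial coefficients V(mn)(R) (see :mod:`cgblob.potentials`) and angular
parts

    Theta(mn) = sum_{a in A, b in B} (Rhat . rho_ab)^n |rho_ab|^(m-n),

with ``rho_ab = rho_a - rho_b`` the lab-frame difference of atom positions
about their respective centres and ``Rhat = (R_A - R_B)/R``.  The truncated
series

    V(R, Omega) = sum_(m,n) V(mn) Theta(mn)

approaches the exact all-atom double sum as the order increases.  The key
computational point is that Theta(mn) never needs the atom loops: it is a
full contraction of the blobs' moment tensors.  Writing the pair difference
moment

    M(m) = sum_{ab} rho_ab^(x m)
         = sum_q (-1)^(m-q) C(m,q) Sym[Gamma_A(q) (x) Gamma_B(m-q)],

a fully symmetric rank-m tensor, the angular part is the contraction of
M(m) with the symmetrised tensor ``Sym[Rhat^(x n) (x) delta^(x (m-n)/2)]``.
This form also yields analytic derivatives with respect to Rhat (for
forces) and with respect to rigid rotations of either blob (for torques).

Both routes are implemented: :func:`angular_part_direct` performs the
O(N_A N_B) atom double sum and serves as the exact reference;
:func:`angular_part_tensor` is the moment-tensor contraction used in
production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .potentials import (
    PairPotential,
    radial_coefficient,
    radial_coefficient_derivative,
    valid_index_pairs,
)
from .quaternion import quat_to_matrix, normalize
from .tensors import BlobTemplate, MomentTensorSet, compute_moment_tensors, rotate_tensors

__all__ = [
    "TruncationScheme",
    "BlobState",
    "angular_part_direct",
    "angular_part_tensor",
    "interblob_energy",
    "allatom_energy",
    "allatom_force_torque",
    "interblob_force_torque",
    "pair_interaction",
    "series_pair_interaction",
    "finite_difference_force_torque",
]

_EPS = np.zeros((3, 3, 3))
_EPS[0, 1, 2] = _EPS[1, 2, 0] = _EPS[2, 0, 1] = 1.0
_EPS[0, 2, 1] = _EPS[2, 1, 0] = _EPS[1, 0, 2] = -1.0


@dataclass(frozen=True)
class TruncationScheme:
    """Which (m, n) pairs of the series are retained.

    ``up_to(0)`` keeps only (0,0) — the bare centre-centre potential scaled
    by N_A N_B; ``up_to(3)`` adds every pair with m <= 3; ``up_to(4)`` is
    the full fourth-order expansion.
    """

    max_m: int
    index_pairs: tuple = field(default=None)

    def __post_init__(self):
        if not 0 <= self.max_m <= 4:
            raise ValueError("max_m must lie in 0..4")
        if self.index_pairs is None:
            object.__setattr__(self, "index_pairs",
                               tuple(valid_index_pairs(self.max_m)))

    @classmethod
    def up_to(cls, max_m: int) -> "TruncationScheme":
        return cls(max_m=max_m)

    def __iter__(self):
        return iter(self.index_pairs)


@dataclass
class BlobState:
    """A rigid blob placed in the laboratory frame.

    ``position`` is the centre of mass (A); ``orientation`` a unit
    quaternion (scalar first).  Lab-frame moment tensors are computed once
    on construction.
    """

    template: BlobTemplate
    position: np.ndarray
    orientation: np.ndarray = None
    max_rank: int = 4

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.orientation is None:
            self.orientation = np.array([1.0, 0.0, 0.0, 0.0])
        q = np.asarray(self.orientation, dtype=float).reshape(4)
        if abs(np.linalg.norm(q) - 1.0) > 1e-10:
            raise ValueError("orientation quaternion must be normalised")
        self.orientation = q
        self._rotation = quat_to_matrix(q)
        body = compute_moment_tensors(self.template, self.max_rank)
        self.lab_tensors: MomentTensorSet = rotate_tensors(body, self._rotation)

    @property
    def rotation(self) -> np.ndarray:
        return self._rotation

    def lab_atom_positions(self) -> np.ndarray:
        return self.position + self.template.atom_positions @ self._rotation.T


# ---------------------------------------------------------------------------
# angular parts


def _pair_geometry(blob_a: BlobState, blob_b: BlobState):
    rvec = blob_a.position - blob_b.position
    r = float(np.linalg.norm(rvec))
    if r <= 0:
        raise ValueError("blob centres coincide")
    return rvec, r, rvec / r


def angular_part_direct(blob_a: BlobState, blob_b: BlobState, m: int, n: int) -> float:
    """Theta(mn) by explicit double summation over atom pairs (the oracle)."""
    _, _, rhat = _pair_geometry(blob_a, blob_b)
    rho_a = blob_a.template.atom_positions @ blob_a.rotation.T
    rho_b = blob_b.template.atom_positions @ blob_b.rotation.T
    diff = rho_a[:, None, :] - rho_b[None, :, :]
    proj = diff @ rhat
    if m == n:
        return float((proj**n).sum()) if n else float(proj.size)
    norm2 = (diff**2).sum(axis=2)
    return float(((proj**n if n else 1.0) * norm2 ** ((m - n) // 2)).sum())


def _sym_outer(a: np.ndarray, b: np.ndarray, rank_a: int, rank_b: int) -> np.ndarray:
    """Symmetrised outer product of two symmetric tensors.

    Averages the C(rank_a + rank_b, rank_a) distinct assignments of output
    slots to the factors (their internal symmetry covers the rest).
    """
    if rank_a == 0:
        return np.asarray(b) * float(a)
    if rank_b == 0:
        return np.asarray(a) * float(b)
    m = rank_a + rank_b
    full = np.multiply.outer(a, b)
    out = np.zeros((3,) * m)
    count = 0
    for slots in combinations(range(m), rank_a):
        rest = [i for i in range(m) if i not in slots]
        # source axis order = a-axes then b-axes; send them to slots/rest
        out += np.moveaxis(full, range(m), list(slots) + rest)
        count += 1
    return out / count


def pair_difference_moment(tensors_a: MomentTensorSet, tensors_b: MomentTensorSet,
                           m: int) -> np.ndarray:
    """M(m) = sum_{ab} (rho_a - rho_b)^(x m), from moment tensors alone."""
    if m == 0:
        return np.array(tensors_a.n_atoms * tensors_b.n_atoms)
    out = np.zeros((3,) * m)
    for q in range(m + 1):
        ga = tensors_a.gamma[q]
        gb = tensors_b.gamma[m - q]
        term = _sym_outer(ga, gb, q, m - q)
        out += (-1.0) ** (m - q) * math.comb(m, q) * term
    return out


def _sym_rhat_delta(m: int, n: int, rhat: np.ndarray) -> np.ndarray:
    """Sym[ rhat^(x n) (x) delta^(x (m-n)/2) ], the rank-m projector whose
    full contraction with rho^(x m) gives (rhat.rho)^n |rho|^(m-n)."""
    e = np.eye(3)
    if (m, n) == (0, 0):
        return np.array(1.0)
    if m == n:
        t = rhat
        for _ in range(m - 1):
            t = np.multiply.outer(t, rhat)
        return t
    if (m, n) == (2, 0):
        return e
    if (m, n) == (3, 1):
        return (np.einsum("i,jk->ijk", rhat, e) + np.einsum("j,ik->ijk", rhat, e)
                + np.einsum("k,ij->ijk", rhat, e)) / 3.0
    if (m, n) == (4, 0):
        return (np.einsum("ij,kl->ijkl", e, e) + np.einsum("ik,jl->ijkl", e, e)
                + np.einsum("il,jk->ijkl", e, e)) / 3.0
    if (m, n) == (4, 2):
        rr = np.outer(rhat, rhat)
        return (np.einsum("ij,kl->ijkl", rr, e) + np.einsum("ik,jl->ijkl", rr, e)
                + np.einsum("il,jk->ijkl", rr, e) + np.einsum("kl,ij->ijkl", rr, e)
                + np.einsum("jl,ik->ijkl", rr, e) + np.einsum("jk,il->ijkl", rr, e)
                ) / 6.0
    raise ValueError(f"invalid index pair ({m}, {n})")


def _contract_all(t: np.ndarray, m: int, vec_or_tensor: np.ndarray) -> float:
    return float(np.tensordot(t, vec_or_tensor, axes=m)) if m else float(t * vec_or_tensor)


def angular_part_tensor(tensors_a: MomentTensorSet, tensors_b: MomentTensorSet,
                        rhat: np.ndarray, m: int, n: int) -> float:
    """Theta(mn) from lab-frame moment tensors only (no atom loops)."""
    if tensors_a.frame != "lab" or tensors_b.frame != "lab":
        raise ValueError("angular_part_tensor requires lab-frame tensors")
    if not 0 <= n <= m or (m - n) % 2:
        raise ValueError(f"invalid index pair ({m}, {n})")
    rhat = np.asarray(rhat, dtype=float)
    big_m = pair_difference_moment(tensors_a, tensors_b, m)
    proj = _sym_rhat_delta(m, n, rhat)
    return _contract_all(big_m, m, proj)


# ---------------------------------------------------------------------------
# energies


def interblob_energy(blob_a: BlobState, blob_b: BlobState,
                     potential: PairPotential,
                     scheme: TruncationScheme) -> float:
    """Truncated series energy V(R, Omega) = sum V(mn) Theta(mn), kcal/mol."""
    _, r, rhat = _pair_geometry(blob_a, blob_b)
    total = 0.0
    for m, n in scheme:
        theta = angular_part_tensor(blob_a.lab_tensors, blob_b.lab_tensors, rhat, m, n)
        total += float(radial_coefficient(potential, r, m, n)) * theta
    return total


def allatom_energy(blob_a: BlobState, blob_b: BlobState,
                   potential: PairPotential) -> float:
    """Exact all-atom double sum E = sum_{ab} U(|r_ab|) (the oracle)."""
    ra = blob_a.lab_atom_positions()
    rb = blob_b.lab_atom_positions()
    d = np.linalg.norm(ra[:, None, :] - rb[None, :, :], axis=2)
    return float(potential(d).sum())


def allatom_force_torque(blob_a: BlobState, blob_b: BlobState,
                         potential: PairPotential):
    """Exact force on A and torques on A and B from the atom double sum."""
    ra = blob_a.lab_atom_positions()
    rb = blob_b.lab_atom_positions()
    d = ra[:, None, :] - rb[None, :, :]
    r = np.linalg.norm(d, axis=2)
    f_pair = (-potential.derivative(r, 1) / r)[:, :, None] * d  # on each a-atom
    force_a = f_pair.sum(axis=(0, 1))
    arm_a = ra - blob_a.position
    arm_b = rb - blob_b.position
    torque_a = np.cross(arm_a, f_pair.sum(axis=1)).sum(axis=0)
    torque_b = np.cross(arm_b, -f_pair.sum(axis=0)).sum(axis=0)
    return force_a, torque_a, torque_b


# ---------------------------------------------------------------------------
# series force / torque


def _theta_and_rhat_gradient(big_m, m, n, rhat):
    """Theta(mn) and its gradient w.r.t. the (unconstrained) Rhat vector."""
    k = (m - n) // 2
    w = big_m
    for _ in range(k):
        w = np.trace(w, axis1=w.ndim - 2, axis2=w.ndim - 1) if w.ndim > 2 else np.trace(w)
    # w is the rank-n trace-contracted moment
    if n == 0:
        return float(w), np.zeros(3)
    theta_v = w
    for _ in range(n - 1):
        theta_v = np.tensordot(theta_v, rhat, axes=1)
    # theta_v is now a vector: w contracted with (n-1) copies of rhat
    theta = float(theta_v @ rhat)
    grad = n * theta_v
    return theta, grad


def pair_interaction(tensors_a: MomentTensorSet, tensors_b: MomentTensorSet,
                     rvec: np.ndarray, potential: PairPotential,
                     scheme: TruncationScheme):
    """Energy, force on A, torque on A, torque on B of the truncated series.

    ``rvec = R_A - R_B`` and both tensor sets must be lab frame.  All
    derivatives are analytic: the radial factor differentiates through
    V(mn)'(R); the angular factor through d Theta / d Rhat projected onto
    the sphere; torques through the action of rigid rotations on the
    moment tensors (for a rank-q tensor the generator contracts the
    Levi-Civita symbol with the tensor and the derivative of Theta with
    respect to it).
    """
    rvec = np.asarray(rvec, dtype=float)
    r = float(np.linalg.norm(rvec))
    if r <= 0:
        raise ValueError("blob centres coincide")
    rhat = rvec / r
    ta, tb = tensors_a, tensors_b
    energy = 0.0
    dE_dr = 0.0
    dE_drhat = np.zeros(3)
    torque_a = np.zeros(3)
    torque_b = np.zeros(3)
    for m, n in scheme:
        big_m = pair_difference_moment(ta, tb, m)
        v = float(radial_coefficient(potential, r, m, n))
        dv = float(radial_coefficient_derivative(potential, r, m, n))
        theta, grad = _theta_and_rhat_gradient(big_m, m, n, rhat)
        energy += v * theta
        dE_dr += dv * theta
        dE_drhat += v * grad
        if m == 0:
            continue
        proj = _sym_rhat_delta(m, n, rhat)
        # torque on A: rotation generator acting on Gamma_A(q)
        for q in range(1, m + 1):
            y = np.tensordot(tb.gamma[m - q], proj, axes=m - q) if m - q else proj * float(tb.gamma[0])
            # y: rank-q, symmetric; contract q-1 indices with Gamma_A(q)
            p_bc = np.tensordot(ta.gamma[q], y, axes=(range(1, q), range(1, q))) if q > 1 \
                else np.multiply.outer(ta.gamma[1], y)
            coeff = (-1.0) ** (m - q) * math.comb(m, q) * q
            torque_a -= v * coeff * np.einsum("abc,bc->a", _EPS, p_bc)
        # torque on B: same with roles swapped (sign from (-1)^p)
        for p in range(1, m + 1):
            y = np.tensordot(ta.gamma[m - p], proj, axes=m - p) if m - p else proj * float(ta.gamma[0])
            p_bc = np.tensordot(tb.gamma[p], y, axes=(range(1, p), range(1, p))) if p > 1 \
                else np.multiply.outer(tb.gamma[1], y)
            coeff = (-1.0) ** p * math.comb(m, p) * p
            torque_b -= v * coeff * np.einsum("abc,bc->a", _EPS, p_bc)
    grad_pos = dE_dr * rhat + (dE_drhat - rhat * (dE_drhat @ rhat)) / r
    force_a = -grad_pos
    return energy, force_a, torque_a, torque_b


def series_pair_interaction(blob_a: BlobState, blob_b: BlobState,
                            potential: PairPotential,
                            scheme: TruncationScheme):
    """Energy, force on A, torque on A, torque on B for two placed blobs."""
    return pair_interaction(blob_a.lab_tensors, blob_b.lab_tensors,
                            blob_a.position - blob_b.position,
                            potential, scheme)


# ---------------------------------------------------------------------------
# finite-difference reference


def _rotated_state(blob: BlobState, axis: int, angle: float) -> BlobState:
    from .quaternion import quat_from_axis_angle, quat_multiply
    dq = quat_from_axis_angle(np.eye(3)[axis] * angle)
    q = normalize(quat_multiply(dq, blob.orientation))
    return BlobState(blob.template, blob.position, q, blob.max_rank)


def _shifted_state(blob: BlobState, axis: int, h: float) -> BlobState:
    pos = blob.position.copy()
    pos[axis] += h
    return BlobState(blob.template, pos, blob.orientation, blob.max_rank)


def finite_difference_force_torque(blob_a: BlobState, blob_b: BlobState,
                                   energy_fn, h_t: float = 1e-4,
                                   h_r: float = 1e-5):
    """Symmetric finite differences of an arbitrary pair energy function.

    ``energy_fn(blob_a, blob_b) -> float``.  Translation step ``h_t`` (A),
    rotation step ``h_r`` (rad).  Serves as the reference implementation
    against which the analytic path is validated.
    """
    force = np.empty(3)
    torque_a = np.empty(3)
    torque_b = np.empty(3)
    for ax in range(3):
        ep = energy_fn(_shifted_state(blob_a, ax, +h_t), blob_b)
        em = energy_fn(_shifted_state(blob_a, ax, -h_t), blob_b)
        force[ax] = -(ep - em) / (2 * h_t)
        ep = energy_fn(_rotated_state(blob_a, ax, +h_r), blob_b)
        em = energy_fn(_rotated_state(blob_a, ax, -h_r), blob_b)
        torque_a[ax] = -(ep - em) / (2 * h_r)
        ep = energy_fn(blob_a, _rotated_state(blob_b, ax, +h_r))
        em = energy_fn(blob_a, _rotated_state(blob_b, ax, -h_r))
        torque_b[ax] = -(ep - em) / (2 * h_r)
    return force, torque_a, torque_b


def interblob_force_torque(blob_a: BlobState, blob_b: BlobState,
                           potential: PairPotential,
                           scheme: TruncationScheme,
                           method: str = "analytic",
                           h_t: float = 1e-4, h_r: float = 1e-5):
    """Force on A and torques on A and B of the truncated series.

    ``method='analytic'`` differentiates the series exactly;
    ``method='fd'`` applies symmetric finite differences to
    :func:`interblob_energy` (the reference path).  The force on B is the
    negative of the force on A by construction.
    """
    if method == "analytic":
        _, force, ta, tb = series_pair_interaction(blob_a, blob_b, potential, scheme)
        return force, ta, tb
    if method == "fd":
        return finite_difference_force_torque(
            blob_a, blob_b,
            lambda a, b: interblob_energy(a, b, potential, scheme),
            h_t=h_t, h_r=h_r)
    raise ValueError("method must be 'analytic' or 'fd'")
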