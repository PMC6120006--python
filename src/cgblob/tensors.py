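"""Interaction moment tensors of rigid blobs and their symmetric flat storage.

A *blob* is a rigid group of atoms treated as one coarse-grained interaction
site.  Its internal mass distribution enters the inter-blob potential only
through the interaction moment tensors

    Gamma(m) = sum_alpha  rho_alpha (x) ... (x) rho_alpha      (m factors),

the rank-m sums of outer products of the atom position vectors
``rho_alpha`` about the blob's centre of mass.  ``Gamma(0)`` is the atom
count.  These tensors are fully symmetric, so a rank-m tensor over 3
dimensions has only C(m+2, m) independent components; all ranks 0..4 fit in
a single flat array of 35 numbers.  :class:`SymmetricIndexMap` provides the
row-major mapping from sorted index tuples to flat storage locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, permutations

import numpy as np

__all__ = [
    "SymmetricIndexMap",
    "BlobTemplate",
    "MomentTensorSet",
    "compute_moment_tensors",
    "rotate_tensors",
    "sym_index",
    "count_components",
]


def count_components(rank: int, ndim: int = 3) -> int:
    """Number of independent components of a symmetric rank-``rank`` tensor
    in ``ndim`` dimensions, C(ndim + rank - 1, rank)."""
    if rank < 0:
        raise ValueError("rank must be non-negative")
    if ndim < 1:
        raise ValueError("ndim must be positive")
    return math.comb(ndim + rank - 1, rank)


class SymmetricIndexMap:
    """Row-major flat storage layout for symmetric tensors of rank 0..max_rank.

    Ranks are stored contiguously (rank 0 first); within a rank, independent
    components are ordered by their sorted index tuple, lexicographically:
    rank 2 is (11, 12, 13, 22, 23, 33), occupying locations 4..9, and the
    last rank-4 component (3,3,3,3) sits at location 34.

    Index tuples use 1-based axis labels (1..ndim), matching the component
    labels G11, G123, ... customary for this layout.
    """

    def __init__(self, ndim: int = 3, max_rank: int = 4):
        if ndim < 1 or max_rank < 0:
            raise ValueError("ndim must be >= 1 and max_rank >= 0")
        self.ndim = ndim
        self.max_rank = max_rank
        self.offsets = np.concatenate(
            [[0], np.cumsum([count_components(m, ndim) for m in range(max_rank + 1)])]
        ).astype(int)
        self.total = int(self.offsets[-1])

    def tuples(self, rank: int):
        """All sorted index tuples of a given rank, in storage order."""
        return list(combinations_with_replacement(range(1, self.ndim + 1), rank))

    def __call__(self, indices) -> int:
        return self.index(indices)

    def index(self, indices) -> int:
        """Flat location of a component; unsorted tuples are canonicalised
        by sorting (the tensors are symmetric)."""
        t = tuple(sorted(int(i) for i in indices))
        m = len(t)
        if m > self.max_rank:
            raise ValueError(f"rank {m} exceeds max_rank {self.max_rank}")
        if t and (t[0] < 1 or t[-1] > self.ndim):
            raise ValueError(f"axis labels must lie in 1..{self.ndim}, got {indices}")
        return int(self.offsets[m]) + self._rank_position(t)

    def _rank_position(self, t) -> int:
        # lexicographic position of a sorted tuple among all sorted tuples
        N, m = self.ndim, len(t)
        pos = 0
        lo = 1
        for k, ti in enumerate(t):
            rem = m - k - 1
            for v in range(lo, ti):
                # tuples continuing with entries all >= v
                pos += count_components(rem, N - v + 1)
            lo = ti
        return pos

    def label(self, flat: int) -> str:
        """Storage label ('G0'..'G34') of a flat location."""
        if not 0 <= flat < self.total:
            raise ValueError("flat index out of range")
        return f"G{flat}"


_DEFAULT_MAP = SymmetricIndexMap(3, 4)


def sym_index(indices, ndim: int = 3) -> int:
    """Flat storage location of a symmetric-tensor component.

    ``indices`` is a tuple of 1-based axis labels; the empty tuple addresses
    the rank-0 component (location 0).  Ranks 0..4 are stored contiguously.
    """
    if ndim == 3:
        return _DEFAULT_MAP.index(indices)
    return SymmetricIndexMap(ndim, len(tuple(indices))).index(indices)


@dataclass
class BlobTemplate:
    """Atoms of one rigid blob in its body-fixed frame.

    Positions are re-centred so the centre of mass sits at the origin.
    Coordinates in A, masses in amu.
    """

    atom_positions: np.ndarray
    atom_masses: np.ndarray
    label: str = "blob"

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.atom_positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("atom_positions must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom positions must be finite")
        masses = np.asarray(self.atom_masses, dtype=float).reshape(-1)
        if masses.shape[0] != pos.shape[0]:
            raise ValueError("one mass per atom required")
        if np.any(masses <= 0):
            raise ValueError("atom masses must be positive")
        com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
        self.atom_positions = pos - com
        self.atom_masses = masses

    @property
    def n_atoms(self) -> int:
        return self.atom_positions.shape[0]

    @property
    def molar_mass(self) -> float:
        """Total mass in amu (= g/mol)."""
        return float(self.atom_masses.sum())

    @property
    def radius(self) -> float:
        """Largest distance of any atom from the centre of mass, A."""
        return float(np.linalg.norm(self.atom_positions, axis=1).max())

    def inertia_tensor(self) -> np.ndarray:
        """Body-frame inertia tensor about the centre of mass, amu A^2."""
        r = self.atom_positions
        m = self.atom_masses
        r2 = (r**2).sum(axis=1)
        return np.einsum("a,a,ij->ij", m, r2, np.eye(3)) - np.einsum(
            "a,ai,aj->ij", m, r, r
        )

    def rotated(self, rotation: np.ndarray) -> "BlobTemplate":
        return BlobTemplate(self.atom_positions @ np.asarray(rotation).T,
                            self.atom_masses, self.label)


@dataclass
class MomentTensorSet:
    """Interaction moment tensors Gamma(0)..Gamma(max_rank) of one blob.

    ``gamma[m]`` is the dense, fully symmetric rank-m tensor (a scalar for
    m = 0).  The trace contractions used by the angular parts of the
    multipolar series are derived quantities:

    * ``tr2_gamma2`` = sum_a |rho_a|^2          (scalar)
    * ``tr2_gamma3`` = sum_a |rho_a|^2 rho_a    (vector)
    * ``tr2_gamma4`` = sum_a |rho_a|^2 rho_a rho_a  (rank 2)
    * ``tr4_gamma4`` = sum_a |rho_a|^4          (scalar)

    ``frame`` records whether the components refer to the body-fixed or the
    laboratory frame; the series contraction requires lab-frame tensors.
    """

    gamma: dict
    frame: str = "body"
    index_map: SymmetricIndexMap = field(default_factory=lambda: _DEFAULT_MAP)

    @property
    def max_rank(self) -> int:
        return max(self.gamma)

    @property
    def n_atoms(self) -> float:
        return float(self.gamma[0])

    @property
    def tr2_gamma2(self) -> float:
        return float(np.trace(self.gamma[2]))

    @property
    def tr2_gamma3(self) -> np.ndarray:
        return np.einsum("ijj->i", self.gamma[3])

    @property
    def tr2_gamma4(self) -> np.ndarray:
        return np.einsum("ijkk->ij", self.gamma[4])

    @property
    def tr4_gamma4(self) -> float:
        return float(np.einsum("iijj->", self.gamma[4]))

    def flat(self) -> np.ndarray:
        """Independent components of all ranks as one flat array (storage
        order of the index map)."""
        out = np.empty(self.index_map.offsets[self.max_rank + 1])
        for m in range(self.max_rank + 1):
            g = np.asarray(self.gamma[m])
            for t in self.index_map.tuples(m):
                out[self.index_map.index(t)] = g[tuple(i - 1 for i in t)] if m else g
        return out

    @classmethod
    def from_flat(cls, values, max_rank: int = 4, frame: str = "body"):
        imap = _DEFAULT_MAP
        values = np.asarray(values, dtype=float)
        gamma = {}
        for m in range(max_rank + 1):
            if m == 0:
                gamma[0] = float(values[0])
                continue
            g = np.zeros((3,) * m)
            for t in imap.tuples(m):
                v = values[imap.index(t)]
                for p in set(permutations(tuple(i - 1 for i in t))):
                    g[p] = v
            gamma[m] = g
        return cls(gamma=gamma, frame=frame)

    def save(self, path) -> None:
        """Write a plain-text table: rank, storage label, value."""
        flat = self.flat()
        with open(path, "w") as fh:
            fh.write("# rank  location  value\n")
            for m in range(self.max_rank + 1):
                for t in self.index_map.tuples(m):
                    i = self.index_map.index(t)
                    fh.write(f"{m}  G{i}  {flat[i]:.8f}\n")

    @classmethod
    def load(cls, path, frame: str = "body"):
        values = np.zeros(_DEFAULT_MAP.total)
        max_rank = 0
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                rank_s, loc, val = line.split()
                values[int(loc.lstrip("GΓ"))] = float(val)
                max_rank = max(max_rank, int(rank_s))
        return cls.from_flat(values, max_rank=max_rank, frame=frame)

    def is_isotropic(self, rtol: float = 1e-8) -> bool:
        """True when every tensor is rotation invariant: odd ranks vanish,
        Gamma(2) is proportional to the identity and Gamma(4) to the fully
        symmetrised double identity.  Holds exactly for icosahedral blobs
        (ranks <= 4 admit no other invariant), making the inter-blob series
        orientation independent."""
        scale = max(1.0, abs(self.n_atoms))
        size2 = max(self.tr2_gamma2, 1e-300) if 2 in self.gamma else 1.0
        for m, g in self.gamma.items():
            if m == 0:
                continue
            if m % 2 == 1:
                if np.linalg.norm(np.ravel(g)) > rtol * scale * size2 ** (m / 2):
                    return False
            elif m == 2:
                iso = self.tr2_gamma2 / 3.0 * np.eye(3)
                if not np.allclose(g, iso, atol=rtol * size2):
                    return False
            elif m == 4:
                e = np.eye(3)
                sym2 = (
                    np.einsum("ij,kl->ijkl", e, e)
                    + np.einsum("ik,jl->ijkl", e, e)
                    + np.einsum("il,jk->ijkl", e, e)
                ) / 3.0
                iso = self.tr4_gamma4 / 5.0 * sym2
                if not np.allclose(g, iso, atol=rtol * max(self.tr4_gamma4, 1e-300)):
                    return False
        return True


def compute_moment_tensors(blob: BlobTemplate, max_rank: int = 4) -> MomentTensorSet:
    """Moment tensors Gamma(0)..Gamma(max_rank) of a blob, body frame.

    Gamma(m) = sum over atoms of the m-fold outer product of the atom
    position vector about the centre of mass.
    """
    if not 0 <= max_rank <= 4:
        raise ValueError("max_rank must lie in 0..4")
    rho = blob.atom_positions
    gamma = {0: float(blob.n_atoms)}
    if max_rank >= 1:
        gamma[1] = rho.sum(axis=0)
    # ranks >= 2: compute each independent (sorted-tuple) component once and
    # fill every permutation with the identical value, so the stored dense
    # tensors are symmetric exactly, not merely to round-off
    imap = _DEFAULT_MAP
    for m in range(2, max_rank + 1):
        g = np.empty((3,) * m)
        for t in imap.tuples(m):
            prod = np.ones(rho.shape[0])
            for i in t:
                prod = prod * rho[:, i - 1]
            val = prod.sum()
            for p in set(permutations(tuple(i - 1 for i in t))):
                g[p] = val
        gamma[m] = g
    return MomentTensorSet(gamma=gamma, frame="body")


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    q = np.asarray(rotation, dtype=float)
    if q.shape != (3, 3) or not np.allclose(q @ q.T, np.eye(3), atol=1e-10):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    return q


def rotate_tensors(tensors: MomentTensorSet, rotation: np.ndarray) -> MomentTensorSet:
    """Apply a rotation to every index of every tensor (body -> lab frame).

    Scalar traces are rotation invariant; vector/tensor traces follow from
    the rotated tensors automatically since they are contractions of them.
    """
    q = _check_rotation(rotation)
    gamma = {}
    for m, g in tensors.gamma.items():
        if m == 0:
            gamma[0] = g
        else:
            out = np.asarray(g)
            for axis in range(m):
                out = np.tensordot(q, out, axes=([1], [axis]))
                out = np.moveaxis(out, 0, axis)
            gamma[m] = out
    return MomentTensorSet(gamma=gamma, frame="lab", index_map=tensors.index_map)
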