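"""Blob geometry construction and I/O: the C60 cage, random test blobs,
XYZ files, and FCC starting configurations for liquid simulations.

The buckminsterfullerene cage is built from first principles: a truncated
icosahedron has 60 vertices obtained by cutting each of the 12 vertices of
a regular icosahedron at a fraction ``t`` along its 5 edges.  The 60
pentagon edges (C-C single bonds) have length ``t L`` and the 30 edges
shared by two hexagons (C=C double bonds) have length ``(1 - 2t) L``,
where L is the icosahedron edge.  Prescribing the two bond lengths
therefore fixes the construction exactly:

    L = 2 b_CC + b_CC',   t = b_CC / L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quaternion import random_quaternion, identity
from .tensors import BlobTemplate
from .units import DENSITY_FACTOR, KB, KCAL_PER_MOL

__all__ = [
    "build_c60",
    "c60_face_axes",
    "random_blob",
    "point_blob",
    "Configuration",
    "fcc_configuration",
    "read_xyz",
    "write_xyz",
]

_PHI = (1.0 + 5.0**0.5) / 2.0
_CARBON_MASS = 12.011


def _icosahedron_vertices(edge: float) -> np.ndarray:
    """Regular icosahedron with the given edge length, centred at origin."""
    base = []
    for a in (1.0, -1.0):
        for b in (_PHI, -_PHI):
            base += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    return np.array(base) * edge / 2.0


def build_c60(bond_pentagon: float = 1.450,
              bond_hexagon_hexagon: float = 1.386) -> BlobTemplate:
    """Truncated-icosahedral C60 with prescribed bond lengths.

    ``bond_pentagon`` is the pentagon-edge (C-C single) bond and
    ``bond_hexagon_hexagon`` the bond shared by two hexagons (C=C double),
    both in A.  Returns a 60-carbon :class:`BlobTemplate` with full
    icosahedral symmetry, centred on its centre of mass.
    """
    if bond_pentagon <= 0 or bond_hexagon_hexagon <= 0:
        raise ValueError("bond lengths must be positive")
    edge = 2.0 * bond_pentagon + bond_hexagon_hexagon
    t = bond_pentagon / edge
    verts = _icosahedron_vertices(edge)
    dist = np.linalg.norm(verts[:, None] - verts[None, :], axis=-1)
    points = []
    for i in range(12):
        for j in range(12):
            if i != j and abs(dist[i, j] - edge) < 1e-9 * edge:
                points.append(verts[i] + t * (verts[j] - verts[i]))
    pos = np.array(points)
    assert pos.shape == (60, 3)
    return BlobTemplate(pos, np.full(60, _CARBON_MASS), label="C60")


def c60_face_axes(bond_pentagon: float = 1.450,
                  bond_hexagon_hexagon: float = 1.386) -> dict:
    """Unit vectors from the cage centre through one pentagonal and one
    hexagonal face centre (pentagons sit under icosahedron vertices,
    hexagons under icosahedron faces)."""
    verts = _icosahedron_vertices(1.0)
    pent = verts[0] / np.linalg.norm(verts[0])
    dist = np.linalg.norm(verts[:, None] - verts[None, :], axis=-1)
    # find one triangular face: vertex 0 plus two mutually adjacent neighbours
    nb = [j for j in range(12) if 0 != j and abs(dist[0, j] - 1.0) < 1e-9]
    for a in nb:
        for b in nb:
            if a < b and abs(dist[a, b] - 1.0) < 1e-9:
                ctr = (verts[0] + verts[a] + verts[b]) / 3.0
                return {"pentagon": pent, "hexagon": ctr / np.linalg.norm(ctr)}
    raise RuntimeError("icosahedron face search failed")  # pragma: no cover


def random_blob(n_atoms: int, radius_scale: float = 1.0,
                seed: int | None = 0, mass: float = _CARBON_MASS) -> BlobTemplate:
    """Reproducible random atom cloud, re-centred to zero centre of mass.

    A Gaussian cloud with standard deviation ``radius_scale`` per
    coordinate; used as a generic test fixture for the series machinery.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    pos = rng.normal(0.0, radius_scale, (n_atoms, 3))
    if n_atoms == 1:
        pos = np.zeros((1, 3))
    return BlobTemplate(pos, np.full(n_atoms, mass), label=f"random{n_atoms}")


def point_blob(mass: float, label: str = "point") -> BlobTemplate:
    """Single interaction site at the centre of mass (a structureless blob:
    all moment tensors beyond Gamma(0) = 1 vanish)."""
    return BlobTemplate(np.zeros((1, 3)), np.array([mass]), label=label)


# ---------------------------------------------------------------------------
# configurations


@dataclass
class Configuration:
    """A box of rigid blobs: state arrays plus ensemble metadata.

    ``positions`` (N,3) A; ``velocities`` (N,3) A/ps; ``orientations``
    (N,4) unit quaternions; ``angular_velocities`` (N,3) rad/ps in the
    body frame.  The box is cubic with edge ``box_edge`` (A) and periodic
    boundaries.
    """

    template: BlobTemplate
    box_edge: float
    positions: np.ndarray
    velocities: np.ndarray
    orientations: np.ndarray
    angular_velocities: np.ndarray
    temperature: float | None = None
    density: float | None = None
    seed: int | None = None

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Configuration":
        return Configuration(
            self.template, self.box_edge,
            self.positions.copy(), self.velocities.copy(),
            self.orientations.copy(), self.angular_velocities.copy(),
            self.temperature, self.density, self.seed)


def kinetic_temperature(config: Configuration) -> float:
    """Instantaneous temperature from equipartition.

    Rigid non-linear blobs carry 6 degrees of freedom each (3 translation,
    3 rotation); structureless point blobs only 3.
    """
    m = config.template.molar_mass
    ke_trans = 0.5 * m * (config.velocities**2).sum() / KCAL_PER_MOL
    inertia = np.diag(config.template.inertia_tensor())
    if np.all(inertia > 1e-12):
        w = config.angular_velocities
        ke_rot = 0.5 * (inertia * w**2).sum() / KCAL_PER_MOL
        dof = 6 * config.n_molecules
    else:
        ke_rot = 0.0
        dof = 3 * config.n_molecules
    return 2.0 * (ke_trans + ke_rot) / (dof * KB)


def fcc_configuration(n_molecules: int, density: float, template: BlobTemplate,
                      temperature: float, seed: int = 0,
                      molar_mass: float | None = None) -> Configuration:
    """FCC starting configuration at a given density and temperature.

    The cubic box edge follows from the density (g/cm^3) and the molar
    mass; ``n_molecules`` must equal 4 k^3 so the 4-site FCC basis tiles
    the box.  Orientations are uniform random rotations; linear and
    angular velocities are Maxwell-Boltzmann draws at ``temperature``,
    net linear momentum is removed and the velocities are then rescaled so
    the instantaneous kinetic temperature equals the target exactly.
    """
    if n_molecules < 4:
        raise ValueError("need at least 4 molecules")
    k = round((n_molecules / 4) ** (1.0 / 3.0))
    if 4 * k**3 != n_molecules:
        raise ValueError(f"n_molecules must be 4 k^3 for FCC filling, got {n_molecules}")
    if density <= 0 or temperature <= 0:
        raise ValueError("density and temperature must be positive")
    mass = molar_mass if molar_mass is not None else template.molar_mass
    volume = n_molecules * mass / (DENSITY_FACTOR * density)
    box = volume ** (1.0 / 3.0)
    cell = box / k
    basis = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                      [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
    cells = np.stack(np.meshgrid(range(k), range(k), range(k),
                                 indexing="ij"), axis=-1).reshape(-1, 3)
    positions = ((cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)) * cell

    rng = np.random.default_rng(seed)
    vel = rng.normal(0.0, np.sqrt(KB * temperature * KCAL_PER_MOL / mass),
                     (n_molecules, 3))
    vel -= vel.mean(axis=0)

    inertia = np.diag(template.inertia_tensor())
    if np.all(inertia > 1e-12):
        quats = random_quaternion(rng, n_molecules)
        sigma_w = np.sqrt(KB * temperature * KCAL_PER_MOL / inertia)
        omega = rng.normal(0.0, 1.0, (n_molecules, 3)) * sigma_w
    else:
        quats = identity(n_molecules)
        omega = np.zeros((n_molecules, 3))

    config = Configuration(template, box, positions, vel, quats, omega,
                           temperature=temperature, density=density, seed=seed)
    t_now = kinetic_temperature(config)
    factor = np.sqrt(temperature / t_now)
    config.velocities *= factor
    config.angular_velocities *= factor
    return config


# ---------------------------------------------------------------------------
# XYZ I/O


def write_xyz(path, template_or_positions, comment: str = "",
              elements=None, mode: str = "w") -> None:
    """Write an XYZ frame (element, x, y, z in A)."""
    if isinstance(template_or_positions, BlobTemplate):
        pos = template_or_positions.atom_positions
        if elements is None:
            elements = ["C" if abs(m - _CARBON_MASS) < 0.5 else "X"
                        for m in template_or_positions.atom_masses]
    else:
        pos = np.atleast_2d(np.asarray(template_or_positions, dtype=float))
    if elements is None:
        elements = ["X"] * len(pos)
    with open(path, mode) as fh:
        fh.write(f"{len(pos)}\n{comment}\n")
        for el, (x, y, z) in zip(elements, pos):
            fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                   "S": 32.06, "X": 12.011}


def read_xyz(path) -> BlobTemplate:
    """Read a single-frame XYZ file into a :class:`BlobTemplate`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected atom count")
    if len(lines) < n + 2:
        raise ValueError(f"{path}: truncated file, expected {n} atom lines")
    pos, masses = [], []
    for i, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {i}: expected 'element x y z'")
        el = parts[0].capitalize()
        try:
            pos.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-numeric coordinate")
        masses.append(_ELEMENT_MASSES.get(el, 12.011))
    return BlobTemplate(np.array(pos), np.array(masses), label=str(lines[1]).strip() or "xyz")
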