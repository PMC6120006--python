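"""Rigid-body NVT molecular dynamics with periodic boundaries.

Translations follow Newton's equations integrated by the leapfrog Verlet
scheme; rotations follow the body-frame Euler equations

    I dω/dt = τ_body - ω x (I ω)

integrated by a quaternion leapfrog (a half-step estimate of ω at the full
step feeds the gyroscopic term; the orientation advances by the exact
rotation exp(ω dt) so quaternions stay normalised to round-off).
Temperature control is velocity rescaling: every ``thermostat_interval``
steps both linear and angular velocities are scaled by
sqrt(T_target / T_kinetic) with the kinetic temperature taken from
equipartition over the 6 degrees of freedom of each rigid body.

Three interchangeable force providers implement the engines:

* :class:`AllAtomProvider` - exact atom-atom double sums (the benchmark
  engine), with an atom-level cutoff and shifted potential;
* :class:`RadialCGProvider` - the coarse-grained series for blobs whose
  moment tensors are rotation invariant (icosahedral cages, point blobs),
  in which case the series collapses to a radial effective potential and
  torques vanish identically;
* :class:`GeneralCGProvider` - the full anisotropic series with analytic
  forces and torques, for blobs of arbitrary shape.

``make_provider`` picks the radial fast path automatically when the
template's tensors are isotropic; the two CG providers produce identical
energies, the radial one is simply O(N^2) in molecules with no tensor
algebra in the inner loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Configuration, kinetic_temperature
from .potentials import (PairPotential, radial_coefficient,
                         radial_coefficient_derivative)
from .quaternion import quat_from_axis_angle, quat_multiply, quat_to_matrix, normalize
from .series import TruncationScheme, pair_interaction
from .tensors import compute_moment_tensors, rotate_tensors
from .units import KCAL_PER_MOL

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "AllAtomProvider",
    "RadialCGProvider",
    "GeneralCGProvider",
    "make_provider",
    "thermostat_rescale",
    "step",
    "run",
]


@dataclass
class SimulationConfig:
    """Parameters of one MD run.

    ``engine`` is ``'allatom'`` or ``'cg'``; for the CG engine ``order``
    selects the truncation (0, 3 or 4).  ``cutoff`` defaults to three
    times the potential's equilibrium distance (the simulation length
    unit), clamped below half the box edge.  ``timestep`` in fs.
    """

    potential: PairPotential
    engine: str = "cg"
    order: int = 3
    timestep: float = 5.0
    n_steps_equil: int = 4000
    n_steps_prod: int = 8000
    temperature: float = 300.0
    thermostat_interval_equil: int = 10
    thermostat_interval_prod: int = 50
    cutoff: float | None = None
    frame_stride: int = 10
    velocity_stride: int = 2
    seed: int = 0

    def scheme(self) -> TruncationScheme:
        return TruncationScheme.up_to(self.order)


@dataclass
class Trajectory:
    """Stride-sampled output of a run, consumed by the analysis module."""

    box_edge: float
    dt_frames: float            # ps between stored position frames
    dt_velocities: float        # ps between stored velocity samples
    times: np.ndarray           # frame times, ps
    positions: np.ndarray       # (n_frames, N, 3), wrapped
    velocities: np.ndarray      # (n_vel, N, 3) centre-of-mass velocities
    unwrapped: np.ndarray       # (n_vel, N, 3) unwrapped displacements
    energies: np.ndarray        # potential energy per frame, kcal/mol
    temperatures: np.ndarray    # kinetic temperature per frame
    molar_mass: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    def save(self, path) -> None:
        """Persist to a compressed .npz archive (runtime format)."""
        meta_keys = sorted(self.metadata)
        np.savez_compressed(
            path, box_edge=self.box_edge, dt_frames=self.dt_frames,
            dt_velocities=self.dt_velocities, times=self.times,
            positions=self.positions, velocities=self.velocities,
            unwrapped=self.unwrapped, energies=self.energies,
            temperatures=self.temperatures, molar_mass=self.molar_mass,
            meta_keys=np.array(meta_keys),
            meta_values=np.array([repr(self.metadata[k]) for k in meta_keys]))

    @classmethod
    def load(cls, path) -> "Trajectory":
        import ast
        z = np.load(path, allow_pickle=False)
        meta = {}
        for k, v in zip(z["meta_keys"], z["meta_values"]):
            try:
                meta[str(k)] = ast.literal_eval(str(v))
            except (ValueError, SyntaxError):
                meta[str(k)] = str(v)
        return cls(box_edge=float(z["box_edge"]), dt_frames=float(z["dt_frames"]),
                   dt_velocities=float(z["dt_velocities"]), times=z["times"],
                   positions=z["positions"], velocities=z["velocities"],
                   unwrapped=z["unwrapped"], energies=z["energies"],
                   temperatures=z["temperatures"],
                   molar_mass=float(z["molar_mass"]), metadata=meta)


# ---------------------------------------------------------------------------
# force providers


def _minimum_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


class RadialCGProvider:
    """Coarse-grained series force field for isotropic-tensor blobs.

    For a blob whose moment tensors are rotation invariant every angular
    part Theta(mn) is a geometric constant, so the series is the radial
    potential  V_eff(R) = sum_mn Theta_mn V(mn)(R)  and forces are central;
    torques vanish.  The potential is shifted to zero at the cutoff.
    """

    def __init__(self, template, potential: PairPotential,
                 scheme: TruncationScheme, cutoff: float, box: float):
        tensors = rotate_tensors(compute_moment_tensors(template, scheme.max_m),
                                 np.eye(3))
        if not tensors.is_isotropic(rtol=1e-6):
            raise ValueError("RadialCGProvider requires isotropic moment tensors")
        from .series import angular_part_tensor
        zhat = np.array([0.0, 0.0, 1.0])
        self.theta = {(m, n): angular_part_tensor(tensors, tensors, zhat, m, n)
                      for (m, n) in scheme}
        self.potential = potential
        self.scheme = scheme
        self.cutoff = float(cutoff)
        self.box = float(box)
        self.shift = float(self.effective_potential(np.array([self.cutoff]))[0])

    def effective_potential(self, r):
        out = np.zeros_like(r)
        for (m, n), th in self.theta.items():
            if th:
                out = out + th * radial_coefficient(self.potential, r, m, n)
        return out

    def effective_potential_derivative(self, r):
        out = np.zeros_like(r)
        for (m, n), th in self.theta.items():
            if th:
                out = out + th * radial_coefficient_derivative(self.potential, r, m, n)
        return out

    def compute(self, positions, orientations):
        n = positions.shape[0]
        d = _minimum_image(positions[:, None] - positions[None, :], self.box)
        r2 = (d**2).sum(axis=-1)
        np.fill_diagonal(r2, np.inf)
        mask = r2 < self.cutoff**2
        r = np.sqrt(np.where(mask, r2, 1.0))
        dv = np.where(mask, self.effective_potential_derivative(r), 0.0)
        force = ((-dv / r)[:, :, None] * d).sum(axis=1)
        energy = 0.5 * np.where(mask, self.effective_potential(r) - self.shift, 0.0).sum()
        return force, np.zeros((n, 3)), float(energy)


class GeneralCGProvider:
    """Anisotropic coarse-grained series with analytic forces and torques.

    Lab-frame moment tensors are recomputed for every molecule each step;
    each neighbour pair (centre distance below the cutoff) contributes
    through the analytic series derivatives.  Interactions are truncated
    (not shifted) at the cutoff.
    """

    def __init__(self, template, potential: PairPotential,
                 scheme: TruncationScheme, cutoff: float, box: float):
        self.body = compute_moment_tensors(template, max(scheme.max_m, 0))
        self.potential = potential
        self.scheme = scheme
        self.cutoff = float(cutoff)
        self.box = float(box)

    def compute(self, positions, orientations):
        n = positions.shape[0]
        rots = quat_to_matrix(orientations)
        labs = [rotate_tensors(self.body, rots[i]) for i in range(n)]
        d = _minimum_image(positions[:, None] - positions[None, :], self.box)
        r2 = (d**2).sum(axis=-1)
        np.fill_diagonal(r2, np.inf)
        pairs = np.argwhere(r2 < self.cutoff**2)
        force = np.zeros((n, 3))
        torque = np.zeros((n, 3))
        energy = 0.0
        for i, j in pairs[pairs[:, 0] < pairs[:, 1]]:
            rvec = d[i, j]
            e, f, ta, tb = pair_interaction(labs[i], labs[j], rvec,
                                            self.potential, self.scheme)
            energy += e
            force[i] += f
            force[j] -= f
            torque[i] += ta
            torque[j] += tb
        return force, torque, energy


class AllAtomProvider:
    """Benchmark engine: exact atom-atom sums over rigid molecules.

    The atomic potential is cut and shifted at ``cutoff`` (an atom-atom
    distance); molecule pairs are screened by a centre-distance cutoff
    enlarged by twice the blob radius.
    """

    def __init__(self, template, potential: PairPotential,
                 cutoff: float, box: float):
        self.template = template
        self.potential = potential
        self.cutoff = float(cutoff)
        self.box = float(box)
        self.screen = self.cutoff + 2.0 * template.radius
        self.shift = float(potential(np.array([self.cutoff]))[0])

    def compute(self, positions, orientations):
        n = positions.shape[0]
        rots = quat_to_matrix(orientations)
        atoms = np.einsum("nij,aj->nai", rots, self.template.atom_positions)
        d = _minimum_image(positions[:, None] - positions[None, :], self.box)
        r2 = (d**2).sum(axis=-1)
        force = np.zeros((n, 3))
        torque = np.zeros((n, 3))
        energy = 0.0
        pairs = np.argwhere(r2 < self.screen**2)
        for i, j in pairs[pairs[:, 0] < pairs[:, 1]]:
            rel = atoms[i][:, None, :] - atoms[j][None, :, :] + d[i, j]
            rr = np.linalg.norm(rel, axis=-1)
            mask = rr < self.cutoff
            if not mask.any():
                continue
            u = np.where(mask, self.potential(rr) - self.shift, 0.0)
            fmag = np.where(mask, -self.potential.derivative(rr, 1) / rr, 0.0)
            f_ab = fmag[:, :, None] * rel
            fi = f_ab.sum(axis=(0, 1))
            energy += u.sum()
            force[i] += fi
            force[j] -= fi
            torque[i] += np.cross(atoms[i], f_ab.sum(axis=1)).sum(axis=0)
            torque[j] += np.cross(atoms[j], -f_ab.sum(axis=0)).sum(axis=0)
        return force, torque, energy


def make_provider(config: SimulationConfig, template, box: float):
    """Build the force provider for a run, choosing the radial CG fast path
    automatically when the template's moment tensors are isotropic."""
    pot = config.potential
    sigma_star = getattr(pot, "r0", None) or getattr(pot, "sigma", 1.0)
    cutoff = config.cutoff if config.cutoff is not None else 3.0 * sigma_star
    if config.engine == "allatom":
        cutoff = min(cutoff, 0.499 * box - 2.0 * template.radius)
        return AllAtomProvider(template, pot, cutoff, box)
    if config.engine != "cg":
        raise ValueError("engine must be 'allatom' or 'cg'")
    cutoff = min(cutoff, 0.499 * box)
    scheme = config.scheme()
    tensors = compute_moment_tensors(template, max(scheme.max_m, 0))
    if tensors.is_isotropic(rtol=1e-6):
        return RadialCGProvider(template, pot, scheme, cutoff, box)
    return GeneralCGProvider(template, pot, scheme, cutoff, box)


# ---------------------------------------------------------------------------
# integration


def thermostat_rescale(config: Configuration, target_t: float) -> float:
    """Rescale linear and angular velocities to the target temperature;
    returns the scale factor applied."""
    t_now = kinetic_temperature(config)
    if t_now <= 0:
        raise ValueError("kinetic temperature must be positive")
    factor = np.sqrt(target_t / t_now)
    config.velocities *= factor
    config.angular_velocities *= factor
    return factor


class _Integrator:
    """Leapfrog state: half-step linear and angular velocities."""

    def __init__(self, config: Configuration, provider, dt_ps: float):
        self.box = config.box_edge
        self.dt = dt_ps
        self.provider = provider
        self.mass = config.template.molar_mass
        inertia = np.diag(config.template.inertia_tensor())
        self.rotates = bool(np.all(inertia > 1e-12))
        self.inertia = inertia if self.rotates else np.ones(3)
        self.pos = config.positions.copy()
        self.quat = config.orientations.copy()
        force, torque, self.energy = provider.compute(self.pos, self.quat)
        acc = force * KCAL_PER_MOL / self.mass
        self.vhalf = config.velocities + 0.5 * dt_ps * acc
        if self.rotates:
            self.whalf = config.angular_velocities + 0.5 * dt_ps * self._alpha(
                torque, config.angular_velocities)
        else:
            self.whalf = np.zeros_like(config.angular_velocities)
        self.vel = config.velocities.copy()   # full-step estimates
        self.omega = config.angular_velocities.copy()

    def _alpha(self, torque_lab, omega_body):
        """Body-frame angular acceleration from the Euler equations."""
        rots = quat_to_matrix(self.quat)
        tau_body = np.einsum("nji,nj->ni", rots, torque_lab) * KCAL_PER_MOL
        gyro = np.cross(omega_body, omega_body * self.inertia)
        return (tau_body - gyro) / self.inertia

    def step(self):
        dt = self.dt
        self.pos = (self.pos + dt * self.vhalf) % self.box
        if self.rotates:
            self.quat = normalize(quat_multiply(
                self.quat, quat_from_axis_angle(self.whalf * dt)))
        force, torque, self.energy = self.provider.compute(self.pos, self.quat)
        if not np.all(np.isfinite(force)):
            raise FloatingPointError("non-finite forces: integration failed")
        vnew = self.vhalf + dt * force * KCAL_PER_MOL / self.mass
        self.vel = 0.5 * (self.vhalf + vnew)
        self.vhalf = vnew
        if self.rotates:
            # half-step estimate of omega at the full step for the gyroscopic term
            w_est = self.whalf + 0.5 * dt * self._alpha(torque, self.whalf)
            wnew = self.whalf + dt * self._alpha(torque, w_est)
            self.omega = 0.5 * (self.whalf + wnew)
            self.whalf = wnew

    def snapshot(self, config: Configuration):
        config.positions = self.pos.copy()
        config.orientations = self.quat.copy()
        config.velocities = self.vel.copy()
        config.angular_velocities = self.omega.copy()

    def rescale(self, factor: float):
        """Apply a thermostat scale factor to the half-step velocities."""
        self.vhalf *= factor
        self.whalf *= factor
        self.vel *= factor
        self.omega *= factor


def step(config: Configuration, provider, dt_ps: float) -> Configuration:
    """Advance a configuration by one leapfrog step (convenience wrapper;
    :func:`run` keeps the half-step state across steps)."""
    integ = _Integrator(config, provider, dt_ps)
    integ.step()
    out = config.copy()
    integ.snapshot(out)
    return out


def run(config: SimulationConfig, initial: Configuration,
        log=None) -> Trajectory:
    """NVT (or NVE when thermostat intervals are 0) production run.

    Equilibration applies the rescaling thermostat every
    ``thermostat_interval_equil`` steps; production every
    ``thermostat_interval_prod`` (0 disables).  Positions are stored every
    ``frame_stride`` steps, centre-of-mass velocities and unwrapped
    displacements every ``velocity_stride``.  Fully deterministic for a
    given initial configuration.
    """
    dt = config.timestep * 1e-3  # fs -> ps
    provider = make_provider(config, initial.template, initial.box_edge)
    state = initial.copy()
    integ = _Integrator(state, provider, dt)

    n_total = config.n_steps_equil + config.n_steps_prod
    frames, times, energies, temps = [], [], [], []
    vels, unwrapped = [], []
    disp = np.zeros_like(state.positions)

    for s in range(n_total):
        pos_before = integ.pos.copy()
        integ.step()
        raw = integ.pos - pos_before
        disp_step = _minimum_image(raw, state.box_edge)
        in_prod = s >= config.n_steps_equil
        integ.snapshot(state)
        interval = (config.thermostat_interval_prod if in_prod
                    else config.thermostat_interval_equil)
        if interval and (s + 1) % interval == 0:
            factor = thermostat_rescale(state, config.temperature)
            integ.rescale(factor)
        if in_prod:
            disp += disp_step
            sp = s - config.n_steps_equil
            if sp % config.velocity_stride == 0:
                vels.append(state.velocities.copy())
                unwrapped.append(disp.copy())
            if sp % config.frame_stride == 0:
                frames.append(state.positions.copy())
                times.append(sp * dt)
                energies.append(integ.energy)
                temps.append(kinetic_temperature(state))
                if log is not None:
                    log(sp, temps[-1], energies[-1])

    return Trajectory(
        box_edge=state.box_edge,
        dt_frames=config.frame_stride * dt,
        dt_velocities=config.velocity_stride * dt,
        times=np.array(times),
        positions=np.array(frames),
        velocities=np.array(vels),
        unwrapped=np.array(unwrapped),
        energies=np.array(energies),
        temperatures=np.array(temps),
        molar_mass=state.template.molar_mass,
        metadata={
            "engine": config.engine, "order": config.order,
            "temperature": config.temperature, "density": initial.density,
            "timestep_fs": config.timestep, "seed": config.seed,
            "n_steps_equil": config.n_steps_equil,
            "n_steps_prod": config.n_steps_prod,
            "cutoff": provider.cutoff,
        },
    )
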