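"""Agent propagation: the two-step damped Verlet recurrence with the k_BT rule.

The engine advances the agent with the printed two-step recurrence

    r_n     = r_{n-2} + 2 dt v_{n-1}
    v_{n+1} = v_{n-1} - 2 dt (1/m) dE_p/dr(r_n) - (b/m) v_{n-1} 2 dt

so one update spans 2 dt of simulated time.  The Stokes drag coefficient
b = 6 pi eta R follows the viscosity of the region the agent is in.  After
each update the kinetic-energy rule is applied:

* ``"cap"``  — rescale the speed down to sqrt(2 k_B T / m) whenever the
  kinetic energy exceeds k_B T (the literal reading of the k_BT limit);
* ``"hold"`` — rescale the speed to sqrt(2 k_B T / m) every step, up or
  down (a crude isokinetic thermostat; the default, see docs/methods.md:
  it is the only rule under which every run traverses the bilayer the way
  the published trajectories do);
* ``"off"``  — no intervention (for integrator sanity checks).

Two equivalent implementations are provided: a numba kernel (default) and
a pure-python path assembled from the step operations below; their
agreement is under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import (
    ANGSTROM,
    DIPOLE_PREFACTOR,
    KB,
    mass_kg_from_gmol,
    thermal_speed,
)
from .field import AgentSpec, EnvironmentParams, MIN_SEPARATION, field_force  # noqa: F401
from .membrane import MembraneModel

__all__ = [
    "SimulationParams",
    "AgentState",
    "Trajectory",
    "DivergenceError",
    "drag_coefficient",
    "verlet_step",
    "cap_kinetic_energy",
    "run_trajectory",
]

_KE_MODES = {"cap": 0, "hold": 1, "off": 2}


class DivergenceError(RuntimeError):
    """The agent left the 10x box envelope or produced non-finite state.

    Carries the step index and, when raised by :func:`run_trajectory`, the
    partial trajectory recorded up to the abort on ``.trajectory``.
    """

    def __init__(self, message: str, step: int, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.step = step
        self.trajectory = trajectory


@dataclass(frozen=True)
class SimulationParams:
    """Run controls for a single trajectory.

    dt is the half-step of the two-step recurrence (one update advances
    2 dt); n_steps counts updates.  z_start is the initial height above the
    bilayer center (A); the agent starts at the lateral box center moving
    toward the membrane at the thermal speed (``initial_speed="thermal"``)
    or at rest (``initial_speed=0``).
    """

    dt: float = 1e-15  # s
    n_steps: int = 500_000
    seed: int = 0
    z_start: float = 45.0  # A
    temperature: float = 300.0  # K
    bin_width: float = 0.2  # A
    ke_mode: str = "hold"
    transfer_sign: int = 0  # +1 | 0 | -1, see energetics
    stop_at_core: bool = True
    initial_speed: str | float = "thermal"
    min_separation: float = MIN_SEPARATION  # A

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        if self.ke_mode not in _KE_MODES:
            raise ValueError(f"ke_mode must be one of {sorted(_KE_MODES)}")
        if self.transfer_sign not in (-1, 0, 1):
            raise ValueError("transfer_sign must be -1, 0 or +1")


@dataclass
class AgentState:
    """Instantaneous agent state: position (A), velocity (m/s), update index."""

    position: np.ndarray
    velocity: np.ndarray
    step_index: int = 0


@dataclass
class Trajectory:
    """Per-update record of the run, in output units.

    time in s, positions in A, velocities in m/s, potential energy,
    Hamiltonian and cumulative Gibbs free energy in kcal/mol; ``region``
    is True where the agent is inside |z| < half_thickness.  ``status`` is
    "completed", "core_reached" or "diverged".
    """

    time: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    ep_kcal: np.ndarray
    h_kcal: np.ndarray
    dg_kcal: np.ndarray
    region: np.ndarray
    status: str
    agent: AgentSpec
    membrane: MembraneModel
    env: EnvironmentParams
    sim: SimulationParams

    def __len__(self) -> int:
        return len(self.time)

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "vx": self.velocities[:, 0],
                "vy": self.velocities[:, 1],
                "vz": self.velocities[:, 2],
                "ep_kcalmol": self.ep_kcal,
                "h_kcalmol": self.h_kcal,
                "dg_kcalmol": self.dg_kcal,
                "in_membrane": self.region,
            }
        )


def drag_coefficient(eta: float, radius: float) -> float:
    """Stokes drag coefficient b = 6 pi eta R, kg/s."""
    if eta <= 0 or radius <= 0:
        raise ValueError("viscosity and radius must be > 0")
    return 6.0 * math.pi * eta * radius


def verlet_step(r_prev2, v_prev, force, mass_kg: float, b: float, dt: float):
    """One update of the printed two-step recurrence (SI units).

    Returns ``(r_next, v_next)`` with

        r_next = r_prev2 + 2 dt v_prev
        v_next = v_prev (1 - 2 dt b / m) + 2 dt F / m

    where ``force`` is evaluated at ``r_next`` by the caller-facing wrapper
    (the recurrence's force term uses the freshly advanced position).
    """
    r_prev2 = np.asarray(r_prev2, dtype=float)
    v_prev = np.asarray(v_prev, dtype=float)
    force = np.asarray(force, dtype=float)
    r_next = r_prev2 + 2.0 * dt * v_prev
    v_next = v_prev + 2.0 * dt * force / mass_kg - (b / mass_kg) * v_prev * 2.0 * dt
    if not (np.all(np.isfinite(r_next)) and np.all(np.isfinite(v_next))):
        raise FloatingPointError("non-finite state in Verlet update")
    return r_next, v_next


def cap_kinetic_energy(velocity, mass_kg: float, temperature: float):
    """Cap the kinetic energy at k_B T, preserving direction.

    If m |v|^2 / 2 > k_B T the speed is rescaled to sqrt(2 k_B T / m);
    otherwise the velocity is returned unchanged.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    v = np.asarray(velocity, dtype=float)
    v2 = float(v @ v)
    cap2 = 2.0 * KB * temperature / mass_kg
    if v2 > cap2:
        return v * math.sqrt(cap2 / v2)
    return v


def _hold_kinetic_energy(velocity, mass_kg: float, temperature: float):
    """Rescale the speed to exactly sqrt(2 k_B T / m) (isokinetic rule)."""
    v = np.asarray(velocity, dtype=float)
    v2 = float(v @ v)
    if v2 == 0.0:
        return v
    cap2 = 2.0 * KB * temperature / mass_kg
    return v * math.sqrt(cap2 / v2)


@njit(cache=True)
def _kernel(
    r0,
    v0,
    site_pos,
    site_c,
    mass,
    half_t,
    inv_eps_w,
    inv_eps_m,
    b_w,
    b_m,
    dt,
    n_steps,
    cap_v2,
    ke_mode,
    r_min,
    limit,
    cx,
    cy,
    stop_at_core,
):  # pragma: no cover - exercised via run_trajectory
    n_sites = site_pos.shape[0]
    pos = np.empty((n_steps + 1, 3))
    vel = np.empty((n_steps + 1, 3))
    ep = np.empty(n_steps + 1)

    x, y, z = r0[0], r0[1], r0[2]
    vx, vy, vz = v0[0], v0[1], v0[2]

    # energy at the start, for the first record
    inside = abs(z) < half_t
    inv_eps = inv_eps_m if inside else inv_eps_w
    e = 0.0
    for i in range(n_sites):
        dx = x - site_pos[i, 0]
        dy = y - site_pos[i, 1]
        dz = z - site_pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < r_min:
            r = r_min
        e += site_c[i] * inv_eps / (r * r * r)
    pos[0, 0], pos[0, 1], pos[0, 2] = x, y, z
    vel[0, 0], vel[0, 1], vel[0, 2] = vx, vy, vz
    ep[0] = e

    status = 0  # completed
    n_rec = n_steps + 1
    for k in range(1, n_steps + 1):
        # advance position with the previous velocity
        x += 2.0 * dt * vx
        y += 2.0 * dt * vy
        z += 2.0 * dt * vz

        inside = abs(z) < half_t
        inv_eps = inv_eps_m if inside else inv_eps_w
        b = b_m if inside else b_w

        e = 0.0
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for i in range(n_sites):
            dx = x - site_pos[i, 0]
            dy = y - site_pos[i, 1]
            dz = z - site_pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = math.sqrt(r2)
            if r < r_min:
                e += site_c[i] * inv_eps / (r_min * r_min * r_min)
                # flat energy inside the guard -> no force
            else:
                ei = site_c[i] * inv_eps / (r2 * r)
                e += ei
                w = 3.0 * ei / r2
                fx += w * dx
                fy += w * dy
                fz += w * dz

        # velocity update with drag
        fac = 2.0 * dt / mass
        vx = vx + fac * fx - (b / mass) * vx * 2.0 * dt
        vy = vy + fac * fy - (b / mass) * vy * 2.0 * dt
        vz = vz + fac * fz - (b / mass) * vz * 2.0 * dt

        # kinetic-energy rule
        v2 = vx * vx + vy * vy + vz * vz
        if ke_mode == 0:
            if v2 > cap_v2:
                s = math.sqrt(cap_v2 / v2)
                vx *= s
                vy *= s
                vz *= s
        elif ke_mode == 1:
            if v2 > 0.0:
                s = math.sqrt(cap_v2 / v2)
                vx *= s
                vy *= s
                vz *= s

        pos[k, 0], pos[k, 1], pos[k, 2] = x, y, z
        vel[k, 0], vel[k, 1], vel[k, 2] = vx, vy, vz
        ep[k] = e

        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            status = 2
            n_rec = k + 1
            break
        if abs(x - cx) > limit or abs(y - cy) > limit or abs(z) > limit:
            status = 2
            n_rec = k + 1
            break
        if stop_at_core and z <= 0.0:
            status = 1
            n_rec = k + 1
            break

    return pos[:n_rec], vel[:n_rec], ep[:n_rec], status


def _initial_velocity(sim: SimulationParams, mass_kg: float) -> np.ndarray:
    if sim.initial_speed == "thermal":
        return np.array([0.0, 0.0, -thermal_speed(mass_kg, sim.temperature)])
    speed = float(sim.initial_speed)
    return np.array([0.0, 0.0, -speed])


def run_trajectory(
    agent: AgentSpec,
    membrane: MembraneModel,
    env: EnvironmentParams,
    sim: SimulationParams,
    backend: str = "numba",
) -> Trajectory:
    """Propagate the agent through the membrane field and record the run.

    The agent starts at the lateral box center, ``sim.z_start`` A above the
    bilayer center.  Per update the recurrence advances the position, the
    force and energy are evaluated at the new position with the medium of
    the region the agent is in, the velocity is updated with Stokes drag,
    and the kinetic-energy rule is applied.  The run ends after
    ``sim.n_steps`` updates, when the agent reaches the bilayer center
    (``stop_at_core``), or aborts with :class:`DivergenceError` if the
    agent leaves a 10x box envelope or the state goes non-finite.

    The returned :class:`Trajectory` carries E_p, the capped-kinetic
    Hamiltonian and the cumulative Gibbs free energy per record (see
    :mod:`dipscreen.energetics`).
    """
    from . import energetics  # local import to avoid a cycle

    geo = membrane.geometry
    mass_kg = mass_kg_from_gmol(agent.mass)
    r0_ang = np.array([geo.lx / 2.0, geo.ly / 2.0, sim.z_start])
    v0 = _initial_velocity(sim, mass_kg)

    site_pos_m = membrane.positions * ANGSTROM
    site_c = (membrane.dipoles @ np.asarray(agent.dipole, dtype=float)) * DIPOLE_PREFACTOR
    cap_v2 = 2.0 * KB * sim.temperature / mass_kg
    b_w = drag_coefficient(env.eta_water, agent.drag_radius)
    b_m = drag_coefficient(env.eta_membrane, agent.drag_radius)
    limit_m = 10.0 * max(geo.lx, geo.ly, 2.0 * abs(sim.z_start)) * ANGSTROM

    if backend == "numba":
        pos_m, vel, ep_j, status_code = _kernel(
            r0_ang * ANGSTROM,
            v0,
            site_pos_m,
            site_c,
            mass_kg,
            geo.half_thickness * ANGSTROM,
            1.0 / env.eps_r_water,
            1.0 / env.eps_r_membrane,
            b_w,
            b_m,
            sim.dt,
            sim.n_steps,
            cap_v2,
            _KE_MODES[sim.ke_mode],
            sim.min_separation * ANGSTROM,
            limit_m,
            r0_ang[0] * ANGSTROM,
            r0_ang[1] * ANGSTROM,
            sim.stop_at_core,
        )
    elif backend == "python":
        pos_m, vel, ep_j, status_code = _run_python(
            r0_ang, v0, agent, membrane, env, sim, mass_kg, b_w, b_m, limit_m
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    n = len(ep_j)
    time = 2.0 * sim.dt * np.arange(n)
    positions = pos_m / ANGSTROM
    region = np.abs(positions[:, 2]) < geo.half_thickness
    status = {0: "completed", 1: "core_reached", 2: "diverged"}[int(status_code)]

    traj = energetics.attach_energetics(
        time=time,
        positions=positions,
        velocities=vel,
        ep_j=ep_j,
        region=region,
        status=status,
        agent=agent,
        membrane=membrane,
        env=env,
        sim=sim,
    )
    if status == "diverged":
        raise DivergenceError(
            f"trajectory diverged at update {n - 1} (z = {positions[-1, 2]:.1f} A)",
            step=n - 1,
            trajectory=traj,
        )
    return traj


def _run_python(r0_ang, v0, agent, membrane, env, sim, mass_kg, b_w, b_m, limit_m):
    """Reference implementation built from the per-step operations."""
    from .field import potential_energy, viscosity_at

    half_t = membrane.geometry.half_thickness
    cx, cy = r0_ang[0] * ANGSTROM, r0_ang[1] * ANGSTROM
    r = r0_ang * ANGSTROM
    v = np.asarray(v0, dtype=float)

    pos = [r.copy()]
    vel = [v.copy()]
    ep = [
        potential_energy(r0_ang, agent.dipole, membrane, env, sim.min_separation)
    ]
    status = 0
    for k in range(1, sim.n_steps + 1):
        r_ang = (r + 2.0 * sim.dt * v) / ANGSTROM
        inside = abs(r_ang[2]) < half_t
        b = b_m if inside else b_w
        force = field_force(r_ang, agent.dipole, membrane, env, sim.min_separation)
        r, v = verlet_step(r, v, force, mass_kg, b, sim.dt)
        if sim.ke_mode == "cap":
            v = cap_kinetic_energy(v, mass_kg, sim.temperature)
        elif sim.ke_mode == "hold":
            v = _hold_kinetic_energy(v, mass_kg, sim.temperature)
        pos.append(r.copy())
        vel.append(v.copy())
        ep.append(potential_energy(r / ANGSTROM, agent.dipole, membrane, env, sim.min_separation))
        if np.any(np.abs(r - np.array([cx, cy, 0.0])) > limit_m):
            status = 2
            break
        if sim.stop_at_core and r[2] <= 0.0:
            status = 1
            break
    return np.array(pos), np.array(vel), np.array(ep), status
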