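"""Dipole-dipole field evaluation and region-dependent medium properties.

The agent interacts with every membrane site through the scalar
dipole-dipole term

    E_p = sum_i  (mu_i . mu) / (4 pi eps0 eps_r r_i^3)

deliberately omitting the orientation factor of the full dipole tensor;
the force is its exact analytic gradient.  The relative permittivity and
viscosity switch sharply between the water and membrane values at
|z| = half_thickness, resolved from the agent's z position (the boundary
itself counts as water).  A full-tensor variant is available behind an
explicit flag for comparison only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM, DIPOLE_PREFACTOR
from .membrane import MembraneModel

__all__ = [
    "EnvironmentParams",
    "AgentSpec",
    "dipole_pair_energy",
    "potential_energy",
    "field_force",
    "dielectric_at",
    "viscosity_at",
    "MIN_SEPARATION",
]

#: Minimum site-agent separation (A) used in energy/force denominators.
#: The bare 1/r^3 interaction diverges as the agent passes a lattice site;
#: separations below this are clamped instead of blowing up.  The default
#: is a molecular contact distance: the agent and a lipid headgroup are
#: whole molecules, so site-agent separations below ~4 A are geometrically
#: meaningless, and the clamp also bounds single-site energies to the
#: few-kcal/mol scale of the physical problem.
MIN_SEPARATION = 4.0


@dataclass(frozen=True)
class EnvironmentParams:
    """Medium properties for the two regions and the bath temperature."""

    eps_r_water: float = 88.0
    eps_r_membrane: float = 4.0
    eta_water: float = 0.89e-3  # Pa s
    eta_membrane: float = 934e-3  # Pa s
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        for name in ("eps_r_water", "eps_r_membrane", "eta_water", "eta_membrane", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class AgentSpec:
    """The screened molecule as a point dipole on a Stokes sphere.

    mass in g/mol, dipole in Debye, logp dimensionless, drag_radius in m.
    The default drag radius is the engine's nominal 1e-14 m sphere; it only
    scales the drag coefficient b = 6 pi eta R.
    """

    name: str
    mass: float
    dipole: tuple[float, float, float]
    logp: float
    drag_radius: float = 1e-14

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError("agent mass must be > 0")
        if not self.drag_radius > 0:
            raise ValueError("drag radius must be > 0")
        if not np.all(np.isfinite(self.dipole)):
            raise ValueError("agent dipole must be finite")


def dipole_pair_energy(
    mu_a,
    mu_b,
    separation,
    eps_r: float,
    orientation_term: bool = False,
) -> float:
    """Interaction energy (J) of two point dipoles (Debye) at a separation (A).

    Default is the scalar-product form ``(mu_a . mu_b)/(4 pi eps0 eps_r r^3)``;
    ``orientation_term=True`` evaluates the full tensor
    ``[mu_a . mu_b - 3 (mu_a . rhat)(mu_b . rhat)] / (4 pi eps0 eps_r r^3)``.
    Raises on zero separation; callers guard close approaches with
    :data:`MIN_SEPARATION`.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    sep = np.asarray(separation, dtype=float) * ANGSTROM
    r = float(np.linalg.norm(sep))
    if r == 0.0:
        raise ValueError("zero dipole-dipole separation (singularity)")
    scalar = float(mu_a @ mu_b)
    if orientation_term:
        rhat = sep / r
        scalar -= 3.0 * float(mu_a @ rhat) * float(mu_b @ rhat)
    return DIPOLE_PREFACTOR * scalar / (eps_r * r**3)


def dielectric_at(
    z: float,
    membrane: MembraneModel,
    env: EnvironmentParams,
    smooth_width: float = 0.0,
) -> float:
    """Relative permittivity at height z (A).

    Default is a sharp step: membrane value strictly inside
    |z| < half_thickness, water elsewhere (the boundary itself counts as
    water).  A positive ``smooth_width`` (A) replaces the step with a
    logistic switch of that width centered on the boundary, for studying
    the sensitivity of profiles to the dielectric discontinuity.
    """
    h = membrane.geometry.half_thickness
    if smooth_width > 0.0:
        import math

        s = 1.0 / (1.0 + math.exp((abs(z) - h) * 4.0 / smooth_width))
        return env.eps_r_water + (env.eps_r_membrane - env.eps_r_water) * s
    if abs(z) < h:
        return env.eps_r_membrane
    return env.eps_r_water


def viscosity_at(z: float, membrane: MembraneModel, env: EnvironmentParams) -> float:
    """Dynamic viscosity (Pa s) at height z; same region rule as dielectric_at."""
    if abs(z) < membrane.geometry.half_thickness:
        return env.eta_membrane
    return env.eta_water


def _pair_geometry(agent_position, membrane: MembraneModel, min_separation: float):
    """Separation vectors (m), clamped distances (m) and raw distances (m)."""
    pos = np.asarray(agent_position, dtype=float)
    diff = (pos[None, :] - membrane.positions) * ANGSTROM
    r = np.linalg.norm(diff, axis=1)
    if np.any(r == 0.0):
        raise ValueError("agent coincides with a membrane site (singularity)")
    r_min = min_separation * ANGSTROM
    clamped = np.maximum(r, r_min)
    return diff, clamped, r


def potential_energy(
    agent_position,
    agent_dipole,
    membrane: MembraneModel,
    env: EnvironmentParams,
    min_separation: float = MIN_SEPARATION,
    warn_on_clamp: bool = False,
) -> float:
    """Total agent-membrane interaction energy (J) at a position (A).

    Sums the scalar dipole-dipole term over all sites with the permittivity
    resolved from the agent's z.  Distances below ``min_separation`` are
    clamped to it.
    """
    mu = np.asarray(agent_dipole, dtype=float)
    diff, r, r_raw = _pair_geometry(agent_position, membrane, min_separation)
    if warn_on_clamp and np.any(r_raw < min_separation * ANGSTROM):
        warnings.warn("agent within the minimum-separation guard of a membrane site")
    eps_r = dielectric_at(float(np.asarray(agent_position)[2]), membrane, env)
    dots = membrane.dipoles @ mu
    return float(DIPOLE_PREFACTOR / eps_r * np.sum(dots / r**3))


def field_force(
    agent_position,
    agent_dipole,
    membrane: MembraneModel,
    env: EnvironmentParams,
    min_separation: float = MIN_SEPARATION,
) -> np.ndarray:
    """Force (N, 3-vector) on the agent: the exact gradient -dE_p/dr.

    For each site the scalar-form contribution is
    ``3 (mu_i . mu) / (4 pi eps0 eps_r r^4) rhat`` with rhat pointing from
    the site to the agent, so sites with positive dipole overlap repel.
    Inside the clamp radius the energy is constant, hence zero force.
    """
    mu = np.asarray(agent_dipole, dtype=float)
    diff, r, r_raw = _pair_geometry(agent_position, membrane, min_separation)
    eps_r = dielectric_at(float(np.asarray(agent_position)[2]), membrane, env)
    dots = membrane.dipoles @ mu
    coef = 3.0 * DIPOLE_PREFACTOR / eps_r * dots / r**5
    # clamped sites contribute no force: energy is flat there
    coef = np.where(r_raw < min_separation * ANGSTROM, 0.0, coef)
    return np.asarray((coef[:, None] * diff).sum(axis=0), dtype=float)
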