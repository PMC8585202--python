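"""Plain-text file dialects: parameter files and the three output tables.

The parameter file is a ``key = value`` dialect with ``#`` comments and
case-insensitive keys; vector values are whitespace-separated triples.
Lipid and agent blocks can be pulled from the built-in presets
(``lipid = PG``) or given explicitly.  The three numeric outputs keep the
traditional names: ``membrane.txt`` (site positions and dipoles),
``data.txt`` (agent trajectory) and ``energy.txt`` (dG vs z), all
whitespace-separated columns under ``#``-prefixed headers, written at
full float precision so round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .energetics import FreeEnergyProfile
from .field import AgentSpec, EnvironmentParams
from .membrane import LipidSpec, MembraneGeometry, MembraneModel
from .presets import AGENTS, LIPIDS
from .propagate import SimulationParams, Trajectory
from .screening import RunConfig

__all__ = [
    "ParamError",
    "read_params",
    "write_params",
    "write_membrane",
    "read_membrane",
    "write_trajectory",
    "write_profile",
    "read_external_profile",
]

FMT = "%.17g"


class ParamError(ValueError):
    """A parameter file could not be parsed; message carries the line number."""


_REQUIRED_WITHOUT_PRESET = {
    "lipid": ("lipid_mean", "lipid_sd", "apl"),
    "agent": ("agent_mass", "agent_dipole", "logp"),
}

_KNOWN_KEYS = {
    "lipid", "lipid_mean", "lipid_sd", "apl",
    "agent", "agent_mass", "agent_dipole", "logp", "drag_radius",
    "box_x", "box_y", "half_thickness",
    "eps_r_water", "eps_r_membrane", "eta_water", "eta_membrane", "temperature",
    "dt", "n_steps", "seed", "z_start", "bin_width", "ke_mode",
    "transfer_sign", "stop_at_core", "initial_speed",
    "n_replicates", "output_dir",
}


def _parse_lines(path: Path) -> dict[str, str]:
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParamError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        key = key.strip().lower()
        value = value.strip()
        if not key or not value:
            raise ParamError(f"{path}:{lineno}: empty key or value in {raw!r}")
        pairs[key] = value
    return pairs


def _as_float(pairs: dict[str, str], key: str, default: float | None = None) -> float:
    if key not in pairs:
        if default is None:
            raise ParamError(f"missing required key {key!r}")
        return default
    try:
        return float(pairs[key])
    except ValueError:
        raise ParamError(f"key {key!r}: non-numeric value {pairs[key]!r}") from None


def _as_vector(pairs: dict[str, str], key: str) -> tuple[float, float, float]:
    parts = pairs[key].replace(",", " ").split()
    if len(parts) != 3:
        raise ParamError(f"key {key!r}: expected 3 components, got {pairs[key]!r}")
    try:
        x, y, z = (float(p) for p in parts)
    except ValueError:
        raise ParamError(f"key {key!r}: non-numeric component in {pairs[key]!r}") from None
    return (x, y, z)


def read_params(path) -> RunConfig:
    """Parse a parameter file into a :class:`RunConfig`.

    Unknown keys warn; missing required keys raise :class:`ParamError`
    naming the key.  ``lipid``/``agent`` may name a preset (PC, PG, OCT,
    CHX) or be accompanied by explicit ``lipid_*``/``agent_*`` keys that
    override preset values.
    """
    import warnings

    path = Path(path)
    if not path.exists():
        raise ParamError(f"parameter file not found: {path}")
    pairs = _parse_lines(path)

    for key in pairs:
        if key not in _KNOWN_KEYS:
            warnings.warn(f"{path}: unknown parameter key {key!r} ignored")

    # lipid
    lipid_name = pairs.get("lipid", "").upper()
    if lipid_name in LIPIDS:
        base = LIPIDS[lipid_name]
        lipid = LipidSpec(
            name=base.name,
            mean_dipole=_as_vector(pairs, "lipid_mean") if "lipid_mean" in pairs else base.mean_dipole,
            sd_dipole=_as_vector(pairs, "lipid_sd") if "lipid_sd" in pairs else base.sd_dipole,
            apl=_as_float(pairs, "apl", base.apl),
        )
    else:
        for key in _REQUIRED_WITHOUT_PRESET["lipid"]:
            if key not in pairs:
                raise ParamError(f"missing required key {key!r} (no lipid preset given)")
        lipid = LipidSpec(
            name=lipid_name or "custom",
            mean_dipole=_as_vector(pairs, "lipid_mean"),
            sd_dipole=_as_vector(pairs, "lipid_sd"),
            apl=_as_float(pairs, "apl"),
        )

    # agent
    agent_name = pairs.get("agent", "").upper()
    if agent_name in AGENTS:
        base = AGENTS[agent_name]
        agent = AgentSpec(
            name=base.name,
            mass=_as_float(pairs, "agent_mass", base.mass),
            dipole=_as_vector(pairs, "agent_dipole") if "agent_dipole" in pairs else base.dipole,
            logp=_as_float(pairs, "logp", base.logp),
            drag_radius=_as_float(pairs, "drag_radius", base.drag_radius),
        )
    else:
        for key in _REQUIRED_WITHOUT_PRESET["agent"]:
            if key not in pairs:
                raise ParamError(f"missing required key {key!r} (no agent preset given)")
        agent = AgentSpec(
            name=agent_name or "custom",
            mass=_as_float(pairs, "agent_mass"),
            dipole=_as_vector(pairs, "agent_dipole"),
            logp=_as_float(pairs, "logp"),
            drag_radius=_as_float(pairs, "drag_radius", 1e-14),
        )

    geometry = MembraneGeometry(
        lx=_as_float(pairs, "box_x", 80.0),
        ly=_as_float(pairs, "box_y", 80.0),
        half_thickness=_as_float(pairs, "half_thickness", 20.0),
    )
    env = EnvironmentParams(
        eps_r_water=_as_float(pairs, "eps_r_water", 88.0),
        eps_r_membrane=_as_float(pairs, "eps_r_membrane", 4.0),
        eta_water=_as_float(pairs, "eta_water", 0.89e-3),
        eta_membrane=_as_float(pairs, "eta_membrane", 934e-3),
        temperature=_as_float(pairs, "temperature", 300.0),
    )
    defaults = SimulationParams()
    sim = SimulationParams(
        dt=_as_float(pairs, "dt", defaults.dt),
        n_steps=int(_as_float(pairs, "n_steps", defaults.n_steps)),
        seed=int(_as_float(pairs, "seed", defaults.seed)),
        z_start=_as_float(pairs, "z_start", defaults.z_start),
        temperature=_as_float(pairs, "temperature", defaults.temperature),
        bin_width=_as_float(pairs, "bin_width", defaults.bin_width),
        ke_mode=pairs.get("ke_mode", defaults.ke_mode).lower(),
        transfer_sign=int(_as_float(pairs, "transfer_sign", defaults.transfer_sign)),
        stop_at_core=pairs.get("stop_at_core", "on").lower() in ("on", "true", "1", "yes"),
        initial_speed=pairs.get("initial_speed", defaults.initial_speed),
    )
    return RunConfig(
        lipid=lipid,
        agent=agent,
        geometry=geometry,
        env=env,
        sim=sim,
        n_replicates=int(_as_float(pairs, "n_replicates", 10)),
        output_dir=pairs.get("output_dir", "."),
    )


def write_params(config: RunConfig, path) -> None:
    """Write a parameter file that :func:`read_params` round-trips exactly."""
    lines = ["# dipscreen parameter file"]
    lines += [
        f"lipid = {config.lipid.name}",
        "lipid_mean = " + " ".join(FMT % v for v in config.lipid.mean_dipole),
        "lipid_sd = " + " ".join(FMT % v for v in config.lipid.sd_dipole),
        f"apl = {FMT % config.lipid.apl}",
        f"agent = {config.agent.name}",
        f"agent_mass = {FMT % config.agent.mass}",
        "agent_dipole = " + " ".join(FMT % v for v in config.agent.dipole),
        f"logp = {FMT % config.agent.logp}",
        f"drag_radius = {FMT % config.agent.drag_radius}",
        f"box_x = {FMT % config.geometry.lx}",
        f"box_y = {FMT % config.geometry.ly}",
        f"half_thickness = {FMT % config.geometry.half_thickness}",
        f"eps_r_water = {FMT % config.env.eps_r_water}",
        f"eps_r_membrane = {FMT % config.env.eps_r_membrane}",
        f"eta_water = {FMT % config.env.eta_water}",
        f"eta_membrane = {FMT % config.env.eta_membrane}",
        f"temperature = {FMT % config.env.temperature}",
        f"dt = {FMT % config.sim.dt}",
        f"n_steps = {config.sim.n_steps}",
        f"seed = {config.sim.seed}",
        f"z_start = {FMT % config.sim.z_start}",
        f"bin_width = {FMT % config.sim.bin_width}",
        f"ke_mode = {config.sim.ke_mode}",
        f"transfer_sign = {config.sim.transfer_sign}",
        f"stop_at_core = {'on' if config.sim.stop_at_core else 'off'}",
        f"initial_speed = {config.sim.initial_speed}",
        f"n_replicates = {config.n_replicates}",
        f"output_dir = {config.output_dir}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_membrane(membrane: MembraneModel, path) -> None:
    """membrane.txt: columns x y z (A) mu_x mu_y mu_z (Debye), one site/line."""
    header = (
        f"# membrane dipole sites: lipid={membrane.lipid_name} seed={membrane.seed}\n"
        "# x_A y_A z_A mux_D muy_D muz_D"
    )
    data = np.hstack([membrane.positions, membrane.dipoles])
    np.savetxt(path, data, fmt=FMT, header=header, comments="")


def read_membrane(path, geometry: MembraneGeometry | None = None) -> MembraneModel:
    """Read a membrane.txt back into a :class:`MembraneModel`."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {data.shape[1]}")
    if geometry is None:
        lx = 2.0 * float(np.abs(data[:, 0]).max())
        ly = 2.0 * float(np.abs(data[:, 1]).max())
        h = float(np.abs(data[:, 2]).max())
        geometry = MembraneGeometry(lx=max(lx, 1.0), ly=max(ly, 1.0), half_thickness=max(h, 1.0))
    return MembraneModel(
        positions=data[:, :3], dipoles=data[:, 3:], geometry=geometry
    )


def write_trajectory(trajectory: Trajectory, path) -> None:
    """data.txt: step, time (s), x y z (A), dG (kcal/mol)."""
    n = len(trajectory)
    data = np.column_stack(
        [np.arange(n), trajectory.time, trajectory.positions, trajectory.dg_kcal]
    )
    header = (
        f"# agent trajectory: agent={trajectory.agent.name} status={trajectory.status}\n"
        "# step time_s x_A y_A z_A dG_kcalmol"
    )
    np.savetxt(path, data, fmt=["%d", FMT, FMT, FMT, FMT, FMT], header=header, comments="")


def write_profile(profile: FreeEnergyProfile, path, sd: np.ndarray | None = None) -> None:
    """energy.txt: z (A) and dG (kcal/mol); optional per-bin SD third column."""
    if sd is not None:
        data = np.column_stack([profile.z_centers, profile.delta_g, sd])
        cols = "# z_A dG_kcalmol sd_kcalmol"
    else:
        data = np.column_stack([profile.z_centers, profile.delta_g])
        cols = "# z_A dG_kcalmol"
    header = f"# free-energy profile (bin_width={profile.bin_width} A)\n{cols}"
    np.savetxt(path, data, fmt=FMT, header=header, comments="")


def read_external_profile(path, bin_width: float | None = None, rezero_bulk: bool = False) -> FreeEnergyProfile:
    """Read a two-column (z, dG) text profile, e.g. an MD/ABF export.

    Units are assumed to be A and kcal/mol; ``#`` comments and blank lines
    are allowed; ragged rows raise with the row number.  With
    ``rezero_bulk`` the profile is shifted so its outermost-|z| value is 0.
    """
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric entry in {raw!r}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    z = np.array([r[0] for r in rows])
    dg = np.array([r[1] for r in rows])
    if rezero_bulk:
        dg = dg - dg[np.argmax(np.abs(z))]
    if bin_width is None:
        diffs = np.diff(np.sort(z))
        bin_width = float(np.min(diffs[diffs > 0])) if np.any(diffs > 0) else 1.0
    return FreeEnergyProfile(
        z_centers=z,
        delta_g=dg,
        counts=np.ones_like(z, dtype=int),
        bin_width=bin_width,
        reference_z=float(z[np.argmax(np.abs(z))]),
    )
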