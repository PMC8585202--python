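"""Replicate screening: seeded runs, mean profiles and feature summaries.

Run-to-run variation in this engine comes entirely from membrane
generation: every replicate draws a fresh dipole lattice from the lipid
statistics and propagates the same agent through it.  The screen
aggregates the per-replicate free-energy profiles into a per-bin
mean +/- SD profile and extracts the headline features (translocation
free energy, entry/interface barriers, interior minima) from the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import (
    CoreNotReachedError,
    FreeEnergyProfile,
    ProfileFeatures,
    build_profile,
    find_extrema,
    replicate_statistics,
    trans_free_energy,
)
from .field import AgentSpec, EnvironmentParams
from .membrane import LipidSpec, MembraneGeometry, build_membrane
from .propagate import DivergenceError, SimulationParams, Trajectory, run_trajectory

__all__ = [
    "RunConfig",
    "ScreenResult",
    "run_single",
    "run_screen",
    "entry_barrier",
    "water_side_barrier",
    "headline_features",
    "interior_minimum",
    "tallest_barrier",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a screen: specs, geometry, run controls."""

    lipid: LipidSpec
    agent: AgentSpec
    geometry: MembraneGeometry = field(default_factory=MembraneGeometry)
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    sim: SimulationParams = field(default_factory=SimulationParams)
    n_replicates: int = 10
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ScreenResult:
    """Outcome of a replicate screen."""

    config: RunConfig
    seeds: list[int]
    trajectories: list[Trajectory]
    profiles: list[FreeEnergyProfile]
    mean_profile: FreeEnergyProfile
    profile_sd: np.ndarray
    features: ProfileFeatures  # extracted from the mean profile
    per_run: pd.DataFrame  # one row per replicate

    def summary(self) -> pd.DataFrame:
        """Per-replicate feature table plus a mean +/- SD summary row."""
        df = self.per_run.copy()
        numeric = df.select_dtypes("number")
        mean_row = {c: numeric[c].mean() for c in numeric.columns}
        sd_row = {c: numeric[c].std(ddof=1) for c in numeric.columns}
        mean_row["seed"], sd_row["seed"] = "mean", "sd"
        return pd.concat(
            [df, pd.DataFrame([mean_row, sd_row])], ignore_index=True
        )


def run_single(
    config: RunConfig, seed: int, backend: str = "numba"
) -> tuple[Trajectory, FreeEnergyProfile]:
    """One seeded replicate: build a membrane, propagate, bin the profile.

    A run that leaves the box envelope (e.g. an agent deflected back into
    bulk) is kept with its partial trajectory rather than discarded.
    """
    membrane = build_membrane(config.lipid, config.geometry, seed)
    try:
        traj = run_trajectory(config.agent, membrane, config.env, config.sim, backend=backend)
    except DivergenceError as err:
        traj = err.trajectory
        if traj is None:
            raise
    return traj, build_profile(traj)


def run_screen(config: RunConfig, base_seed: int | None = None, backend: str = "numba") -> ScreenResult:
    """Run ``config.n_replicates`` seeded replicates and aggregate them.

    Per-replicate membrane seeds are spawned deterministically from
    ``base_seed`` (default: ``config.sim.seed``) and kept below 2**31.
    """
    if base_seed is None:
        base_seed = config.sim.seed
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(config.n_replicates)]

    trajectories: list[Trajectory] = []
    profiles: list[FreeEnergyProfile] = []
    rows = []
    for seed in seeds:
        traj, prof = run_single(config, seed, backend=backend)
        trajectories.append(traj)
        profiles.append(prof)
        try:
            dg_t = trans_free_energy(prof)
        except CoreNotReachedError:
            dg_t = math.nan
        rows.append(
            {
                "seed": seed,
                "status": traj.status,
                "n_records": len(traj),
                "min_z": float(traj.z.min()),
                "dg_trans_kcalmol": dg_t,
            }
        )

    if len(profiles) >= 2:
        mean_profile, sd = replicate_statistics(profiles)
    else:
        mean_profile, sd = profiles[0], np.zeros(len(profiles[0]))
    features = find_extrema(mean_profile)
    return ScreenResult(
        config=config,
        seeds=seeds,
        trajectories=trajectories,
        profiles=profiles,
        mean_profile=mean_profile,
        profile_sd=sd,
        features=features,
        per_run=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# feature selectors used for the headline numbers


def _region_max(profile: FreeEnergyProfile, mask) -> tuple[float, float]:
    z = profile.z_centers[mask]
    g = profile.delta_g[mask]
    if len(z) == 0:
        raise ValueError("profile has no samples in the queried region")
    i = int(np.argmax(g))
    return abs(float(z[i])), float(g[i])


def water_side_barrier(
    features: ProfileFeatures,
    half_thickness: float,
    profile: FreeEnergyProfile | None = None,
) -> tuple[float, float]:
    """First barrier met on approach strictly outside the membrane region.

    Returns ``(|z|, height)`` of the outermost local maximum with
    |z| > half_thickness.  If there is no local maximum and a ``profile``
    is given, falls back to the highest water-side profile value above the
    bulk reference (a profile that never rises has a ~0 barrier);
    otherwise raises.
    """
    for z, h in features.barriers:  # already ordered bulk-side inward
        if z > half_thickness:
            return z, h
    if profile is not None:
        return _region_max(profile, np.abs(profile.z_centers) > half_thickness)
    raise ValueError("no barrier outside the membrane region")


def entry_barrier(
    features: ProfileFeatures,
    half_thickness: float,
    margin: float = 2.0,
    profile: FreeEnergyProfile | None = None,
) -> tuple[float, float]:
    """Tallest barrier in the entry region |z| >= half_thickness - margin.

    The entry region spans the approach and the first couple of angstroms
    past the dipole plane, where the permittivity switch and close site
    passages pile up.  Same fallback rule as :func:`water_side_barrier`.
    """
    candidates = [(z, h) for z, h in features.barriers if z >= half_thickness - margin]
    if candidates:
        return max(candidates, key=lambda t: t[1])
    if profile is not None:
        return _region_max(profile, np.abs(profile.z_centers) >= half_thickness - margin)
    raise ValueError("no barrier in the membrane-entry region")


def interior_minimum(
    features: ProfileFeatures,
    half_thickness: float,
    profile: FreeEnergyProfile | None = None,
) -> tuple[float, float]:
    """Lowest local minimum strictly inside the membrane region.

    Falls back to the lowest interior profile value when no local minimum
    qualifies and a ``profile`` is given.
    """
    candidates = [(z, g) for z, g in features.minima if z < half_thickness]
    if candidates:
        return min(candidates, key=lambda t: t[1])
    if profile is not None:
        mask = np.abs(profile.z_centers) < half_thickness
        z = profile.z_centers[mask]
        g = profile.delta_g[mask]
        if len(z):
            i = int(np.argmin(g))
            return abs(float(z[i])), float(g[i])
    raise ValueError("no local minimum inside the membrane region")


def headline_features(result: ScreenResult) -> dict[str, float]:
    """The screen's headline numbers, all from the mean profile (kcal/mol, A).

    Keys: ``dg_trans``, ``water_barrier`` / ``water_barrier_z``,
    ``entry_barrier`` / ``entry_barrier_z``, ``interior_min`` /
    ``interior_min_z``, ``tallest_barrier`` / ``tallest_barrier_z``.
    Quantities that cannot be measured on this screen are NaN.
    """
    h = result.config.geometry.half_thickness
    prof = result.mean_profile
    feats = result.features
    out: dict[str, float] = {}
    try:
        out["dg_trans"] = trans_free_energy(prof)
    except CoreNotReachedError:
        out["dg_trans"] = math.nan
    for key, fn in (
        ("water_barrier", lambda: water_side_barrier(feats, h, profile=prof)),
        ("entry_barrier", lambda: entry_barrier(feats, h, profile=prof)),
        ("interior_min", lambda: interior_minimum(feats, h, profile=prof)),
        ("tallest_barrier", lambda: tallest_barrier(feats, profile=prof)),
    ):
        try:
            z, v = fn()
        except ValueError:
            z, v = math.nan, math.nan
        out[key] = v
        out[key + "_z"] = z
    return out


def tallest_barrier(
    features: ProfileFeatures, profile: FreeEnergyProfile | None = None
) -> tuple[float, float]:
    """The profile's highest barrier, ``(|z|, height)``.

    Falls back to the profile's global maximum when no local maximum
    qualifies and a ``profile`` is given.
    """
    if features.barriers:
        return max(features.barriers, key=lambda t: t[1])
    if profile is not None:
        return _region_max(profile, np.ones(len(profile), dtype=bool))
    raise ValueError("profile has no barriers")
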