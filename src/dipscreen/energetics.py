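"""Gibbs free-energy bookkeeping, profile binning and feature extraction.

Along the trajectory the engine tracks the Hamiltonian

    H = E_p + min(m v^2 / 2, k_B T)

(the kinetic part never counts above k_B T) and accumulates the free
energy as work between consecutive states, ``dG = H_B - H_A``, optionally
adding the logP-derived transfer enthalpy

    dH_transfer = ln(10) R T logP

with sign ``+transfer_sign`` on a water->membrane crossing and
``-transfer_sign`` on the way back (so enter-then-exit cancels exactly).
The cumulative dG is binned along the bilayer normal into a
:class:`FreeEnergyProfile` re-zeroed at the bulk bin, from which barrier
and minimum features and the translocation free energy
``dG_trans = dG_core - dG_bulk`` are extracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import KB, KCAL, N_AVOGADRO, R_GAS, mass_kg_from_gmol

__all__ = [
    "FreeEnergyProfile",
    "ProfileFeatures",
    "CoreNotReachedError",
    "hamiltonian",
    "transfer_enthalpy",
    "free_energy_increment",
    "accumulate_free_energy",
    "build_profile",
    "trans_free_energy",
    "find_extrema",
    "replicate_statistics",
]

#: A populated bin whose center lies within this distance (A) of z = 0 is
#: accepted as the bilayer-core bin; otherwise the core counts as not reached.
CORE_WINDOW = 1.0


class CoreNotReachedError(ValueError):
    """The trajectory never sampled the bilayer center, so dG_trans is undefined."""


@dataclass
class FreeEnergyProfile:
    """dG (kcal/mol) binned along the bilayer normal.

    ``z_centers`` are bin centers (A) on the lattice ``(k + 1/2) * bin_width``;
    only populated bins are stored (``counts`` > 0 everywhere).  ``delta_g``
    is re-zeroed at the reference (bulk) bin.
    """

    z_centers: np.ndarray
    delta_g: np.ndarray
    counts: np.ndarray
    bin_width: float
    reference_z: float

    def __post_init__(self) -> None:
        order = np.argsort(self.z_centers)
        self.z_centers = np.asarray(self.z_centers, dtype=float)[order]
        self.delta_g = np.asarray(self.delta_g, dtype=float)[order]
        self.counts = np.asarray(self.counts, dtype=int)[order]

    def __len__(self) -> int:
        return len(self.z_centers)

    def value_at(self, z: float) -> float:
        """dG of the populated bin nearest z; NaN if the profile is empty."""
        if len(self) == 0:
            return math.nan
        i = int(np.argmin(np.abs(self.z_centers - z)))
        return float(self.delta_g[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z_centers, "dg_kcalmol": self.delta_g, "count": self.counts}
        )


@dataclass
class ProfileFeatures:
    """Extracted profile features, all heights/depths relative to the bulk bin.

    ``barriers`` and ``minima`` are lists of ``(|z| A, dG kcal/mol)`` sorted
    from the bulk side inward (descending |z|).  ``dg_trans`` is
    ``dg_core - dg_bulk`` and is NaN when the core was never sampled.
    """

    dg_bulk: float
    dg_core: float
    dg_trans: float
    barriers: list[tuple[float, float]] = field(default_factory=list)
    minima: list[tuple[float, float]] = field(default_factory=list)
    core_reached: bool = True


def hamiltonian(ep: float, velocity, mass_kg: float, temperature: float) -> float:
    """H = E_p + min(m v^2/2, k_B T), in J (inputs SI)."""
    v = np.asarray(velocity, dtype=float)
    ke = 0.5 * mass_kg * float(v @ v)
    return float(ep) + min(ke, KB * temperature)


def transfer_enthalpy(logp: float, temperature: float) -> float:
    """Water->organic transfer enthalpy ln(10) R T logP, in J/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return math.log(10.0) * R_GAS * temperature * logp


def free_energy_increment(
    h_prev: float,
    h_next: float,
    region_prev: str,
    region_next: str,
    transfer: float,
    sign_convention: int = 1,
) -> float:
    """One bookkeeping increment dG = H_next - H_prev (J per molecule).

    ``transfer`` is the per-molecule transfer enthalpy (J); it is added with
    ``+sign_convention`` on a water->membrane crossing and
    ``-sign_convention`` on membrane->water, so a closed enter/exit pair
    contributes zero net transfer.
    """
    for r in (region_prev, region_next):
        if r not in ("water", "membrane"):
            raise ValueError(f"region must be 'water' or 'membrane', got {r!r}")
    inc = h_next - h_prev
    if region_prev == "water" and region_next == "membrane":
        inc += sign_convention * transfer
    elif region_prev == "membrane" and region_next == "water":
        inc -= sign_convention * transfer
    return inc


def accumulate_free_energy(
    ep_j: np.ndarray,
    velocities: np.ndarray,
    region: np.ndarray,
    mass_kg: float,
    temperature: float,
    transfer_j_per_mol: float = 0.0,
    sign_convention: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dG and H along a run (both J per molecule).

    The start state is the reference (dG = 0).  Crossings are detected from
    the boolean ``region`` array (True inside the membrane).
    """
    ep_j = np.asarray(ep_j, dtype=float)
    v = np.asarray(velocities, dtype=float)
    ke = 0.5 * mass_kg * np.sum(v * v, axis=1)
    h = ep_j + np.minimum(ke, KB * temperature)

    dg = np.zeros_like(h)
    dg[1:] = np.diff(h)
    if sign_convention != 0 and transfer_j_per_mol != 0.0:
        reg = np.asarray(region, dtype=bool)
        transfer = transfer_j_per_mol / N_AVOGADRO
        enter = (~reg[:-1]) & reg[1:]
        leave = reg[:-1] & (~reg[1:])
        dg[1:][enter] += sign_convention * transfer
        dg[1:][leave] -= sign_convention * transfer
    return np.cumsum(dg), h


def attach_energetics(
    *,
    time,
    positions,
    velocities,
    ep_j,
    region,
    status,
    agent,
    membrane,
    env,
    sim,
):
    """Assemble a :class:`dipscreen.propagate.Trajectory` with energy columns."""
    from .propagate import Trajectory

    mass_kg = mass_kg_from_gmol(agent.mass)
    transfer = transfer_enthalpy(agent.logp, env.temperature)
    dg_j, h_j = accumulate_free_energy(
        ep_j,
        velocities,
        region,
        mass_kg,
        env.temperature,
        transfer_j_per_mol=transfer,
        sign_convention=sim.transfer_sign,
    )
    to_kcal = N_AVOGADRO / KCAL
    return Trajectory(
        time=np.asarray(time, dtype=float),
        positions=np.asarray(positions, dtype=float),
        velocities=np.asarray(velocities, dtype=float),
        ep_kcal=np.asarray(ep_j, dtype=float) * to_kcal,
        h_kcal=h_j * to_kcal,
        dg_kcal=dg_j * to_kcal,
        region=np.asarray(region, dtype=bool),
        status=status,
        agent=agent,
        membrane=membrane,
        env=env,
        sim=sim,
    )


def build_profile(trajectory, bin_width: float | None = None) -> FreeEnergyProfile:
    """Bin the cumulative dG samples by agent z into a bulk-referenced profile.

    Bin value = mean of the dG samples falling in the bin (repeated visits
    average); bins with no samples are simply absent.  The profile is
    re-zeroed at the bin containing the start height, so the bulk reference
    is exactly zero.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    w = bin_width if bin_width is not None else trajectory.sim.bin_width
    z = trajectory.z
    dg = trajectory.dg_kcal
    idx = np.floor(z / w).astype(int)
    grouped = pd.Series(dg).groupby(idx)
    means = grouped.mean()
    counts = grouped.size()
    centers = (means.index.to_numpy() + 0.5) * w

    ref_idx = int(np.floor(trajectory.sim.z_start / w))
    if ref_idx not in means.index:
        # start sample always exists; guard against a pathological bin_width
        ref_idx = int(idx[0])
    profile = FreeEnergyProfile(
        z_centers=centers,
        delta_g=means.to_numpy() - means.loc[ref_idx],
        counts=counts.to_numpy(),
        bin_width=w,
        reference_z=(ref_idx + 0.5) * w,
    )
    return profile


def _core_index(profile: FreeEnergyProfile, core_window: float = CORE_WINDOW) -> int | None:
    if len(profile) == 0:
        return None
    i = int(np.argmin(np.abs(profile.z_centers)))
    if abs(profile.z_centers[i]) <= core_window:
        return i
    return None


def trans_free_energy(profile: FreeEnergyProfile, core_window: float = CORE_WINDOW) -> float:
    """dG_trans = dG_core - dG_bulk (kcal/mol).

    The bulk bin is the profile reference (exactly zero); the core bin is
    the populated bin nearest z = 0, required to lie within ``core_window``
    A of the center — otherwise :class:`CoreNotReachedError` is raised
    rather than returning a misleading zero.
    """
    i = _core_index(profile, core_window)
    if i is None:
        raise CoreNotReachedError(
            "trajectory never reached the bilayer center; dG_trans undefined"
        )
    ref = profile.value_at(profile.reference_z)
    return float(profile.delta_g[i] - ref)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(values) < window:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(values)]


def find_extrema(
    profile: FreeEnergyProfile,
    smooth_window: int = 3,
    prominence: float = 0.05,
    core_window: float = CORE_WINDOW,
) -> ProfileFeatures:
    """Locate barriers (local maxima) and minima of a smoothed profile.

    The profile is smoothed with a centered moving average
    (``smooth_window`` bins) before peak finding; peaks need at least
    ``prominence`` kcal/mol of prominence so single-bin noise is ignored.
    Heights are measured from the bulk reference and positions reported as
    |z| from the bilayer center, ordered from the bulk side inward.
    """
    if len(profile) < 5:
        raise ValueError("need at least 5 populated bins to extract features")
    smoothed = _smooth(profile.delta_g, smooth_window)
    ref = profile.value_at(profile.reference_z)

    peaks, _ = find_peaks(smoothed, prominence=prominence)
    dips, _ = find_peaks(-smoothed, prominence=prominence)

    def _collect(indices):
        out = [
            (abs(float(profile.z_centers[i])), float(smoothed[i] - ref)) for i in indices
        ]
        order = np.argsort([-abs(float(profile.z_centers[i])) for i in indices])
        return [out[j] for j in order]

    core = _core_index(profile, core_window)
    dg_core = float(smoothed[core] - ref) if core is not None else math.nan
    return ProfileFeatures(
        dg_bulk=0.0,
        dg_core=dg_core,
        dg_trans=dg_core,
        barriers=_collect(peaks),
        minima=_collect(dips),
        core_reached=core is not None,
    )


def replicate_statistics(
    profiles: list[FreeEnergyProfile],
    min_replicates: int = 2,
) -> tuple[FreeEnergyProfile, np.ndarray]:
    """Per-bin mean profile and SD over replicate runs.

    Profiles must share ``bin_width`` (bins then align exactly on the
    common lattice).  Each bin averages over the replicates that populated
    it; bins populated by fewer than ``min_replicates`` runs are dropped
    (at least 2, so every reported bin has a sample SD).
    Returns ``(mean_profile, sd)`` with ``sd`` the per-bin sample SD (ddof=1).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicate profiles")
    w = profiles[0].bin_width
    if any(abs(p.bin_width - w) > 1e-12 for p in profiles[1:]):
        raise ValueError("replicate profiles have incompatible bin widths")

    all_idx = sorted(
        {int(round(z / w - 0.5)) for p in profiles for z in p.z_centers}
    )
    index_of = {k: j for j, k in enumerate(all_idx)}
    mat = np.full((len(profiles), len(all_idx)), np.nan)
    for i, p in enumerate(profiles):
        for z, g in zip(p.z_centers, p.delta_g):
            mat[i, index_of[int(round(z / w - 0.5))]] = g

    n_pop = np.sum(~np.isnan(mat), axis=0)
    keep = n_pop >= max(2, min_replicates)
    if not np.any(keep):
        raise ValueError("no bin is populated in enough replicates")
    centers = (np.array(all_idx)[keep] + 0.5) * w
    mean = np.nanmean(mat[:, keep], axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(mat[:, keep], axis=0, ddof=1)
    sd = np.nan_to_num(sd)

    ref_z = profiles[0].reference_z
    mean_profile = FreeEnergyProfile(
        z_centers=centers,
        delta_g=mean,
        counts=n_pop[keep],
        bin_width=w,
        reference_z=ref_z,
    )
    # re-zero the mean at the bulk reference bin
    mean_profile.delta_g = mean_profile.delta_g - mean_profile.value_at(ref_z)
    return mean_profile, sd
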