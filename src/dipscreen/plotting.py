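"""Matplotlib plots: trajectory, free-energy profile, engine-vs-MD overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .energetics import FreeEnergyProfile
from .propagate import Trajectory

__all__ = ["plot_trajectory", "plot_profile", "plot_comparison"]


def plot_trajectory(trajectory: Trajectory, path=None):
    """z(t) and lateral wander of one run, with the membrane region shaded."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    t_ps = trajectory.time * 1e12
    h = trajectory.membrane.geometry.half_thickness
    ax1.plot(t_ps, trajectory.z, lw=0.7)
    ax1.axhspan(-h, h, color="tan", alpha=0.3, label="membrane")
    ax1.set_xlabel("time (ps)")
    ax1.set_ylabel("z ($\\AA$)")
    ax1.legend(frameon=False)
    ax2.plot(trajectory.positions[:, 0], trajectory.positions[:, 1], lw=0.7)
    ax2.set_xlabel("x ($\\AA$)")
    ax2.set_ylabel("y ($\\AA$)")
    ax2.set_title(f"{trajectory.agent.name} ({trajectory.status})")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_profile(
    profile: FreeEnergyProfile,
    sd: np.ndarray | None = None,
    half_thickness: float | None = None,
    path=None,
    label: str | None = None,
):
    """dG(z) with optional per-bin SD band."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5), constrained_layout=True)
    ax.plot(profile.z_centers, profile.delta_g, color="firebrick", lw=1.2, label=label)
    if sd is not None and len(sd) == len(profile):
        ax.fill_between(
            profile.z_centers,
            profile.delta_g - sd,
            profile.delta_g + sd,
            color="firebrick",
            alpha=0.25,
            lw=0,
        )
    if half_thickness is not None:
        ax.axvspan(-half_thickness, half_thickness, color="tan", alpha=0.3)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("z ($\\AA$)")
    ax.set_ylabel("$\\Delta G$ (kcal/mol)")
    if label:
        ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_comparison(
    engine_profile: FreeEnergyProfile,
    external_profile: FreeEnergyProfile,
    path=None,
    labels: tuple[str, str] = ("engine", "MD reference"),
):
    """Overlay the engine profile with an externally computed one."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5), constrained_layout=True)
    ax.plot(
        engine_profile.z_centers, engine_profile.delta_g, color="firebrick", lw=1.2, label=labels[0]
    )
    ax.plot(
        external_profile.z_centers,
        external_profile.delta_g,
        color="black",
        lw=1.2,
        label=labels[1],
    )
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("z ($\\AA$)")
    ax.set_ylabel("$\\Delta G$ (kcal/mol)")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
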