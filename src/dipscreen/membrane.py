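"""Randomized dipole-lattice membrane builder.

A lipid bilayer is reduced to two planes of point dipoles at z = +/-
``half_thickness``.  Each leaflet carries ``floor(lx * ly / apl)`` sites on
a regular lateral grid with spacing ``sqrt(apl)``; every site's dipole is
drawn independently, per axis, from a normal law whose mean and standard
deviation come from MD-derived per-lipid statistics.  The lower leaflet's
z dipole component is sign-flipped so the bilayer is mirror-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LipidSpec",
    "MembraneGeometry",
    "DipoleSite",
    "MembraneModel",
    "lipid_count",
    "sample_lipid_dipole",
    "build_membrane",
    "make_toy_membrane",
]


@dataclass(frozen=True)
class LipidSpec:
    """Per-axis dipole statistics (Debye) and area per lipid (A^2) for one lipid type."""

    name: str
    mean_dipole: tuple[float, float, float]
    sd_dipole: tuple[float, float, float]
    apl: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mean_dipole)) or not np.all(np.isfinite(self.sd_dipole)):
            raise ValueError(f"lipid {self.name!r}: dipole statistics must be finite")
        if any(s < 0 for s in self.sd_dipole):
            raise ValueError(f"lipid {self.name!r}: dipole SDs must be >= 0")
        if not self.apl > 0:
            raise ValueError(f"lipid {self.name!r}: area per lipid must be > 0, got {self.apl}")


@dataclass(frozen=True)
class MembraneGeometry:
    """Lateral box lengths and leaflet-plane offset, all in angstrom.

    z = 0 is the bilayer center; the two dipole planes sit at
    ``+half_thickness`` and ``-half_thickness`` by default.
    """

    lx: float = 80.0
    ly: float = 80.0
    half_thickness: float = 20.0

    def __post_init__(self) -> None:
        if self.lx <= 0 or self.ly <= 0 or self.half_thickness <= 0:
            raise ValueError("box lengths and half_thickness must be > 0")

    @property
    def leaflet_z(self) -> tuple[float, float]:
        return (self.half_thickness, -self.half_thickness)

    @property
    def center(self) -> tuple[float, float]:
        return (self.lx / 2.0, self.ly / 2.0)


@dataclass(frozen=True)
class DipoleSite:
    """A single membrane dipole: position (A) and moment (Debye)."""

    position: tuple[float, float, float]
    dipole: tuple[float, float, float]


@dataclass
class MembraneModel:
    """A generated membrane: site positions (A), dipoles (Debye), and provenance.

    ``eps_r_inside`` / ``eta_inside`` record the interior medium the membrane
    was built for; the field evaluation takes its environment from
    :class:`dipscreen.field.EnvironmentParams`.
    """

    positions: np.ndarray  # (n, 3) angstrom
    dipoles: np.ndarray  # (n, 3) Debye
    geometry: MembraneGeometry
    eps_r_inside: float = 4.0
    eta_inside: float = 0.934
    seed: int | None = None
    lipid_name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.positions.shape != self.dipoles.shape:
            raise ValueError("positions and dipoles must have matching shapes")
        if len(self.positions) == 0:
            raise ValueError("membrane has no dipole sites")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def sites(self) -> list[DipoleSite]:
        return [
            DipoleSite(tuple(p), tuple(d))
            for p, d in zip(self.positions, self.dipoles)
        ]


def lipid_count(geometry: MembraneGeometry, apl: float) -> int:
    """Number of lipids per leaflet for a given lateral box and area per lipid.

    The count is ``floor(lx * ly / apl)``; the full bilayer carries twice
    this number of dipole sites.
    """
    if apl <= 0:
        raise ValueError(f"area per lipid must be > 0, got {apl}")
    return int(np.floor(geometry.lx * geometry.ly / apl))


def sample_lipid_dipole(
    spec: LipidSpec,
    rng: np.random.Generator,
    leaflet: str = "upper",
    truncate: bool = False,
) -> np.ndarray:
    """Draw one per-axis-normal dipole vector (Debye) for a leaflet site.

    The lower leaflet's z component is sign-flipped after the draw so the
    two leaflets mirror each other.  With ``truncate=True`` the draw is
    clipped to mean +/- 1 SD per axis (the narrow reading of "range of
    values defined by the mean +/- standard deviation"); the default is the
    untruncated normal law.
    """
    if leaflet not in ("upper", "lower"):
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    mean = np.asarray(spec.mean_dipole, dtype=float)
    sd = np.asarray(spec.sd_dipole, dtype=float)
    draw = rng.normal(mean, sd)
    if truncate:
        draw = np.clip(draw, mean - sd, mean + sd)
    if leaflet == "lower":
        draw[2] = -draw[2]
    return draw


def _grid_positions(n: int, lx: float, ly: float, spacing: float) -> np.ndarray:
    """First ``n`` points of a centered regular lattice with the given spacing."""
    nx = max(1, int(round(lx / spacing)))
    ny = max(1, int(np.ceil(n / nx)))
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing + lx / 2.0
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing + ly / 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return pts[:n]


def build_membrane(
    spec: LipidSpec,
    geometry: MembraneGeometry,
    seed: int,
    flip_lower: bool = True,
    truncate: bool = False,
    jitter: float = 0.0,
) -> MembraneModel:
    """Generate a two-leaflet dipole membrane, deterministically from ``seed``.

    Site layout is a regular lateral grid with spacing ``sqrt(apl)``,
    identical on both leaflets and independent of the seed; only the
    dipole draws (and optional lateral jitter) consume randomness.

    Parameters
    ----------
    flip_lower
        Mirror the z dipole component on the lower leaflet (default).
        With ``False`` both leaflets draw from the raw statistics, i.e. a
        uniformly polarized slab.
    jitter
        SD (A) of an optional lateral Gaussian displacement per site;
        0 (default) keeps the exact lattice.
    """
    n_per_leaflet = lipid_count(geometry, spec.apl)
    if n_per_leaflet < 1:
        raise ValueError(
            f"box {geometry.lx} x {geometry.ly} A holds zero lipids at APL {spec.apl} A^2"
        )
    rng = np.random.default_rng(seed)
    spacing = float(np.sqrt(spec.apl))
    lateral = _grid_positions(n_per_leaflet, geometry.lx, geometry.ly, spacing)

    positions = []
    dipoles = []
    for leaflet, z_plane in zip(("upper", "lower"), geometry.leaflet_z):
        eff_leaflet = leaflet if flip_lower else "upper"
        for (x, y) in lateral:
            mu = sample_lipid_dipole(spec, rng, eff_leaflet, truncate=truncate)
            if jitter > 0.0:
                x = x + rng.normal(0.0, jitter)
                y = y + rng.normal(0.0, jitter)
            positions.append((x, y, z_plane))
            dipoles.append(mu)

    return MembraneModel(
        positions=np.array(positions),
        dipoles=np.array(dipoles),
        geometry=geometry,
        seed=seed,
        lipid_name=spec.name,
    )


def make_toy_membrane(
    positions,
    dipole=None,
    dipoles=None,
    geometry: MembraneGeometry | None = None,
) -> MembraneModel:
    """Deterministic membrane from explicit positions, for oracle tests.

    Either one shared ``dipole`` (Debye 3-vector) applied to every site,
    or a per-site ``dipoles`` list of the same length as ``positions``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        raise ValueError("toy membrane needs at least one site")
    if (dipole is None) == (dipoles is None):
        raise ValueError("give exactly one of 'dipole' or 'dipoles'")
    if dipole is not None:
        dip = np.tile(np.asarray(dipole, dtype=float), (len(positions), 1))
    else:
        dip = np.atleast_2d(np.asarray(dipoles, dtype=float))
        if len(dip) != len(positions):
            raise ValueError(
                f"{len(positions)} positions but {len(dip)} dipoles"
            )
    if geometry is None:
        span = max(1.0, 2.0 * float(np.abs(positions[:, :2]).max(initial=1.0)))
        zmax = float(np.abs(positions[:, 2]).max())
        geometry = MembraneGeometry(lx=span, ly=span, half_thickness=max(zmax, 1.0))
    return MembraneModel(positions=positions, dipoles=dip, geometry=geometry, lipid_name="toy")
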