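"""Built-in lipid and agent parameter sets.

Per-axis dipole means and SDs (Debye) are MD-derived statistics for
POPC ("PC"), POPG ("PG") and the two validation antiseptics octenidine
("OCT") and chlorhexidine ("CHX"); masses in g/mol, logP dimensionless.
The default area per lipid of 64 A^2 reproduces the 200-lipid reference
membranes (100 per leaflet) in an 80 x 80 A box.
"""

from .field import AgentSpec
from .membrane import LipidSpec

__all__ = ["LIPIDS", "AGENTS", "get_lipid", "get_agent"]

#: Default area per lipid, A^2.
DEFAULT_APL = 64.0

LIPIDS: dict[str, LipidSpec] = {
    "PC": LipidSpec(
        name="PC",
        mean_dipole=(0.34, -0.37, 1.65),
        sd_dipole=(11.29, 11.39, 8.44),
        apl=DEFAULT_APL,
    ),
    "PG": LipidSpec(
        name="PG",
        mean_dipole=(0.14, 0.29, -35.08),
        sd_dipole=(10.17, 10.09, 8.29),
        apl=DEFAULT_APL,
    ),
}

AGENTS: dict[str, AgentSpec] = {
    "OCT": AgentSpec(
        name="OCT",
        mass=623.84,
        dipole=(0.69, 2.12, -0.51),
        logp=9.25,
    ),
    "CHX": AgentSpec(
        name="CHX",
        mass=505.452,
        dipole=(2.74, 2.21, -0.55),
        logp=5.48,
    ),
}


def get_lipid(name: str) -> LipidSpec:
    """Look up a lipid preset by (case-insensitive) name."""
    try:
        return LIPIDS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown lipid preset {name!r}; available: {sorted(LIPIDS)}"
        ) from None


def get_agent(name: str) -> AgentSpec:
    """Look up an agent preset by (case-insensitive) name."""
    try:
        return AGENTS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown agent preset {name!r}; available: {sorted(AGENTS)}"
        ) from None
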