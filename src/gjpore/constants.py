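"""Physical constants and element tables shared by every analysis stage.

All lengths are in Angstrom, times in ps, temperatures in K, voltages in
mV and energies in kcal/mol.  Every unit conversion in the package goes
through this module so that Boltzmann inversion, the synthetic Brownian
generator and the constant-field setup use numerically identical factors.
"""

from __future__ import annotations

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3

#: Default simulation temperature (K); the production thermostat setting.
DEFAULT_T = 303.15

#: Energy picked up by one elementary charge over 1 mV, in kcal/mol
#: (1 eV = 23.060548 kcal/mol).
KCAL_PER_E_MV = 23.060548e-3

#: Effective hydrated radii (A) of the permeant species.
HYDRATED_RADIUS = {"K+": 3.3, "Cl-": 3.6}

#: Bondi-style van der Waals radii (A) by element symbol.  Unknown
#: elements raise rather than defaulting; see :func:`vdw_radius`.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "K": 2.75,
    "CL": 1.75,
    "X": 1.50,  # generic pseudo-atom used by synthetic pore walls
}

#: Default residue-name -> species map for trajectory readers.  Covers
#: the common CHARMM/AMBER dialects for potassium and chloride.
DEFAULT_SPECIES_MAP = {
    "K": "K+",
    "POT": "K+",
    "CLA": "Cl-",
    "CL": "Cl-",
}


class UnknownElementError(KeyError):
    """Raised when an element has no van der Waals radius assigned."""


def vdw_radius(element: str) -> float:
    """Return the van der Waals radius (A) for *element*.

    Raises
    ------
    UnknownElementError
        If the element is not in the radius table.  Silent defaults
        would bias pore-radius and voxel-emptiness profiles.
    """
    key = element.strip().upper()
    if key not in VDW_RADII:
        raise UnknownElementError(
            f"no van der Waals radius for element {element!r}; extend "
            "gjpore.constants.VDW_RADII"
        )
    return VDW_RADII[key]


def kT(temperature: float = DEFAULT_T) -> float:
    """Thermal energy R*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
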