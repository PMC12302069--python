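"""Physical constants and fixed unit conventions.

Units are fixed package-wide: coordinates in Angstrom, energies in eV,
partial charges in units of the elementary charge, temperatures in K.
No unit autodetection is performed anywhere.
"""

# Boltzmann constant, eV/K (CODATA).
KB_EV: float = 8.617333262e-5

# Coulomb prefactor e^2/(4 pi eps0), in eV * Angstrom per e^2.
COULOMB_EV_ANG: float = 14.399645

# Absolute oxidation free energy of the standard hydrogen electrode,
# eV per electron; potentials are reported relative to this reference.
DG_SHE_EV: float = 4.44

# Simulation temperature of the aqueous systems this package targets, K.
DEFAULT_TEMPERATURE: float = 310.0

# Default QM cutoff radii swept when building QM regions, Angstrom.
# 0.0 is the sentinel for a solute-only QM region.
DEFAULT_QM_RADII: tuple[float, ...] = (0.0, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5)

# Standard atomic masses (u) for the elements the generators and parsers
# emit; center-of-mass computations refuse unknown elements rather than
# guessing.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
}

# TIP3P-like rigid water geometry and charges.
WATER_OH_BOND: float = 0.9572
WATER_HOH_ANGLE_DEG: float = 104.52
WATER_O_CHARGE: float = -0.834
WATER_H_CHARGE: float = 0.417


def atomic_mass(element: str) -> float:
    """Standard atomic mass of ``element`` (case-insensitive symbol)."""
    from .errors import ValidationError

    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise ValidationError(
            f"no standard atomic mass tabulated for element {element!r}"
        ) from None
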