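"""Bundled reference data for the five aqueous aromatic test solutes.

``REFERENCE_AVEG`` holds published ensemble-average vertical energy gaps
(AVEGs, eV) for benzene, phenol, phenolate, indole, and lumiflavin in water,
computed with range-separated hybrid DFT embedded in point charges, on
conformations from classical (MM) and hybrid QM/MM sampling, at the two
bracketing QM-region sizes (solute-only, labelled ``0.0``, and a 7.5 A
cutoff).  These are *inputs* for worked examples and regression checks —
data, not computation; this package cannot regenerate them at desk scale.

``EXPERIMENTAL_E_OX`` holds literature one-electron oxidation potentials
(V vs SHE); single values or (low, high) ranges where the measured spread is
wide.  Footnotes: the benzene value was measured in acetonitrile, the
lumiflavin value refers to FMN.
"""

from __future__ import annotations

MOLECULES = ("benzene", "phenol", "phenolate", "indole", "lumiflavin")

SAMPLINGS = ("MM", "QM/MM")

# {molecule: {(sampling, cutoff_label): (AVEG_reduced, AVEG_oxidized)}}  [eV]
REFERENCE_AVEG: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "benzene": {
        ("MM", "0.0"): (9.75, 4.91),
        ("MM", "7.5"): (9.32, 4.95),
        ("QM/MM", "0.0"): (9.44, 4.72),
        ("QM/MM", "7.5"): (9.03, 4.76),
    },
    "phenol": {
        ("MM", "0.0"): (9.23, 4.20),
        ("MM", "7.5"): (8.80, 4.18),
        ("QM/MM", "0.0"): (8.89, 3.99),
        ("QM/MM", "7.5"): (8.45, 3.92),
    },
    "phenolate": {
        ("MM", "0.0"): (7.80, 2.80),
        ("MM", "7.5"): (8.01, 3.36),
        ("QM/MM", "0.0"): (7.59, 2.57),
        ("QM/MM", "7.5"): (7.81, 3.11),
    },
    "indole": {
        ("MM", "0.0"): (8.12, 4.03),
        ("MM", "7.5"): (7.91, 4.09),
        ("QM/MM", "0.0"): (8.16, 3.64),
        ("QM/MM", "7.5"): (7.79, 3.67),
    },
    "lumiflavin": {
        ("MM", "0.0"): (5.74, 2.02),
        ("MM", "7.5"): (5.93, 2.31),
        ("QM/MM", "0.0"): (6.12, 2.31),
        ("QM/MM", "7.5"): (6.24, 2.58),
    },
}

# Literature one-electron oxidation potentials, V vs SHE.
# Values are either a float or an inclusive (low, high) range.
EXPERIMENTAL_E_OX: dict[str, float | tuple[float, float]] = {
    "benzene": 2.72,        # measured in acetonitrile
    "phenol": (1.0, 1.5),
    "phenolate": (0.83, 0.86),
    "indole": 1.24,
    "lumiflavin": 0.101,    # measured for FMN
}

EXPERIMENTAL_NOTES: dict[str, str] = {
    "benzene": "in acetonitrile",
    "lumiflavin": "for FMN",
}
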