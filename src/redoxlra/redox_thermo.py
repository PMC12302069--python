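"""Electrode potentials from oxidation free energies, and comparison tables.

The one-electron oxidation potential relative to the standard hydrogen
electrode follows the Nernst relation ``E = (dG_ox - dG_SHE) / (n F)``.
Because this package expresses free energies in eV *per transferred
electron*, the Faraday constant cancels numerically: an energy difference of
x eV per electron is a potential difference of x V, so the implementation
divides by the electron count only.  The SHE reference is the absolute
oxidation free energy 4.44 eV per electron.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .constants import DG_SHE_EV
from .errors import ValidationError
from .reference import EXPERIMENTAL_E_OX

__all__ = [
    "RedoxRecord",
    "oxidation_potential",
    "sampling_shift",
    "comparison_table",
    "format_comparison",
]


def oxidation_potential(
    dG_ox: float, dG_SHE: float = DG_SHE_EV, n_electrons: int = 1
) -> float:
    """Oxidation potential vs SHE, volts.

    ``dG_ox`` and ``dG_SHE`` are in eV per transferred electron, so
    ``(dG_ox - dG_SHE) / n_electrons`` is already in volts.
    """
    if n_electrons < 1:
        raise ValidationError(
            f"n_electrons must be a positive integer, got {n_electrons}"
        )
    return (dG_ox - dG_SHE) / n_electrons


@dataclass
class RedoxRecord:
    """One molecule/sampling row: free energy, potential, optional experiment."""

    molecule: str
    sampling_label: str
    dG_ox: float
    E_ox: float
    E_expt: float | tuple[float, float] | None = None

    @classmethod
    def from_free_energy(
        cls,
        molecule: str,
        sampling_label: str,
        dG_ox: float,
        dG_SHE: float = DG_SHE_EV,
        E_expt: float | tuple[float, float] | None = None,
    ) -> "RedoxRecord":
        return cls(
            molecule=molecule,
            sampling_label=sampling_label,
            dG_ox=dG_ox,
            E_ox=oxidation_potential(dG_ox, dG_SHE),
            E_expt=E_expt,
        )


def sampling_shift(record_a: RedoxRecord, record_b: RedoxRecord) -> float:
    """Signed potential shift ``E_ox(a) - E_ox(b)`` between two sampling
    protocols for the same molecule, volts."""
    if record_a.molecule != record_b.molecule:
        raise ValidationError(
            f"sampling_shift compares one molecule; got {record_a.molecule!r} "
            f"and {record_b.molecule!r}"
        )
    return record_a.E_ox - record_b.E_ox


def _fmt_expt(value: float | tuple[float, float] | None) -> str:
    if value is None:
        return ""
    if isinstance(value, tuple):
        lo, hi = value
        return f"{lo:g}–{hi:g}"
    return f"{value:g}"


def comparison_table(records: list[RedoxRecord]) -> pd.DataFrame:
    """Tabulate records as one row per molecule with per-sampling columns.

    Columns: ``molecule``, then ``dG_ox (<label>)`` / ``E_ox (<label>)`` for
    each sampling label in first-appearance order, then ``E_expt`` rendered
    as a single value, a ``low-high`` range, or blank when absent.
    """
    if not records:
        raise ValidationError("comparison_table requires at least one record")
    labels: list[str] = []
    molecules: list[str] = []
    for r in records:
        if r.sampling_label not in labels:
            labels.append(r.sampling_label)
        if r.molecule not in molecules:
            molecules.append(r.molecule)

    by_key = {(r.molecule, r.sampling_label): r for r in records}
    rows = []
    for mol in molecules:
        row: dict[str, object] = {"molecule": mol}
        expt: float | tuple[float, float] | None = None
        for lab in labels:
            r = by_key.get((mol, lab))
            row[f"dG_ox ({lab})"] = r.dG_ox if r else float("nan")
            row[f"E_ox ({lab})"] = r.E_ox if r else float("nan")
            if r is not None and r.E_expt is not None:
                expt = r.E_expt
        if expt is None:
            expt = EXPERIMENTAL_E_OX.get(mol)
        row["E_expt"] = _fmt_expt(expt)
        rows.append(row)
    return pd.DataFrame(rows)


def _round_half_up(v: float, places: int = 2) -> Decimal:
    q = Decimal(10) ** -places
    return Decimal(str(round(v, 10))).quantize(q, rounding=ROUND_HALF_UP)


def format_comparison(table: pd.DataFrame) -> str:
    """Pretty-print a comparison table with two-decimal energies.

    Uses half-up decimal rounding so borderline values (e.g. 7.135) print
    the way tabulated energies conventionally do (7.14).
    """
    df = table.copy()
    for col in df.columns:
        if col.startswith(("dG_ox", "E_ox")):
            df[col] = df[col].map(
                lambda v: str(_round_half_up(v)) if pd.notna(v) else ""
            )
    return df.to_string(index=False)
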