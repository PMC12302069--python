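"""Molecular snapshots, trajectories, and gap tables, plus their file formats.

Containers
----------
:class:`Atom`, :class:`Snapshot`, :class:`Trajectory` hold solvated-box
geometry with two partial-charge sets (one per oxidation state) and a role
per atom (``solute`` / ``water`` / ``counterion``).  :class:`GapTable` holds
per-frame vertical energy gaps labeled by state and QM-cutoff.

Formats
-------
* multi-frame XYZ (count line, comment line, ``element x y z`` records); a
  ``box=<L>`` token on the comment line carries the cubic box edge.  Roles
  and charges travel in a comma-delimited topology sidecar
  (``index,residue_id,role,charge_red,charge_ox``, 1-based indices).
* minimal PDB (ATOM/HETATM with MODEL/ENDMDL frames); waters are recognized
  by residue name, counterions by element.
* gap tables as comma-delimited text with header ``frame,state,cutoff,gap_eV``.

Only cubic boxes are supported; atom indices in emitted files are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContentError, ParseError, StructuralError, ValidationError

ROLES = ("solute", "water", "counterion")
STATES = ("reduced", "oxidized")

WATER_RESNAMES = {"HOH", "TIP3", "WAT", "SOL"}
COUNTERION_ELEMENTS = {"NA", "CL", "K"}

_CHARGE_TOL = 1e-6


@dataclass
class Atom:
    """One atom: element symbol, position (Angstrom), one partial charge per
    oxidation state (e), a role, and a residue id grouping atoms into
    molecules."""

    element: str
    position: np.ndarray
    charge_red: float = 0.0
    charge_ox: float = 0.0
    role: str = "solute"
    residue_id: int = 1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValidationError(
                f"atom position must be a 3-vector, got shape {self.position.shape}"
            )
        if not np.all(np.isfinite(self.position)):
            raise ValidationError("atom position components must be finite")
        if not self.element or not self.element.strip():
            raise ValidationError("atom element symbol must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown atom role {self.role!r}; expected one of {ROLES}"
            )

    def charge(self, state: str) -> float:
        if state == "reduced":
            return self.charge_red
        if state == "oxidized":
            return self.charge_ox
        raise ValidationError(f"unknown oxidation state {state!r}")


@dataclass
class Snapshot:
    """One frame: an ordered atom list in a cubic periodic box."""

    atoms: list[Atom]
    box_edge: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ---- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.box_edge <= 0:
            raise ValidationError(f"box_edge must be positive, got {self.box_edge}")
        if not self.atoms:
            raise ValidationError("snapshot has no atoms")

        # water residues are intact 3-site molecules (one O, two H)
        waters: dict[int, list[str]] = {}
        for a in self.atoms:
            if a.role == "water":
                waters.setdefault(a.residue_id, []).append(a.element.upper())
        for rid, elems in waters.items():
            if sorted(elems) != ["H", "H", "O"]:
                raise ValidationError(
                    f"water residue {rid} must contain exactly one O and two H, "
                    f"got {elems}"
                )

        n_ions = sum(a.role == "counterion" for a in self.atoms)
        if n_ions > 1:
            raise ValidationError(f"at most one counterion allowed, found {n_ions}")

        solute_rids = {a.residue_id for a in self.atoms if a.role == "solute"}
        if len(solute_rids) != 1:
            raise ValidationError(
                f"exactly one solute residue required, found residues {sorted(solute_rids)}"
            )
        # contiguity: solute atoms occupy one uninterrupted index block
        roles = [a.role for a in self.atoms]
        first = roles.index("solute")
        last = len(roles) - 1 - roles[::-1].index("solute")
        if any(r != "solute" for r in roles[first : last + 1]):
            raise ValidationError("solute residue must be contiguous in atom order")

        # charge bookkeeping: sum_ox = sum_red + 1 on the solute, provided the
        # source format carried charges at all (minimal PDB does not).
        q_red = sum(a.charge_red for a in self.atoms if a.role == "solute")
        q_ox = sum(a.charge_ox for a in self.atoms if a.role == "solute")
        any_charge = any(
            a.charge_red != 0.0 or a.charge_ox != 0.0
            for a in self.atoms
            if a.role == "solute"
        )
        if any_charge:
            if abs(q_red - round(q_red)) > _CHARGE_TOL:
                raise ValidationError(
                    f"solute reduced charges must sum to an integer formal charge, "
                    f"got {q_red:.8f}"
                )
            if abs(q_ox - (q_red + 1.0)) > _CHARGE_TOL:
                raise ValidationError(
                    f"solute oxidized charge sum must exceed the reduced sum by "
                    f"exactly +1 e, got red={q_red:.8f} ox={q_ox:.8f}"
                )

    # ---- array views ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def roles(self) -> np.ndarray:
        return np.array([a.role for a in self.atoms])

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=int)

    def charges(self, state: str) -> np.ndarray:
        return np.array([a.charge(state) for a in self.atoms], dtype=float)

    def indices(self, role: str | None = None, element: str | None = None,
                heavy: bool | None = None) -> np.ndarray:
        """Indices of atoms matching a role/element filter.

        ``heavy=True`` keeps non-hydrogen atoms only.
        """
        keep = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            keep &= self.roles == role
        if element is not None:
            keep &= np.char.upper(self.elements.astype(str)) == element.upper()
        if heavy:
            keep &= np.char.upper(self.elements.astype(str)) != "H"
        return np.nonzero(keep)[0]

    def solute_com(self) -> np.ndarray:
        """Mass-weighted center of mass of the solute, Angstrom."""
        from .constants import atomic_mass

        idx = self.indices(role="solute")
        masses = np.array([atomic_mass(self.atoms[i].element) for i in idx])
        pos = self.positions[idx]
        return masses @ pos / masses.sum()


@dataclass
class Trajectory:
    """Ordered snapshots sharing atom ordering and box edge."""

    snapshots: list[Snapshot]

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValidationError("trajectory must contain at least one snapshot")
        ref = self.snapshots[0]
        prev_frame = None
        for snap in self.snapshots:
            if snap.n_atoms != ref.n_atoms:
                raise StructuralError(
                    f"frame {snap.frame_index} has {snap.n_atoms} atoms "
                    f"but frame {ref.frame_index} had {ref.n_atoms}"
                )
            if snap.box_edge != ref.box_edge:
                raise StructuralError("all frames must share the same box edge")
            if prev_frame is not None and snap.frame_index <= prev_frame:
                raise StructuralError(
                    f"frame indices must be strictly increasing "
                    f"({prev_frame} then {snap.frame_index})"
                )
            prev_frame = snap.frame_index

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    @property
    def box_edge(self) -> float:
        return self.snapshots[0].box_edge


class GapTable:
    """Per-frame vertical energy gaps keyed by (frame, state, cutoff label).

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``frame, state, cutoff, gap_eV``.
    """

    COLUMNS = ("frame", "state", "cutoff", "gap_eV")

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"gap table missing columns {missing}")
        df = df[list(self.COLUMNS)]
        df["frame"] = df["frame"].astype(int)
        df["state"] = df["state"].astype(str)
        df["cutoff"] = df["cutoff"].astype(str)
        df["gap_eV"] = df["gap_eV"].astype(float)

        bad_state = df[~df["state"].isin(STATES)]
        if not bad_state.empty:
            rows = bad_state.index[:5].tolist()
            raise ValidationError(
                f"unknown state label(s) {sorted(bad_state['state'].unique())} "
                f"in row(s) {rows}"
            )
        if not np.all(np.isfinite(df["gap_eV"])):
            raise ValidationError("gap_eV values must all be finite")
        dup = df.duplicated(subset=["frame", "state", "cutoff"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValidationError(
                "duplicate (frame, state, cutoff) key: "
                f"({first['frame']}, {first['state']}, {first['cutoff']})"
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GapTable):
            return NotImplemented
        a = self.frame.sort_values(list(self.COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(self.COLUMNS)).reset_index(drop=True)
        return a.equals(b)

    def gaps(self, state: str, cutoff: str | None = None) -> np.ndarray:
        """Gap values for one state (and optionally one cutoff), frame-ordered."""
        if state not in STATES:
            raise ValidationError(f"unknown oxidation state {state!r}")
        df = self.frame[self.frame["state"] == state]
        if cutoff is not None:
            df = df[df["cutoff"] == str(cutoff)]
        return df.sort_values("frame")["gap_eV"].to_numpy()

    def ensemble(self, state: str, cutoff: str | None = None,
                 temperature: float = 310.0):
        """Build a :class:`~redoxlra.gap_statistics.GapEnsemble` view."""
        from .gap_statistics import GapEnsemble

        return GapEnsemble(
            state=state,
            gaps=self.gaps(state, cutoff),
            temperature=temperature,
            cutoff_label=str(cutoff) if cutoff is not None else "",
        )


# ---------------------------------------------------------------------------
# topology sidecar
# ---------------------------------------------------------------------------

def read_topology(path: str | Path) -> pd.DataFrame:
    """Read a topology sidecar (``index,residue_id,role,charge_red,charge_ox``).

    Indices are 1-based in the file and returned as-is, sorted.
    """
    df = pd.read_csv(path)
    required = ["index", "residue_id", "role", "charge_red", "charge_ox"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"topology file {path} missing columns {missing}")
    bad = df[~df["role"].isin(ROLES)]
    if not bad.empty:
        raise ValidationError(
            f"topology file {path} has unknown role(s) {sorted(bad['role'].unique())}"
        )
    df = df.sort_values("index").reset_index(drop=True)
    if not np.array_equal(df["index"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ValidationError(
            f"topology indices must be 1..N without gaps in {path}"
        )
    return df


def write_topology(snapshot: Snapshot, path: str | Path) -> None:
    rows = [
        {
            "index": i + 1,
            "residue_id": a.residue_id,
            "role": a.role,
            "charge_red": a.charge_red,
            "charge_ox": a.charge_ox,
        }
        for i, a in enumerate(snapshot.atoms)
    ]
    # full precision: rounding the two charge sets could break the exact
    # formal-charge bookkeeping the snapshot invariant enforces
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# multi-frame XYZ
# ---------------------------------------------------------------------------

def _parse_box_token(comment: str) -> float | None:
    for token in comment.split():
        if token.startswith("box="):
            try:
                return float(token[4:])
            except ValueError:
                raise ParseError(f"malformed box token {token!r} in comment line")
    return None


def read_xyz(path: str | Path, topology: str | Path | pd.DataFrame,
             box_edge: float | None = None) -> Trajectory:
    """Read a multi-frame XYZ file with a topology sidecar.

    Parameters
    ----------
    path:
        XYZ file: repeated blocks of count line, comment line, then
        ``element x y z`` records.  A ``box=<L>`` token on the comment line
        supplies the cubic box edge; otherwise ``box_edge`` must be given.
    topology:
        Sidecar path or already-loaded DataFrame carrying residue ids, roles,
        and the two charge sets per (1-based) atom index.
    """
    topo = topology if isinstance(topology, pd.DataFrame) else read_topology(topology)

    path = Path(path)
    lines = path.read_text().splitlines()
    snapshots: list[Snapshot] = []
    i = 0
    n_expected: int | None = None
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # trailing blank lines
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            )
        if n <= 0:
            raise ParseError(f"{path}: line {i + 1}: atom count must be positive")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise StructuralError(
                f"{path}: frame {frame + 1} declares {n} atoms but frame 1 had "
                f"{n_expected}"
            )
        if i + 1 >= len(lines):
            raise ParseError(f"{path}: line {i + 2}: missing comment line")
        comment = lines[i + 1]
        box = _parse_box_token(comment)
        if box is None:
            box = box_edge
        if box is None:
            raise ValidationError(
                f"{path}: frame {frame + 1} has no box= token and no box_edge "
                "was supplied"
            )
        if len(topo) != n:
            raise StructuralError(
                f"{path}: topology has {len(topo)} atoms but frame declares {n}"
            )
        atoms: list[Atom] = []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(f"{path}: line {ln + 1}: unexpected end of file")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {ln + 1}: expected 'element x y z', "
                    f"got {lines[ln]!r}"
                )
            try:
                pos = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(
                    f"{path}: line {ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                )
            row = topo.iloc[k]
            atoms.append(
                Atom(
                    element=parts[0],
                    position=np.array(pos),
                    charge_red=float(row["charge_red"]),
                    charge_ox=float(row["charge_ox"]),
                    role=str(row["role"]),
                    residue_id=int(row["residue_id"]),
                )
            )
        snapshots.append(Snapshot(atoms=atoms, box_edge=float(box), frame_index=frame))
        frame += 1
        i += 2 + n
    if not snapshots:
        raise ContentError(f"{path}: no frames found")
    return Trajectory(snapshots)


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-frame XYZ file with ``frame=`` and ``box=`` comment tokens."""
    with open(path, "w") as fh:
        for snap in traj:
            fh.write(f"{snap.n_atoms}\n")
            fh.write(f"frame={snap.frame_index} box={snap.box_edge:.6f}\n")
            for a in snap.atoms:
                x, y, z = a.position
                fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# minimal PDB
# ---------------------------------------------------------------------------

def _pdb_element(line: str) -> str:
    el = line[76:78].strip() if len(line) >= 78 else ""
    if not el:
        # fall back on the atom-name column, stripping digits
        name = line[12:16].strip()
        el = "".join(c for c in name if c.isalpha())[:2]
        if len(el) == 2 and el[1].islower() is False and el.upper() not in (
            COUNTERION_ELEMENTS | {"MG", "FE", "ZN"}
        ):
            el = el[0]
    return el.upper()


def read_pdb_minimal(path: str | Path, box_edge: float | None = None) -> Trajectory:
    """Read a minimal PDB (ATOM/HETATM records, MODEL/ENDMDL frames).

    Roles: waters by residue name (HOH/TIP3/WAT/SOL), counterions by element
    (NA/CL/K), everything else solute.  PDB carries no partial charges, so
    both charge sets are zero.  A CRYST1 record supplies the cubic box edge
    when present; otherwise ``box_edge`` must be given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    frames: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    seen_model = False
    box = box_edge
    # residue id remapping so that each (chain, resseq, resname) maps to a
    # compact integer, waters distinct from the solute block
    for ln_no, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec == "CRYST1":
            try:
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
            except ValueError:
                raise ParseError(f"{path}: line {ln_no}: malformed CRYST1 record")
            if not (math.isclose(a, b, rel_tol=1e-6) and math.isclose(a, c, rel_tol=1e-6)):
                raise ValidationError(
                    f"{path}: non-cubic box ({a}, {b}, {c}) is unsupported"
                )
            box = a
        elif rec == "MODEL":
            if current:
                frames.append(current)
                current = []
            in_model = True
            seen_model = True
        elif rec == "ENDMDL":
            frames.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(
                    f"{path}: line {ln_no}: truncated {rec} record"
                )
            # columns 18-21: three-letter PDB names plus the four-letter
            # water names (TIP3 etc.) common in simulation-derived files
            resname = line[17:21].strip().upper()
            try:
                resseq = int(line[22:26])
            except ValueError:
                raise ParseError(f"{path}: line {ln_no}: malformed residue number")
            try:
                pos = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise ParseError(f"{path}: line {ln_no}: malformed coordinates")
            element = _pdb_element(line)
            if resname in WATER_RESNAMES:
                role = "water"
            elif element in COUNTERION_ELEMENTS and resname not in WATER_RESNAMES:
                role = "counterion"
            else:
                role = "solute"
            current.append(
                Atom(
                    element=element.capitalize() if len(element) > 1 else element,
                    position=np.array(pos),
                    role=role,
                    residue_id=resseq,
                )
            )
    if current or (not frames and not seen_model):
        if current:
            frames.append(current)
    if not frames or not any(frames):
        raise ContentError(f"{path}: no ATOM/HETATM records found")
    if box is None:
        raise ValidationError(
            f"{path}: no CRYST1 record and no box_edge supplied"
        )

    snapshots = []
    for i, atoms in enumerate(f for f in frames if f):
        if not any(a.role == "solute" for a in atoms):
            raise ContentError(f"{path}: frame {i + 1} contains no solute atoms")
        # collapse all solute residues into one residue id (minimal PDB may
        # number a multi-residue solute arbitrarily; the container requires a
        # single contiguous solute residue)
        solute_rid = min(a.residue_id for a in atoms if a.role == "solute")
        for a in atoms:
            if a.role == "solute":
                a.residue_id = solute_rid
        snapshots.append(Snapshot(atoms=atoms, box_edge=float(box), frame_index=i))
    return Trajectory(snapshots)


# ---------------------------------------------------------------------------
# gap tables
# ---------------------------------------------------------------------------

def read_gap_table(path: str | Path) -> GapTable:
    """Read a comma-delimited gap table with header ``frame,state,cutoff,gap_eV``."""
    try:
        df = pd.read_csv(path, dtype={"cutoff": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"could not parse gap table {path}: {exc}") from exc
    return GapTable(df)


def write_gap_table(table: GapTable, path: str | Path) -> None:
    """Write a gap table in the canonical dialect (6 decimal places)."""
    table.frame.to_csv(path, index=False, float_format="%.6f")


def gap_table_from_arrays(
    reduced: Sequence[float],
    oxidized: Sequence[float],
    cutoff: str = "7.5",
    frames: Iterable[int] | None = None,
) -> GapTable:
    """Assemble a :class:`GapTable` from two per-state gap vectors."""
    reduced = np.asarray(reduced, dtype=float)
    oxidized = np.asarray(oxidized, dtype=float)
    rows = []
    fr = list(frames) if frames is not None else None
    for state, gaps in (("reduced", reduced), ("oxidized", oxidized)):
        idx = fr if fr is not None else range(len(gaps))
        for f, g in zip(idx, gaps):
            rows.append({"frame": f, "state": state, "cutoff": cutoff, "gap_eV": g})
    return GapTable(pd.DataFrame(rows))
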