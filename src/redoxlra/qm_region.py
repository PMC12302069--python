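"""QM-region construction for electrostatically embedded single points.

A QM region contains the solute and every *whole* water molecule whose
oxygen lies within a cutoff radius of the solute, selected either from the
solute center of mass ("com" criterion) or from the nearest solute atom
("atom" criterion).  Radius 0.0 is the sentinel for a solute-only QM region.
Everything outside the QM region — distant waters and the counterion, which
is never promoted to QM — becomes a fixed point charge drawn from the charge
set of the requested oxidation state.

The module also provides the cutoff sweep used to report mean QM water
counts per radius, a fixed-charge Coulomb surrogate for the vertical energy
gap (pipeline plumbing and qualitative trends only — it carries no
polarization and never stands in for a quantum treatment), and writers for
the QM-geometry / point-charge input files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import COULOMB_EV_ANG, DEFAULT_QM_RADII
from .errors import ClashError, ValidationError
from .solvation import min_image_distance
from .structures_io import Snapshot, Trajectory

__all__ = [
    "QMRegionSpec",
    "QMRegion",
    "select_qm_region",
    "cutoff_sweep",
    "surrogate_gap",
    "write_embedding_input",
]

CRITERIA = ("com", "atom")


@dataclass(frozen=True)
class QMRegionSpec:
    """Selection criterion ("com" or "atom") and cutoff radius in Angstrom;
    radius 0.0 selects the solute only."""

    criterion: str = "com"
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValidationError(
                f"unknown criterion {self.criterion!r}; expected one of {CRITERIA}"
            )
        if self.radius < 0:
            raise ValidationError(f"radius must be >= 0, got {self.radius}")


@dataclass
class QMRegion:
    """Resolved QM atom set plus the complementary MM point charges.

    Every atom of the snapshot is in exactly one of ``qm_atom_indices`` or
    the MM charge list; selected waters contribute all three atoms to QM.
    """

    qm_atom_indices: np.ndarray
    qm_water_residues: set[int]
    mm_positions: np.ndarray
    mm_charges: np.ndarray
    mm_atom_indices: np.ndarray
    charge_state_used: str

    @property
    def mm_point_charges(self) -> list[tuple[np.ndarray, float]]:
        """(position, charge) pairs for the MM environment."""
        return [(p, float(q)) for p, q in zip(self.mm_positions, self.mm_charges)]

    @property
    def n_qm_waters(self) -> int:
        return len(self.qm_water_residues)


def select_qm_region(
    snap: Snapshot, spec: QMRegionSpec, charge_state: str = "reduced"
) -> QMRegion:
    """Resolve a QM region on one snapshot.

    Water membership is decided solely by its oxygen's minimum-image
    distance: "com" measures from the solute center of mass, "atom" from the
    nearest solute atom.  Ties at exactly the radius are included.  The
    counterion always stays in the MM charge list with its charge for
    ``charge_state``.
    """
    if charge_state not in ("reduced", "oxidized"):
        raise ValidationError(f"unknown oxidation state {charge_state!r}")
    box = snap.box_edge
    if spec.radius > box / 2:
        raise ValidationError(
            f"radius {spec.radius} exceeds half the box edge ({box / 2})"
        )

    pos = snap.positions
    solute_idx = snap.indices(role="solute")
    water_o_idx = snap.indices(role="water", element="O")

    selected_residues: set[int] = set()
    if spec.radius > 0 and water_o_idx.size:
        o_pos = pos[water_o_idx]
        if spec.criterion == "com":
            d = min_image_distance(snap.solute_com()[None, :], o_pos, box)
        else:  # nearest solute atom
            all_d = min_image_distance(
                pos[solute_idx][:, None, :], o_pos[None, :, :], box
            )
            d = all_d.min(axis=0)
        rids = snap.residue_ids[water_o_idx]
        selected_residues = set(int(r) for r in rids[d <= spec.radius])

    rid_arr = snap.residue_ids
    roles = snap.roles
    in_qm = roles == "solute"
    if selected_residues:
        in_qm |= (roles == "water") & np.isin(rid_arr, sorted(selected_residues))

    qm_idx = np.nonzero(in_qm)[0]
    mm_idx = np.nonzero(~in_qm)[0]
    return QMRegion(
        qm_atom_indices=qm_idx,
        qm_water_residues=selected_residues,
        mm_positions=pos[mm_idx],
        mm_charges=snap.charges(charge_state)[mm_idx],
        mm_atom_indices=mm_idx,
        charge_state_used=charge_state,
    )


def cutoff_sweep(
    traj: Trajectory,
    radii: tuple[float, ...] = DEFAULT_QM_RADII,
    criterion: str = "com",
) -> pd.DataFrame:
    """Mean and standard deviation of QM water counts per cutoff radius.

    Returns a DataFrame with columns ``radius, mean_waters, sd_waters``
    aggregated over all frames.
    """
    radii = tuple(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValidationError("radii must be sorted strictly ascending")
    counts = np.empty((len(radii), len(traj)))
    for j, r in enumerate(radii):
        spec = QMRegionSpec(criterion=criterion, radius=r)
        for i, snap in enumerate(traj):
            counts[j, i] = select_qm_region(snap, spec).n_qm_waters
    return pd.DataFrame(
        {
            "radius": radii,
            "mean_waters": counts.mean(axis=1),
            "sd_waters": counts.std(axis=1, ddof=1) if len(traj) > 1
            else np.zeros(len(radii)),
        }
    )


def surrogate_gap(snap: Snapshot, region: QMRegion, dE_gas: float) -> float:
    """Fixed-charge Coulomb surrogate for the vertical energy gap, eV.

    ``dE = dE_gas + sum_i sum_j k_e (q_i^ox - q_i^red) q_j / r_ij`` over
    solute atoms i and MM point charges j, with minimum-image distances.
    Waters promoted to the QM region contribute no point-charge term (their
    response is what a real quantum treatment would capture).  This is
    pipeline plumbing with qualitative trends only: fixed charges, no
    polarization, no exchange — it does not emulate quantum-level gaps.
    """
    solute_idx = snap.indices(role="solute")
    dq = snap.charges("oxidized")[solute_idx] - snap.charges("reduced")[solute_idx]
    if region.mm_charges.size == 0 or np.all(dq == 0):
        return float(dE_gas)
    pos = snap.positions
    r = min_image_distance(
        pos[solute_idx][:, None, :], region.mm_positions[None, :, :], snap.box_edge
    )
    if np.any(r < 0.5):
        i, j = np.unravel_index(np.argmin(r), r.shape)
        ai = snap.atoms[solute_idx[i]]
        aj = snap.atoms[region.mm_atom_indices[j]]
        raise ClashError(
            f"solute atom {solute_idx[i] + 1} ({ai.element}) and MM atom "
            f"{region.mm_atom_indices[j] + 1} ({aj.element}) are "
            f"{r[i, j]:.3f} A apart (< 0.5 A)"
        )
    coupling = COULOMB_EV_ANG * np.sum((dq[:, None] * region.mm_charges[None, :]) / r)
    return float(dE_gas + coupling)


def write_embedding_input(
    snap: Snapshot,
    region: QMRegion,
    path_qm: str | Path,
    path_charges: str | Path,
) -> None:
    """Write the QM geometry (XYZ) and MM point charges for one single point.

    ``path_qm`` receives an XYZ block of the QM atoms in original order;
    ``path_charges`` a text file whose first line is the charge count
    followed by one ``x y z q`` line per MM charge (6 decimals).
    """
    try:
        with open(path_qm, "w") as fh:
            fh.write(f"{region.qm_atom_indices.size}\n")
            fh.write(
                f"qm-region frame={snap.frame_index} "
                f"state={region.charge_state_used} "
                f"waters={region.n_qm_waters}\n"
            )
            for i in region.qm_atom_indices:
                a = snap.atoms[i]
                x, y, z = a.position
                fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")
        with open(path_charges, "w") as fh:
            fh.write(f"{region.mm_charges.size}\n")
            for p, q in zip(region.mm_positions, region.mm_charges):
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {q:.6f}\n")
    except OSError as exc:
        raise OSError(
            f"failed writing embedding input ({path_qm}, {path_charges}): {exc}"
        ) from exc


def read_point_charges(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a point-charge file back into (positions, charges) arrays."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    data = np.array([[float(v) for v in ln.split()] for ln in lines[1 : n + 1]])
    if data.shape != (n, 4):
        raise ValidationError(
            f"{path}: expected {n} 'x y z q' records, got shape {data.shape}"
        )
    return data[:, :3], data[:, 3]
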