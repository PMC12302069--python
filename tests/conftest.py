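import numpy as np
import pytest

from redoxlra import (
    Atom,
    Snapshot,
    SyntheticBoxConfig,
    Trajectory,
    generate_solvated_box,
)


@pytest.fixture(scope="session")
def small_box() -> Trajectory:
    """Charged solute in a small solvated periodic box, several frames."""
    cfg = SyntheticBoxConfig(
        n_waters=120,
        seed=3,
        box_edge=25.0,
        solute_template="ring6-O-",
        n_frames=10,
        jitter_sd=0.05,
    )
    return generate_solvated_box(cfg)


def make_point_solute_snapshot(
    water_o_positions,
    box_edge: float = 50.0,
    frame_index: int = 0,
    ion_position=None,
    ion_element: str = "K",
    solute_position=None,
):
    """Snapshot with a single-carbon solute (ox-red charge difference +1)
    plus waters at prescribed oxygen positions (hydrogens offset along x/y)."""
    center = (
        np.asarray(solute_position, dtype=float)
        if solute_position is not None
        else np.full(3, box_edge / 2.0)
    )
    atoms = [Atom("C", center, charge_red=0.0, charge_ox=1.0, role="solute",
                  residue_id=1)]
    rid = 2
    for o in water_o_positions:
        o = np.asarray(o, dtype=float)
        atoms.append(Atom("O", o, -0.834, -0.834, "water", rid))
        atoms.append(Atom("H", o + [0.9572, 0, 0], 0.417, 0.417, "water", rid))
        atoms.append(Atom("H", o + [0, 0.9572, 0], 0.417, 0.417, "water", rid))
        rid += 1
    if ion_position is not None:
        atoms.append(
            Atom(ion_element, np.asarray(ion_position, dtype=float),
                 1.0, 1.0, "counterion", rid)
        )
    return Snapshot(atoms=atoms, box_edge=box_edge, frame_index=frame_index)
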