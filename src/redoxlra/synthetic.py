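"""Synthetic gap ensembles and solvated boxes for desk-scale testing.

Real gap data comes from MD sampling followed by quantum single points;
neither runs at desk scale, so this module emulates their statistical and
geometric structure instead:

* gap ensembles with exact linear-response statistics — two Gaussians with
  means ``dG +/- lambda`` and common variance ``2 kB T lambda`` (the
  fluctuation-dissipation relation tying the gap spread to the
  reorganization energy), optionally skewed with matched mean/variance;
* cubic solvated boxes with a rigid idealized solute template, TIP3P-like
  3-site rigid waters, and an optional single neutralizing counterion.

Frames are independent draws, not time-correlated dynamics, and template
charges are plausible hand-assigned stand-ins (exact formal sums, ox - red
= +1 distributed over heavy atoms), not derived from any electronic
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import (
    DEFAULT_TEMPERATURE,
    KB_EV,
    WATER_H_CHARGE,
    WATER_HOH_ANGLE_DEG,
    WATER_O_CHARGE,
    WATER_OH_BOND,
)
from .errors import ValidationError
from .gap_statistics import GapEnsemble
from .structures_io import Atom, Snapshot, Trajectory

__all__ = [
    "SyntheticGapConfig",
    "SyntheticBoxConfig",
    "generate_gap_ensembles",
    "solute_template",
    "generate_solvated_box",
    "TEMPLATE_NAMES",
]

_MIN_HEAVY_DIST = 2.4  # A, rejection threshold between heavy atoms
_MAX_ATTEMPTS = 100_000


# ---------------------------------------------------------------------------
# gap ensembles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGapConfig:
    """Parameters of the linear-response gap generator.

    ``dG_true`` / ``lambda_true`` (eV) place the two state means at
    ``dG_true +/- lambda_true``; the common spread follows from the
    temperature as ``sigma = sqrt(2 kB T lambda_true)``.  ``skew`` != 0
    draws from a skew-normal reshaped to the same mean and variance.
    """

    dG_true: float
    lambda_true: float
    temperature: float = DEFAULT_TEMPERATURE
    n_per_state: int = 500
    seed: int = 0
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_true < 0:
            raise ValidationError(f"lambda_true must be >= 0, got {self.lambda_true}")
        if self.n_per_state < 1:
            raise ValidationError(f"n_per_state must be >= 1, got {self.n_per_state}")
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0, got {self.temperature}")

    @property
    def sigma(self) -> float:
        return math.sqrt(2.0 * KB_EV * self.temperature * self.lambda_true)


def _draw(rng: np.random.Generator, mean: float, sigma: float, n: int,
          skew: float) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, mean)
    if skew == 0.0:
        return rng.normal(mean, sigma, size=n)
    # skew-normal with shape a, rescaled so mean and variance match exactly
    a = skew
    delta = a / math.sqrt(1.0 + a * a)
    scale = sigma / math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    loc = mean - scale * delta * math.sqrt(2.0 / math.pi)
    return stats.skewnorm.rvs(a, loc=loc, scale=scale, size=n, random_state=rng)


def generate_gap_ensembles(
    cfg: SyntheticGapConfig,
) -> tuple[GapEnsemble, GapEnsemble]:
    """Draw the (reduced, oxidized) gap ensembles for one synthetic system."""
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.sigma
    red = _draw(rng, cfg.dG_true + cfg.lambda_true, sigma, cfg.n_per_state, cfg.skew)
    ox = _draw(rng, cfg.dG_true - cfg.lambda_true, sigma, cfg.n_per_state, cfg.skew)
    return (
        GapEnsemble(state="reduced", gaps=red, temperature=cfg.temperature),
        GapEnsemble(state="oxidized", gaps=ox, temperature=cfg.temperature),
    )


# ---------------------------------------------------------------------------
# solute templates
# ---------------------------------------------------------------------------

_BOND = 1.4       # aromatic ring bond, A
_CH_BOND = 1.09
_NH_BOND = 1.01
_OH_BOND = 0.96
_CO_BOND = 1.36


def _hexagon(center: np.ndarray, flat_top: bool = False) -> np.ndarray:
    """Vertices of a regular hexagon of side _BOND around ``center``."""
    phase = 30.0 if flat_top else 0.0
    ang = np.deg2rad(phase + 60.0 * np.arange(6))
    return center + _BOND * np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)


def _dedupe(points: np.ndarray, tol: float = 0.05) -> np.ndarray:
    kept: list[np.ndarray] = []
    for p in points:
        if not any(np.linalg.norm(p - q) < tol for q in kept):
            kept.append(p)
    return np.array(kept)


def _ring_system(hex_centers: list[np.ndarray], extra: np.ndarray | None = None,
                 flat_top: bool = False) -> np.ndarray:
    pts = np.concatenate(
        [_hexagon(np.asarray(c, dtype=float), flat_top) for c in hex_centers]
        + ([extra] if extra is not None else [])
    )
    return _dedupe(pts)


def _add_ring_hydrogens(heavy: np.ndarray, elements: list[str],
                        skip: set[int] | None = None) -> list[tuple[str, np.ndarray]]:
    """One H per perimeter heavy atom with exactly two ring neighbours,
    pointing away from its neighbours' midpoint."""
    skip = skip or set()
    out: list[tuple[str, np.ndarray]] = []
    n = heavy.shape[0]
    for i in range(n):
        if i in skip:
            continue
        d = np.linalg.norm(heavy - heavy[i], axis=1)
        nbrs = np.nonzero((d > 0.1) & (d < 1.55))[0]
        if nbrs.size != 2:
            continue
        direction = heavy[i] - heavy[nbrs].mean(axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        bond = _NH_BOND if elements[i] == "N" else _CH_BOND
        out.append(("H", heavy[i] + bond * direction / norm))
    return out


def _balance_charges(n_atoms: int, heavy_mask: np.ndarray, base: np.ndarray,
                     formal_red: int) -> tuple[np.ndarray, np.ndarray]:
    """Force exact formal sums: reduced sums to ``formal_red``; oxidized adds
    +1 e spread uniformly over heavy atoms."""
    n_heavy = int(heavy_mask.sum())
    red = base.copy()
    red[heavy_mask] += (formal_red - base.sum()) / n_heavy
    ox = red.copy()
    ox[heavy_mask] += 1.0 / n_heavy
    return red, ox


TEMPLATE_NAMES = ("ring6", "ring6-OH", "ring6-O-", "ring9", "tricycle")

# formal charge of the reduced state per template
_FORMAL_RED = {"ring6": 0, "ring6-OH": 0, "ring6-O-": -1, "ring9": 0, "tricycle": 0}


def solute_template(name: str) -> list[Atom]:
    """Rigid idealized solute geometry with both charge sets.

    Bundled templates (geometric stand-ins for small aromatic redox
    molecules, not quantum-accurate):

    * ``ring6``     — bare six-membered ring (benzene-like), neutral;
    * ``ring6-OH``  — ring with a hydroxyl substituent (phenol-like);
    * ``ring6-O-``  — ring with an oxide substituent (phenolate-like), -1;
    * ``ring9``     — fused 6+5 ring with one NH (indole-like);
    * ``tricycle``  — three linearly fused rings with two N (flavin-like).

    Charge sets are hand-assigned stand-ins with exact bookkeeping: the
    reduced set sums to the formal charge and the oxidized set to formal+1.
    """
    if name == "ring6":
        heavy = _hexagon(np.zeros(3))
        elements = ["C"] * 6
        hydro = _add_ring_hydrogens(heavy, elements)
        base = np.concatenate([np.full(6, -0.115), np.full(len(hydro), 0.115)])
    elif name in ("ring6-OH", "ring6-O-"):
        ring = _hexagon(np.zeros(3))
        o_pos = ring[0] + _CO_BOND * ring[0] / np.linalg.norm(ring[0])
        heavy = np.vstack([ring, o_pos])
        elements = ["C"] * 6 + ["O"]
        hydro = _add_ring_hydrogens(heavy, elements)  # 5 ring H (C0 has O)
        if name == "ring6-OH":
            oh_dir = np.array([math.cos(math.radians(30.0)),
                               math.sin(math.radians(30.0)), 0.0])
            hydro.append(("H", o_pos + _OH_BOND * oh_dir))
            base = np.concatenate([
                [0.20], np.full(5, -0.115), [-0.60],
                np.full(len(hydro) - 1, 0.115), [0.40],
            ])
        else:
            base = np.concatenate([
                [0.10], np.full(5, -0.115), [-1.00],
                np.full(len(hydro), 0.115),
            ])
    elif name == "ring9":
        hexa = _hexagon(np.zeros(3))
        # fuse a regular pentagon on the hexagon edge between vertices 1 and 2
        v1, v2 = hexa[1], hexa[2]
        mid = 0.5 * (v1 + v2)
        outward = mid / np.linalg.norm(mid)
        apothem = _BOND / (2.0 * math.tan(math.pi / 5.0))
        circ = _BOND / (2.0 * math.sin(math.pi / 5.0))
        center5 = mid + apothem * outward
        along = (v1 - v2) / np.linalg.norm(v1 - v2)
        base_ang = math.atan2(*(v1 - center5)[[1, 0]])
        ang = base_ang + 2.0 * math.pi / 5.0 * np.arange(5)
        penta = center5 + circ * np.stack(
            [np.cos(ang), np.sin(ang), np.zeros(5)], axis=1
        )
        heavy = _dedupe(np.vstack([hexa, penta]))
        # nitrogen at the pentagon apex (heavy atom farthest from the origin)
        apex = int(np.argmax(np.linalg.norm(heavy, axis=1)))
        elements = ["C"] * len(heavy)
        elements[apex] = "N"
        hydro = _add_ring_hydrogens(heavy, elements)
        nq = -0.35
        base = np.concatenate([
            np.where(np.arange(len(heavy)) == apex, nq, -0.08),
            np.full(len(hydro), 0.1),
        ])
    elif name == "tricycle":
        d = math.sqrt(3.0) * _BOND
        heavy = _ring_system(
            [np.zeros(3), np.array([d, 0.0, 0.0]), np.array([2 * d, 0.0, 0.0])],
            flat_top=True,
        )
        elements = ["C"] * len(heavy)
        # two nitrogens at the top/bottom vertices of the middle ring
        for target in (np.array([d, _BOND, 0.0]), np.array([d, -_BOND, 0.0])):
            idx = int(np.argmin(np.linalg.norm(heavy - target, axis=1)))
            elements[idx] = "N"
        hydro = _add_ring_hydrogens(heavy, elements)
        base = np.concatenate([
            np.array([-0.30 if e == "N" else -0.06 for e in elements]),
            np.full(len(hydro), 0.09),
        ])
    else:
        raise ValidationError(
            f"unknown solute template {name!r}; available: {', '.join(TEMPLATE_NAMES)}"
        )

    all_elements = elements + [e for e, _ in hydro]
    positions = np.vstack([heavy] + [p for _, p in hydro]) if hydro else heavy
    heavy_mask = np.array([e != "H" for e in all_elements])
    red, ox = _balance_charges(len(all_elements), heavy_mask, base, _FORMAL_RED[name])
    return [
        Atom(
            element=all_elements[i],
            position=positions[i],
            charge_red=float(red[i]),
            charge_ox=float(ox[i]),
            role="solute",
            residue_id=1,
        )
        for i in range(len(all_elements))
    ]


# ---------------------------------------------------------------------------
# solvated boxes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBoxConfig:
    """Parameters of the solvated-box generator.

    ``box_edge`` defaults to the 50 A cubic box the gap-sampling protocol
    targets.  ``include_counterion=None`` adds an ion automatically when the
    solute's reduced formal charge is nonzero.  ``jitter_sd`` is a per-atom
    Gaussian displacement of the solute, giving frames a small amount of
    conformational variance.
    """

    n_waters: int
    seed: int
    box_edge: float = 50.0
    solute_template: str = "ring6"
    include_counterion: bool | None = None
    n_frames: int = 1
    jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_waters < 0:
            raise ValidationError(f"n_waters must be >= 0, got {self.n_waters}")
        if self.box_edge <= 0:
            raise ValidationError(f"box_edge must be > 0, got {self.box_edge}")
        if self.n_frames < 1:
            raise ValidationError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.jitter_sd < 0:
            raise ValidationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")


def _min_image_dists(p: np.ndarray, others: np.ndarray, box: float) -> np.ndarray:
    d = others - p
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=1)


def _water_orientation(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    w = rng.normal(size=3)
    w -= (w @ u) * u
    w /= np.linalg.norm(w)
    theta = math.radians(WATER_HOH_ANGLE_DEG)
    h1 = WATER_OH_BOND * u
    h2 = WATER_OH_BOND * (math.cos(theta) * u + math.sin(theta) * w)
    return h1, h2


def generate_solvated_box(cfg: SyntheticBoxConfig) -> Trajectory:
    """Seeded rejection-sampled solvated box, one independent draw per frame.

    The solute sits at the box center (plus per-atom jitter); water oxygens
    are placed uniformly subject to a 2.4 A heavy-atom exclusion under
    minimum image, with rigid TIP3P-like hydrogens in random orientation;
    the optional counterion lands uniformly at least 3 A from any solute
    atom.  Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    template = solute_template(cfg.solute_template)
    formal_red = round(sum(a.charge_red for a in template))
    want_ion = (
        cfg.include_counterion
        if cfg.include_counterion is not None
        else formal_red != 0
    )
    box = cfg.box_edge
    center = np.full(3, box / 2.0)

    snapshots: list[Snapshot] = []
    for frame in range(cfg.n_frames):
        atoms: list[Atom] = []
        sol_pos = np.array([a.position for a in template]) + center
        if cfg.jitter_sd > 0:
            sol_pos = sol_pos + rng.normal(scale=cfg.jitter_sd, size=sol_pos.shape)
        for a, p in zip(template, sol_pos):
            atoms.append(Atom(element=a.element, position=p,
                              charge_red=a.charge_red, charge_ox=a.charge_ox,
                              role="solute", residue_id=1))
        heavy = sol_pos[[a.element != "H" for a in template]]

        next_rid = 2
        ion_pos: np.ndarray | None = None
        if want_ion:
            for _ in range(_MAX_ATTEMPTS):
                cand = rng.uniform(0.0, box, size=3)
                if np.min(_min_image_dists(cand, sol_pos, box)) > 3.0:
                    ion_pos = cand
                    break
            if ion_pos is None:
                raise ValidationError(
                    "could not place the counterion 3 A away from the solute"
                )
            heavy = np.vstack([heavy, ion_pos])

        o_positions = np.empty((0, 3))
        attempts = 0
        placed = 0
        while placed < cfg.n_waters:
            attempts += 1
            if attempts > _MAX_ATTEMPTS:
                raise ValidationError(
                    f"failed to place water {placed + 1}/{cfg.n_waters} after "
                    f"{_MAX_ATTEMPTS} attempts; reduce n_waters or enlarge the box"
                )
            cand = rng.uniform(0.0, box, size=3)
            if np.min(_min_image_dists(cand, heavy, box)) < _MIN_HEAVY_DIST:
                continue
            heavy = np.vstack([heavy, cand])
            o_positions = np.vstack([o_positions, cand])
            placed += 1

        for o in o_positions:
            h1, h2 = _water_orientation(rng)
            atoms.append(Atom("O", o, WATER_O_CHARGE, WATER_O_CHARGE,
                              "water", next_rid))
            atoms.append(Atom("H", o + h1, WATER_H_CHARGE, WATER_H_CHARGE,
                              "water", next_rid))
            atoms.append(Atom("H", o + h2, WATER_H_CHARGE, WATER_H_CHARGE,
                              "water", next_rid))
            next_rid += 1

        if ion_pos is not None:
            elem, q = ("NA", 1.0) if formal_red < 0 else ("CL", -1.0)
            atoms.append(Atom(elem, ion_pos, q, q, "counterion", next_rid))

        snapshots.append(Snapshot(atoms=atoms, box_edge=box, frame_index=frame))
    return Trajectory(snapshots)
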