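"""Solvent structure around the solute and solute--counterion geometry.

Provides minimum-image distances in the cubic periodic box, radial
distribution functions g(r) between atom selections, first-solvation-shell
descriptors (peak position ``r_max``, first minimum ``r_min1``, coordination
number ``n_wat``), and the per-distance-bin gap statistics used to verify
that a single neutralizing counterion does not bias the gap ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .gap_statistics import GapEnsemble
from .structures_io import Snapshot, Trajectory

__all__ = [
    "min_image_distance",
    "RDFProfile",
    "radial_distribution",
    "first_shell",
    "IonDistanceBins",
    "ion_distance_bins",
]


def min_image_distance(a: np.ndarray, b: np.ndarray, box_edge: float) -> float | np.ndarray:
    """Minimum-image Euclidean distance(s) in a cubic box of edge ``box_edge``.

    Broadcasts over leading axes; the last axis must have length 3.  Each
    displacement component is wrapped into (-L/2, L/2].
    """
    if box_edge <= 0:
        raise ValidationError(f"box_edge must be positive, got {box_edge}")
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= box_edge * np.round(d / box_edge)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out


@dataclass
class RDFProfile:
    """Binned radial distribution function with first-shell descriptors.

    ``r_max``/``r_min1``/``n_wat`` are NaN/NaN/0 with ``shell_defined=False``
    when no qualifying first peak exists (e.g. a structureless g(r) = 1).
    """

    bin_centers: np.ndarray
    g: np.ndarray
    r_max: float
    r_min1: float
    n_wat: float
    reference_selection: str
    target_selection: str
    solvent_density: float
    bin_width: float
    raw_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    n_frames: int = 0
    n_reference: int = 0
    shell_defined: bool = True


def _selection_label(sel: dict) -> str:
    return ",".join(f"{k}={v}" for k, v in sel.items())


def radial_distribution(
    traj: Trajectory,
    reference: dict,
    target: dict,
    bin_width: float = 0.05,
    r_cut: float = 10.0,
) -> RDFProfile:
    """g(r) between two atom selections, averaged over frames.

    Selections are role/element/heavy filters, e.g.
    ``{"role": "solute", "heavy": True}`` for solute heavy atoms and
    ``{"role": "water", "element": "O"}`` for water oxygens.  Counts in each
    shell [r, r+dr) are normalized by the ideal-gas expectation
    ``N_ref * frames * rho_target * (4 pi / 3)[(r+dr)^3 - r^3]`` with
    ``rho_target = N_target / L^3``.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    box = traj.box_edge
    if r_cut > box / 2 + 1e-9:
        raise ValidationError(
            f"r_cut={r_cut} exceeds half the box edge ({box / 2}); "
            "minimum-image distances are ambiguous beyond L/2"
        )
    ref_idx = traj[0].indices(**reference)
    tgt_idx = traj[0].indices(**target)
    if ref_idx.size == 0 or tgt_idx.size == 0:
        raise ValidationError(
            f"empty selection: reference={_selection_label(reference)} "
            f"({ref_idx.size} atoms), target={_selection_label(target)} "
            f"({tgt_idx.size} atoms)"
        )

    n_bins = int(np.ceil(r_cut / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    shared = np.intersect1d(ref_idx, tgt_idx)
    for snap in traj:
        pos = snap.positions
        d = min_image_distance(pos[ref_idx][:, None, :], pos[tgt_idx][None, :, :], box)
        if shared.size:  # drop self-pairs when selections overlap
            mask = ref_idx[:, None] == tgt_idx[None, :]
            d = np.where(mask, np.inf, d)
        h, _ = np.histogram(d[d < r_cut], bins=edges)
        counts += h

    volume = box**3
    rho = tgt_idx.size / volume
    shell_vol = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = ref_idx.size * len(traj) * rho * shell_vol
    g = counts / norm
    centers = 0.5 * (edges[1:] + edges[:-1])

    profile = RDFProfile(
        bin_centers=centers,
        g=g,
        r_max=np.nan,
        r_min1=np.nan,
        n_wat=0.0,
        reference_selection=_selection_label(reference),
        target_selection=_selection_label(target),
        solvent_density=rho,
        bin_width=bin_width,
        raw_counts=counts,
        n_frames=len(traj),
        n_reference=int(ref_idx.size),
        shell_defined=False,
    )
    r_max, n_wat = first_shell(profile)
    return profile


def first_shell(profile: RDFProfile) -> tuple[float, float]:
    """First-shell radius ``r_max`` and coordination number ``n_wat``.

    After 3-bin moving-average smoothing, ``r_max`` is the center of the
    first strict local maximum with g > 1 and ``r_min1`` the first strict
    local minimum after it; ``n_wat`` integrates
    ``4 pi rho g(r) r^2 dr`` over bins up to ``r_min1``.  When no qualifying
    peak exists the profile is flagged undefined (``shell_defined=False``,
    NaN radii) rather than given fabricated values.  Results are written
    back onto ``profile`` and also returned.
    """
    g = np.asarray(profile.g, dtype=float)
    if g.size < 5:
        raise ValidationError("first_shell needs a profile with at least 5 bins")
    smooth = np.convolve(g, np.ones(3) / 3.0, mode="same")
    centers = profile.bin_centers

    peak = None
    for i in range(1, g.size - 1):
        if smooth[i] > smooth[i - 1] and smooth[i] > smooth[i + 1] and smooth[i] > 1.0:
            peak = i
            break
    if peak is None:
        profile.r_max = np.nan
        profile.r_min1 = np.nan
        profile.n_wat = 0.0
        profile.shell_defined = False
        return (np.nan, 0.0)

    trough = None
    for i in range(peak + 1, g.size - 1):
        if smooth[i] < smooth[i - 1] and smooth[i] < smooth[i + 1]:
            trough = i
            break
    if trough is None:
        trough = g.size - 1  # integrate to the end of the profile

    rho = profile.solvent_density
    dr = profile.bin_width
    upto = slice(0, trough + 1)
    n_wat = float(
        4.0 * np.pi * rho * np.sum(g[upto] * centers[upto] ** 2 * dr)
    )
    profile.r_max = float(centers[peak])
    profile.r_min1 = float(centers[trough])
    profile.n_wat = n_wat
    profile.shell_defined = True
    return (profile.r_max, n_wat)


@dataclass
class IonDistanceBins:
    """Frames partitioned by solute-COM-to-counterion distance, with per-bin
    mean gaps.  ``edges=[10, 20]`` reproduces the r < 10, 10 <= r <= 20,
    r > 20 Angstrom grouping; empty bins carry count 0 and a NaN mean."""

    edges: np.ndarray
    counts: np.ndarray
    mean_gap: np.ndarray
    sd_gap: np.ndarray
    distances: np.ndarray


def ion_distance_bins(
    traj: Trajectory,
    gaps: GapEnsemble,
    edges: tuple[float, ...] = (10.0, 20.0),
) -> IonDistanceBins:
    """Group frames by solute--counterion distance and average gaps per group.

    The distance is the minimum-image separation between the solute center of
    mass and the single counterion; frames fall into the len(edges)+1 bins
    delimited by ``edges``.
    """
    if len(traj) != gaps.n:
        raise ValidationError(
            f"one gap per frame required: {len(traj)} frames vs {gaps.n} gaps"
        )
    box = traj.box_edge
    dists = np.empty(len(traj))
    for i, snap in enumerate(traj):
        ion_idx = snap.indices(role="counterion")
        if ion_idx.size != 1:
            raise ValidationError(
                f"ion_distance_bins: frame {snap.frame_index} has "
                f"{ion_idx.size} counterions (exactly one required)"
            )
        dists[i] = min_image_distance(
            snap.solute_com(), snap.positions[ion_idx[0]], box
        )

    edges_arr = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges_arr) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    # boundary convention: r < e1 | e1 <= r <= e2 | r > e2, i.e. edges after
    # the first are inclusive on the left-hand bin
    which = np.searchsorted(edges_arr, dists, side="right")
    for k in range(1, edges_arr.size):
        which[dists == edges_arr[k]] = k
    n_bins = edges_arr.size + 1
    counts = np.zeros(n_bins, dtype=int)
    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b] > 0:
            means[b] = float(np.mean(gaps.gaps[mask]))
            if counts[b] > 1:
                sds[b] = float(np.std(gaps.gaps[mask], ddof=1))
    return IonDistanceBins(
        edges=edges_arr, counts=counts, mean_gap=means, sd_gap=sds, distances=dists
    )
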