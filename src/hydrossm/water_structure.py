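"""Tetrahedral order parameter and geometric hydrogen bonds of shell water.

The orientational (Errington-Debenedetti) tetrahedral order parameter of
a water molecule is computed from the six angles psi_jk subtended at its
oxygen by its four nearest oxygen neighbours:

    q_tet = 1 - 3/8 * sum_{j<k} (cos psi_jk + 1/3)^2.

It equals 1 for a perfect tetrahedron (every cos psi = -1/3), -3 for four
collinear neighbours, and averages 0 for i.i.d. uniform neighbour
directions.  Shell statistics take the *central* molecules from one
hydration shell but select neighbours among **all** solvent oxygens in
the frame, because molecules at the outer surface of a shell hydrogen-
bond into the next shell.

Hydrogen bonds use the standard geometric criterion (donor-acceptor
O-O distance <= 0.35 nm and H-O...O angle <= 30 degrees by default);
donor and acceptor roles both count towards a molecule's tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .proximal_rdf import ShellBoundaries
from .ssm_core import AxisSpec, _radial_distances, block_slices
from .trajectory_io import (
    SOLVENT_OTHER,
    SOLVENT_OXYGEN,
    Frame,
    Trajectory,
    minimum_image,
)

__all__ = [
    "HBondCriterion",
    "qtet_per_molecule",
    "qtet_frame",
    "shell_qtet",
    "hbond_count",
]

#: Sites closer to their oxygen than this are treated as virtual (M) sites,
#: not hydrogens, when grouping water molecules.
_VIRTUAL_SITE_CUTOFF = 0.05  # nm


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition (distance in nm, angle in degrees)."""

    d_oo_max: float = 0.35
    angle_max_deg: float = 30.0

    def __post_init__(self):
        if self.d_oo_max <= 0 or not (0 < self.angle_max_deg < 180):
            raise ValueError("invalid hydrogen-bond criterion")


def _qtet_from_vectors(vecs: np.ndarray) -> float:
    """q_tet from the four neighbour displacement vectors (4, 3)."""
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    total = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            total += (float(np.dot(units[j], units[k])) + 1.0 / 3.0) ** 2
    return 1.0 - 0.375 * total


def qtet_per_molecule(frame: Frame, central: int, candidates) -> float:
    """Tetrahedral order parameter of one molecule.

    ``central`` indexes the central oxygen in ``frame.positions``;
    ``candidates`` are the indices eligible as neighbours.  The four
    nearest by minimum-image distance are used.  Fewer than four distinct
    candidates is an error.
    """
    candidates = np.asarray(candidates, dtype=int)
    candidates = candidates[candidates != central]
    if len(candidates) < 4:
        raise ValueError(f"need >= 4 neighbour candidates, got {len(candidates)}")
    delta = minimum_image(
        frame.positions[candidates] - frame.positions[central][None, :],
        frame.box_lengths,
    )
    d2 = np.einsum("ij,ij->i", delta, delta)
    nearest = np.argpartition(d2, 3)[:4]
    return _qtet_from_vectors(delta[nearest])


def qtet_frame(frame: Frame, centrals, candidates) -> np.ndarray:
    """Vector of q_tet values for several central oxygens in one frame."""
    return np.array([qtet_per_molecule(frame, c, candidates) for c in np.asarray(centrals)])


def _shell_central_mask(frame: Frame, boundaries: ShellBoundaries, axis: AxisSpec, shell_id: int):
    """Oxygen indices, plus the subset radially inside the requested shell."""
    oxy = np.nonzero(frame.labels == SOLVENT_OXYGEN)[0]
    r = _radial_distances(frame, axis, frame.positions[oxy])
    lo, hi = boundaries.shell_interval(shell_id)
    return oxy, oxy[(r >= lo) & (r < hi)]


def shell_qtet(
    traj: Trajectory,
    boundaries: ShellBoundaries,
    axis: AxisSpec,
    shell_id: int = 1,
    n_blocks: int = 4,
) -> tuple[float, float]:
    """Block-averaged mean q_tet of the molecules in one hydration shell.

    Central molecules are the oxygens whose radial distance to the axis
    lies inside the shell; neighbour candidates are all solvent oxygens
    in the frame (first-shell surface molecules keep their second-shell
    neighbours).  Frames with an empty shell contribute nothing; a shell
    empty in every frame is an error.  Returns ``(mean, se)``.
    """
    sums, counts = [], []
    for frame in traj:
        oxy, centrals = _shell_central_mask(frame, boundaries, axis, shell_id)
        if len(centrals) == 0:
            sums.append(0.0)
            counts.append(0)
            continue
        q = qtet_frame(frame, centrals, oxy)
        sums.append(float(q.sum()))
        counts.append(len(q))
    if not sums:
        raise ValueError("trajectory is empty")
    sums = np.asarray(sums)
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError(f"shell {shell_id} is empty in every frame")
    block_means = []
    for sl in block_slices(len(sums), n_blocks):
        c = counts[sl].sum()
        if c > 0:
            block_means.append(sums[sl].sum() / c)
    block_means = np.asarray(block_means)
    if len(block_means) < 2:
        return float(block_means.mean()), float("nan")
    return (
        float(block_means.mean()),
        float(np.std(block_means, ddof=1) / np.sqrt(len(block_means))),
    )


def _water_molecules(frame: Frame):
    """Group water sites into (oxygen index, hydrogen indices) tuples.

    Assumes GROMACS-style site ordering: each solvent oxygen is followed
    by its hydrogen / virtual sites.  Sites within 0.05 nm of their
    oxygen are treated as virtual (M) sites and skipped.
    """
    molecules = []
    current_o = None
    hydrogens: list[int] = []
    for i, label in enumerate(frame.labels):
        if label == SOLVENT_OXYGEN:
            if current_o is not None:
                molecules.append((current_o, hydrogens))
            current_o = i
            hydrogens = []
        elif label == SOLVENT_OTHER and current_o is not None:
            d = minimum_image(
                frame.positions[i] - frame.positions[current_o], frame.box_lengths
            )
            if np.linalg.norm(d) > _VIRTUAL_SITE_CUTOFF:
                hydrogens.append(i)
    if current_o is not None:
        molecules.append((current_o, hydrogens))
    return molecules


def _hbond_counts_frame(
    frame: Frame, molecules, criterion: HBondCriterion
) -> np.ndarray:
    """Per-molecule hydrogen-bond tallies (donor + acceptor roles)."""
    o_idx = np.array([m[0] for m in molecules])
    o_pos = frame.positions[o_idx]
    n = len(molecules)
    counts = np.zeros(n, dtype=int)
    cos_max = np.cos(np.deg2rad(criterion.angle_max_deg))
    for a in range(n):
        delta = minimum_image(o_pos - o_pos[a][None, :], frame.box_lengths)
        d = np.linalg.norm(delta, axis=1)
        for b in np.nonzero((d <= criterion.d_oo_max) & (d > 1e-9))[0]:
            if b <= a:
                continue
            # donor a -> acceptor b, then donor b -> acceptor a
            for donor, acceptor, o_to_o in ((a, b, delta[b]), (b, a, -delta[b])):
                bonded = False
                for h in molecules[donor][1]:
                    oh = minimum_image(
                        frame.positions[h] - o_pos[donor], frame.box_lengths
                    )
                    cos_angle = float(
                        np.dot(oh, o_to_o) / (np.linalg.norm(oh) * np.linalg.norm(o_to_o))
                    )
                    if cos_angle >= cos_max:
                        bonded = True
                        break
                if bonded:
                    counts[donor] += 1
                    counts[acceptor] += 1
    return counts


def hbond_count(
    traj: Trajectory,
    boundaries: ShellBoundaries,
    axis: AxisSpec,
    shell_id: int = 1,
    criterion: HBondCriterion = HBondCriterion(),
    n_blocks: int = 4,
) -> tuple[float, float]:
    """Block-averaged hydrogen bonds per molecule in one hydration shell.

    A pair is bonded when the O-O distance and the H-O...O angle (at the
    donor oxygen, between the O-H bond and the O->O vector) satisfy the
    criterion; each bond increments both partners' tallies.  Only
    molecules whose oxygen lies radially inside the shell contribute to
    the per-molecule average, but partners may sit anywhere.  Requires
    hydrogen positions (a trajectory of bare oxygens is an error).
    """
    sums, counts = [], []
    saw_hydrogens = False
    for frame in traj:
        molecules = _water_molecules(frame)
        if any(m[1] for m in molecules):
            saw_hydrogens = True
        else:
            sums.append(0.0)
            counts.append(0)
            continue
        per_mol = _hbond_counts_frame(frame, molecules, criterion)
        o_idx = np.array([m[0] for m in molecules])
        r = _radial_distances(frame, axis, frame.positions[o_idx])
        lo, hi = boundaries.shell_interval(shell_id)
        in_shell = (r >= lo) & (r < hi)
        sums.append(float(per_mol[in_shell].sum()))
        counts.append(int(in_shell.sum()))
    if not sums:
        raise ValueError("trajectory is empty")
    if not saw_hydrogens:
        raise ValueError(
            "no hydrogen positions found: hydrogen-bond analysis needs a "
            "three-site water trajectory (oxygen-only data supports q_tet and "
            "fluctuation analyses, not hydrogen bonds)"
        )
    sums = np.asarray(sums)
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError(f"shell {shell_id} is empty in every frame")
    block_means = []
    for sl in block_slices(len(sums), n_blocks):
        c = counts[sl].sum()
        if c > 0:
            block_means.append(sums[sl].sum() / c)
    block_means = np.asarray(block_means)
    if len(block_means) < 2:
        return float(block_means.mean()), float("nan")
    return (
        float(block_means.mean()),
        float(np.std(block_means, ddof=1) / np.sqrt(len(block_means))),
    )
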