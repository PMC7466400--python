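"""Tetrahedral order parameter and geometric hydrogen bonds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrossm.proximal_rdf import ShellBoundaries
from hydrossm.ssm_core import AxisSpec
from hydrossm.synthetic_data import (
    generate_neighbor_geometry,
    rigid_water_frame,
)
from hydrossm.trajectory_io import SOLVENT_OXYGEN, Frame, Trajectory
from hydrossm.water_structure import (
    HBondCriterion,
    _qtet_from_vectors,
    hbond_count,
    qtet_per_molecule,
    shell_qtet,
)

BIG_BOX = (50.0, 50.0, 50.0)  # effectively no periodic images


def _geometry_frame(center, neighbors):
    pos = np.vstack([center[None, :], neighbors]) + 10.0  # away from box walls
    return Frame(BIG_BOX, pos, np.full(5, SOLVENT_OXYGEN))


class TestQtetPerMolecule:
    def test_perfect_tetrahedron_is_one(self):
        center, nbrs = generate_neighbor_geometry("perfect-tetrahedron", 1, seed=0)[0]
        frame = _geometry_frame(center, nbrs)
        assert qtet_per_molecule(frame, 0, range(5)) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_is_minus_three(self):
        center, nbrs = generate_neighbor_geometry("collinear", 1, seed=1)[0]
        frame = _geometry_frame(center, nbrs)
        assert qtet_per_molecule(frame, 0, range(5)) == pytest.approx(-3.0, abs=1e-10)

    def test_uniform_random_mean_is_zero(self):
        q = []
        for center, nbrs in generate_neighbor_geometry("uniform-random", 4000, seed=2):
            q.append(qtet_per_molecule(_geometry_frame(center, nbrs), 0, range(5)))
        q = np.asarray(q)
        assert abs(q.mean()) < 3 * q.std(ddof=1) / np.sqrt(len(q))

    def test_uses_four_nearest_neighbors_only(self):
        center, nbrs = generate_neighbor_geometry("perfect-tetrahedron", 1, seed=3)[0]
        # a fifth, far candidate must not displace the tetrahedral four
        far = center + np.array([1.5, 0.0, 0.0])
        pos = np.vstack([center, nbrs, far]) + 10.0
        frame = Frame(BIG_BOX, pos, np.full(6, SOLVENT_OXYGEN))
        assert qtet_per_molecule(frame, 0, range(6)) == pytest.approx(1.0, abs=1e-10)

    def test_too_few_candidates_is_error(self):
        frame = Frame(BIG_BOX, np.full((4, 3), 10.0) + np.eye(4, 3), np.full(4, SOLVENT_OXYGEN))
        with pytest.raises(ValueError, match=">= 4"):
            qtet_per_molecule(frame, 0, range(4))  # central excluded -> only 3


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(0, 2**31 - 1))
def test_qtet_bounds_and_rigid_motion_invariance(seed):
    """-3 <= qtet <= 1, and qtet is invariant under rotation + translation."""
    rng = np.random.default_rng(seed)
    vecs = rng.uniform(-0.4, 0.4, size=(4, 3))
    if np.any(np.linalg.norm(vecs, axis=1) < 1e-3):
        vecs += 0.5
    q = _qtet_from_vectors(vecs)
    assert -3.0 - 1e-9 <= q <= 1.0 + 1e-9
    # random proper rotation via QR
    m = rng.standard_normal((3, 3))
    rot, r = np.linalg.qr(m)
    rot *= np.sign(np.diag(r))
    if np.linalg.det(rot) < 0:
        rot[:, 0] = -rot[:, 0]
    assert _qtet_from_vectors(vecs @ rot.T) == pytest.approx(q, abs=1e-9)


class TestShellQtet:
    @staticmethod
    def _uniform_traj(n_frames=8, n=350, box=4.0, seed=5):
        rng = np.random.default_rng(seed)
        frames = [
            Frame((box, box, box), rng.random((n, 3)) * box, np.full(n, SOLVENT_OXYGEN))
            for _ in range(n_frames)
        ]
        return Trajectory(frames)

    def test_homogeneous_fixture_matches_bulk_and_shell_choice(self):
        """For uniform solvent, shell qtet is shell-independent within SE."""
        traj = self._uniform_traj()
        axis = AxisSpec(2.0, 2.0)
        bounds = ShellBoundaries(r1=0.2, boundaries=(0.8, 1.4))
        m1, s1 = shell_qtet(traj, bounds, axis, shell_id=1)
        m2, s2 = shell_qtet(traj, bounds, axis, shell_id=2)
        assert abs(m1 - m2) < 3 * np.hypot(s1, s2)

    def test_candidate_inclusion_rule_matters_across_boundary(self):
        """Restricting neighbours to the shell (the wrong mode) changes qtet.

        Construction: a central oxygen just inside the shell boundary with
        its perfect tetrahedron partly outside the shell, plus four far
        decoy oxygens inside the shell.
        """
        axis = AxisSpec(25.0, 25.0)
        base = np.array([25.55, 25.0, 25.0])  # central at radial distance 0.55
        # un-rotated perfect tetrahedron at 0.3 nm: neighbour radial
        # distances are hypot(0.55 +/- 0.173, 0.173) = 0.743 or 0.415,
        # i.e. all OUTSIDE the narrow shell [0.5, 0.6)
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
        nbrs = base[None, :] + 0.3 * dirs
        # decoys: 2 near the axis (not centrals, farther than true nbrs),
        # 2 at radial 0.7 but 1 nm away along z
        decoys = np.array(
            [
                [25.30, 25.0, 25.4],
                [25.30, 25.0, 24.6],
                [25.70, 25.0, 26.0],
                [25.70, 25.0, 24.0],
            ]
        )
        pos = np.vstack([base, nbrs, decoys])
        frame = Frame(BIG_BOX, pos, np.full(len(pos), SOLVENT_OXYGEN))
        bounds = ShellBoundaries(r1=0.5, boundaries=(0.6,))
        traj = Trajectory([frame, frame])
        # the shell holds only the central; with unrestricted candidates its
        # four nearest are the true tetrahedral neighbours
        full, _ = shell_qtet(traj, bounds, axis, shell_id=1, n_blocks=2)
        assert full == pytest.approx(1.0, abs=1e-9)
        # wrong mode: restrict candidates to a radial band [0.5, 0.8) that
        # cuts away half the tetrahedron and pulls in the far decoys
        r = np.hypot(pos[:, 0] - 25.0, pos[:, 1] - 25.0)
        band = np.nonzero((r >= 0.5) & (r < 0.8))[0]
        wrong = qtet_per_molecule(frame, 0, band)
        assert abs(wrong - full) > 0.1

    def test_all_empty_shell_is_error(self):
        traj = self._uniform_traj(n_frames=4, n=30)
        bounds = ShellBoundaries(r1=0.001, boundaries=(0.002,))
        with pytest.raises(ValueError, match="empty"):
            shell_qtet(traj, bounds, AxisSpec(2.0, 2.0), shell_id=1, n_blocks=2)


class TestHbond:
    @staticmethod
    def _pair_frame(d_oo=0.28, tilt_deg=0.0):
        """Donor pointing an OH at the acceptor, O-O distance d_oo."""
        tilt = np.deg2rad(tilt_deg)
        half = np.deg2rad(104.52) / 2
        # bisector chosen so one OH lies at `tilt` from the O->O axis (x)
        c, s = np.cos(tilt - half), np.sin(tilt - half)
        return rigid_water_frame(
            [(5.0, 5.0, 5.0), (5.0 + d_oo, 5.0, 5.0)],
            [(c, s, 0.0), (1.0, 0.3, 0.0)],  # acceptor pointing away
            [(-s, c, 0.0), (0.0, 1.0, 0.0)],
            (10.0, 10.0, 10.0),
        )

    _axis = AxisSpec(5.0, 5.0)
    _bounds = ShellBoundaries(r1=0.0, boundaries=(2.0,))

    def test_ideal_geometry_is_bonded(self):
        traj = Trajectory([self._pair_frame(0.28, 0.0)] * 2)
        mean, _ = hbond_count(traj, self._bounds, self._axis, 1, n_blocks=2)
        assert mean >= 1.0  # both partners tally the shared bond

    def test_distance_cutoff(self):
        traj = Trajectory([self._pair_frame(0.5, 0.0)] * 2)
        mean, _ = hbond_count(traj, self._bounds, self._axis, 1, n_blocks=2)
        assert mean == 0.0

    def test_angle_sweep_drops_to_zero_past_threshold(self):
        means = []
        for tilt in (0.0, 15.0, 29.0, 31.0, 60.0):
            traj = Trajectory([self._pair_frame(0.28, tilt)] * 2)
            mean, _ = hbond_count(traj, self._bounds, self._axis, 1, n_blocks=2)
            means.append(mean)
        assert means[0] >= 1.0 and means[1] >= 1.0 and means[2] >= 1.0
        assert means[3] == 0.0 and means[4] == 0.0

    def test_oxygen_only_trajectory_is_error(self):
        rng = np.random.default_rng(0)
        frame = Frame(
            (4.0, 4.0, 4.0), rng.random((20, 3)) * 4.0, np.full(20, SOLVENT_OXYGEN)
        )
        with pytest.raises(ValueError, match="hydrogen"):
            hbond_count(Trajectory([frame, frame]), self._bounds, AxisSpec(2, 2), 1, n_blocks=2)

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            HBondCriterion(d_oo_max=-0.1)
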