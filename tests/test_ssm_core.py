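"""Fluctuation sampling, scaling fits and the compressibility conversion."""

import numpy as np
import pytest

from hydrossm.ssm_core import (
    KB_BAR_NM3,
    AxisSpec,
    CylinderShell,
    FluctuationProfile,
    SubvolumeSpec,
    block_average,
    block_slices,
    compressibility,
    count_particles,
    default_L_grid,
    extrapolate_radius,
    fit_scaling,
    sample_profile,
)
from hydrossm.synthetic_data import IdealGasSpec, generate_ideal_gas
from hydrossm.trajectory_io import SOLVENT_OXYGEN, Frame, Trajectory


def brute_force_count(frame, axis, sub):
    """Independent O(N) recount with explicit minimum image and z wrap."""
    n = 0
    lx, ly, lz = frame.box_lengths
    for x, y, z in frame.positions:
        dx = x - axis.x0 - lx * round((x - axis.x0) / lx)
        dy = y - axis.y0 - ly * round((y - axis.y0) / ly)
        r = np.hypot(dx, dy)
        dz = (z - sub.z0) % lz
        if sub.geometry.r_in <= r < sub.geometry.r_out and dz < sub.L:
            n += 1
    return n


class TestCountParticles:
    def test_matches_brute_force_on_random_subvolumes(self, rng):
        box = np.array([4.0, 5.0, 6.0])
        frame = Frame(box, rng.random((300, 3)) * box, np.full(300, SOLVENT_OXYGEN))
        for _ in range(100):
            axis = AxisSpec(rng.uniform(0, 4), rng.uniform(0, 5))
            r_in = rng.uniform(0, 1.0) * rng.integers(0, 2)  # half solid cylinders
            r_out = r_in + rng.uniform(0.1, 2.0 - r_in)
            sub = SubvolumeSpec.shell(r_in, r_out, rng.uniform(0.1, 6.0), rng.uniform(0, 6.0))
            assert count_particles(frame, axis, sub) == brute_force_count(frame, axis, sub)

    def test_point_on_axis_is_counted(self):
        frame = Frame(
            (4.0, 4.0, 4.0), [[2.0, 2.0, 1.0]], np.array([SOLVENT_OXYGEN])
        )
        sub = SubvolumeSpec.cylinder(0.5, L=4.0)
        assert count_particles(frame, AxisSpec(2.0, 2.0), sub) == 1

    def test_full_height_counts_all_in_shell(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        frame = Frame(box, rng.random((200, 3)) * box, np.full(200, SOLVENT_OXYGEN))
        axis = AxisSpec(2.0, 2.0)
        counts = {
            count_particles(frame, axis, SubvolumeSpec.cylinder(1.0, L=4.0, z0=z0))
            for z0 in (0.0, 0.7, 3.3)
        }
        assert len(counts) == 1  # z0-independent at L = lz

    def test_oversized_radius_rejected(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        frame = Frame(box, rng.random((10, 3)) * box, np.full(10, SOLVENT_OXYGEN))
        with pytest.raises(ValueError, match="half the smaller box side"):
            count_particles(frame, AxisSpec(2, 2), SubvolumeSpec.cylinder(2.5, 1.0))


class TestSampleProfile:
    def test_ideal_gas_matches_binomial_depletion(self, small_gas, small_gas_spec):
        """1/Gamma(L) tracks the closed-form binomial oracle on the grid.

        The oracle accounts for the exact expectation of the pooled
        estimator: subtracting the block grand mean removes the
        between-frame variance of the frame-averaged count, which for a
        binomial in-shell count n_in ~ B(N, p_s) equals
        (L/lz)^2 var(n_in) / F_block (windows of length L cover each
        particle L/z_step times out of lz/z_step placements).
        """
        rc, lz = 0.7, 4.0
        profile = sample_profile(
            small_gas, AxisSpec(2.0, 2.0), CylinderShell.cylinder(rc),
            L_grid=default_L_grid(lz, L_max=2.4),
        )
        n_b = small_gas_spec.n_particles
        v_b = small_gas_spec.volume
        v = np.pi * rc**2 * profile.L
        p_shell = np.pi * rc**2 / 16.0  # in-shell probability (4x4 cross-section)
        var_n_in = n_b * p_shell * (1 - p_shell)
        mu = n_b * v / v_b
        frames_per_block = len(small_gas) // profile.n_blocks
        pooling_bias = (profile.L / lz) ** 2 * var_n_in / (frames_per_block * mu)
        expected = 1.0 - v / v_b - pooling_bias
        t = np.abs(profile.inv_gamma - expected) / profile.se
        assert np.max(t) < 3.0

    def test_identical_frames_have_zero_variance_at_full_height(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        frame = Frame(box, rng.random((150, 3)) * box, np.full(150, SOLVENT_OXYGEN))
        traj = Trajectory([frame] * 8)
        profile = sample_profile(
            traj, AxisSpec(2.0, 2.0), CylinderShell.cylinder(1.0), L_grid=[1.0, 2.0, 4.0]
        )
        assert profile.inv_gamma[-1] == pytest.approx(0.0, abs=1e-12)

    def test_z_translation_improves_statistics(self, small_gas):
        axis, geom = AxisSpec(2.0, 2.0), CylinderShell.cylinder(0.7)
        grid = [0.5, 1.0, 1.5, 2.0]
        pooled = sample_profile(small_gas, axis, geom, L_grid=grid, z_step=0.1)
        single = sample_profile(small_gas, axis, geom, L_grid=grid, z_step=4.0)
        # same expectation ...
        assert np.allclose(pooled.inv_gamma, single.inv_gamma, atol=3 * (pooled.se + single.se))
        # ... but translation pools ~40x more samples, shrinking the SE
        assert pooled.se.mean() < single.se.mean()

    def test_empty_trajectory_is_error(self):
        traj = Trajectory(factory=lambda: iter(()))
        with pytest.raises(ValueError, match="empty"):
            sample_profile(traj, AxisSpec(2, 2), CylinderShell.cylinder(0.5))

    def test_empty_subvolume_recorded_as_missing(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        # all particles far from the axis: inner cylinder is always empty
        pos = rng.random((50, 3)) * box
        pos[:, 0] = 3.9
        pos[:, 1] = 3.9
        traj = Trajectory(
            [Frame(box, pos, np.full(50, SOLVENT_OXYGEN)) for _ in range(4)]
        )
        with pytest.warns(RuntimeWarning, match="undefined"):
            profile = sample_profile(
                traj, AxisSpec(1.0, 1.0), CylinderShell.cylinder(0.3), L_grid=[1.0, 2.0]
            )
        assert np.all(np.isnan(profile.inv_gamma))


from helpers_scaling import exact_line_profile as _exact_line_profile  # noqa: E402


class TestFitScaling:
    def test_exact_line_recovered_to_machine_precision(self):
        profile = _exact_line_profile(0.06, 0.04)
        fit = fit_scaling(profile, (1.0, 2.0))
        assert fit.intercept == pytest.approx(0.06, abs=1e-12)
        assert fit.slope == pytest.approx(0.04, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_line_intercept_is_unbiased(self):
        rng = np.random.default_rng(99)
        intercepts = [
            fit_scaling(
                _exact_line_profile(0.06, 0.04, noise=1e-3, rng=rng), (0.05, 2.6)
            ).intercept
            for _ in range(50)
        ]
        assert abs(np.mean(intercepts) - 0.06) < 1e-4

    def test_window_reordering_invariance(self):
        profile = _exact_line_profile(0.06, 0.04)
        # feeding a reordered grid is rejected by the profile invariant ...
        with pytest.raises(ValueError, match="increasing"):
            _exact_line_profile(0.06, 0.04, L=[2.0, 1.0, 1.5])
        # ... and the fit depends only on which points fall in the window
        a = fit_scaling(profile, (1.0, 2.0))
        b = fit_scaling(profile, (0.999, 2.001))
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_too_few_points_rejected(self):
        profile = _exact_line_profile(0.06, 0.04, L=[1.0, 1.5, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            fit_scaling(profile, (1.2, 1.6))


class TestExtrapolateRadius:
    def test_exact_line_in_inverse_radius(self):
        rcs = np.array([0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 2.0])
        intercepts = 0.062 + 0.03 / rcs
        fit = extrapolate_radius(list(zip(rcs, intercepts)), rc_max=1.5)
        assert fit.intercept == pytest.approx(0.062, abs=1e-12)
        assert fit.n_points == 6  # rc = 2.0 is outside the linear window

    def test_radius_independent_intercepts_give_flat_line(self):
        rcs = [0.4, 0.8, 1.2]
        fit = extrapolate_radius([(rc, 1.0) for rc in rcs], rc_max=1.5)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_single_radius_is_error(self):
        with pytest.raises(ValueError, match=">= 3 radii"):
            extrapolate_radius([(0.5, 1.0)], rc_max=1.5)


class TestCompressibility:
    def test_ideal_gas_identity(self):
        res = compressibility(1.0, rho=33.3, T=300.0)
        assert res.chi == pytest.approx(1.0 / (33.3 * KB_BAR_NM3 * 300.0), rel=1e-12)
        assert res.chi == pytest.approx(7.25e-4, rel=2e-3)
        assert res.chi == res.chi_ideal

    def test_incompressible_limit_and_temperature_scaling(self):
        assert compressibility(0.0, 33.0, 300.0).chi == 0.0
        chi1 = compressibility(0.5, 33.0, 300.0).chi
        chi2 = compressibility(0.5, 33.0, 600.0).chi
        assert chi2 == pytest.approx(chi1 / 2.0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compressibility(1.0, -1.0, 300.0)
        with pytest.raises(ValueError):
            compressibility(1.0, 33.0, 0.0)


class TestBlockAverage:
    def test_identical_blocks_have_zero_se(self):
        mean, se = block_average([2.0] * 8, n_blocks=4)
        assert (mean, se) == (2.0, 0.0)

    def test_four_value_arithmetic(self):
        mean, se = block_average([1.0, 2.0, 3.0, 4.0], n_blocks=4)
        assert mean == pytest.approx(2.5)
        assert se == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2.0)

    def test_remainder_goes_to_last_block(self):
        slices = block_slices(10, 4)
        assert [s.stop - s.start for s in slices] == [2, 2, 2, 4]

    def test_fewer_samples_than_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0], n_blocks=4)

    def test_ideal_gas_se_magnitude(self, small_gas, small_gas_spec):
        """Block SE of 1/Gamma is the right order for binomial sampling."""
        profile = sample_profile(
            small_gas, AxisSpec(2.0, 2.0), CylinderShell.cylinder(0.7), L_grid=[1.0]
        )
        n_eff = len(small_gas)  # frames are the independent unit
        rough = np.sqrt(2.0 / n_eff)  # relative fluctuation of a variance estimate
        assert 0.05 * rough < profile.se[0] < 5 * rough
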