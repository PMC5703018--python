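"""Torus attractor: kernel, dynamics, projection decoding and tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canmap import grid
from canmap.config import GridConfig
from canmap.errors import DivergenceError, UndecodableStateError, VelocityRangeError


def triad_pattern(cfg, axes, t0x, t0y, width=0.5):
    """Analytic k^2-bump pattern centred at (t0x, t0y), uniform over nu.

    Gaussian bumps on the staggered lattice of the hexagonal triad:
    (0,0), (pi,0), (pi/2,pi), (3*pi/2,pi) relative to the centre (for k=2).
    """
    th = grid.theta_coords(cfg)
    offsets = [(0.0, 0.0), (np.pi, 0.0), (np.pi / 2, np.pi), (3 * np.pi / 2, np.pi)]
    pat = np.zeros((cfg.n_theta, cfg.n_theta))
    for ox, oy in offsets:
        dx = np.angle(np.exp(1j * (th[:, None] - t0x - ox)))
        dy = np.angle(np.exp(1j * (th[None, :] - t0y - oy)))
        pat += np.exp(-(dx**2 + dy**2) / (2 * width**2))
    return np.broadcast_to(
        pat[:, :, None, None], (cfg.n_theta, cfg.n_theta, cfg.n_nu, cfg.n_nu)
    ).copy()


def circ_err(a, b, k):
    """Distance between two phases on the period 2*pi/k."""
    return abs(np.angle(np.exp(1j * k * (a - b)))) / k


class TestKernel:
    def test_fully_aligned_offset_weight(self, grid_cfg, grid_kernel):
        z = np.zeros(2)
        assert grid_kernel.evaluate(z, z, z, z) == pytest.approx(-10.0)  # J0 + Jk

    def test_half_torus_offset_is_second_bump(self, grid_cfg, grid_kernel):
        # cos(k * pi) = 1 for k = 2: a second bump per axis
        z = np.zeros(2)
        got = grid_kernel.evaluate(np.array([np.pi, 0.0]), z, z, z)
        assert got == pytest.approx(grid_cfg.J0 + grid_cfg.Jk)

    def test_quarter_period_velocity_offset_cancels_interaction(self, grid_cfg, grid_kernel):
        dv = np.pi / (2.0 * grid_cfg.lambda_v)
        got = grid_kernel.evaluate(
            np.array([1.0, 2.0]), np.array([dv, 0.0]), np.zeros(2), np.zeros(2)
        )
        assert got == pytest.approx(grid_cfg.J0)

    def test_fft_drive_matches_dense_matrix(self, small_grid_cfg):
        kernel = grid.build_grid_weight_kernel(small_grid_cfg)
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, (
            small_grid_cfg.n_theta, small_grid_cfg.n_theta,
            small_grid_cfg.n_nu, small_grid_cfg.n_nu,
        ))
        dense = kernel.dense_matrix()
        ref = (dense @ (kernel.presyn_weights * m).reshape(-1)).reshape(m.shape)
        np.testing.assert_allclose(kernel.drive(m), ref, atol=1e-12)

    def test_fft_drive_matches_dense_matrix_medium_size(self):
        cfg = GridConfig(n_theta=10, n_nu=5)
        kernel = grid.build_grid_weight_kernel(cfg)
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, (cfg.n_theta, cfg.n_theta, cfg.n_nu, cfg.n_nu))
        dense = kernel.dense_matrix()
        ref = (dense @ (kernel.presyn_weights * m).reshape(-1)).reshape(m.shape)
        np.testing.assert_allclose(kernel.drive(m), ref, atol=1e-12)


class TestVelocityInput:
    def test_zero_velocity_peaks_at_center_with_full_amplitude(self, grid_cfg):
        field = grid.translational_velocity_input(np.zeros(2), grid_cfg)
        assert field.max() == pytest.approx(grid_cfg.I_t)
        c = grid_cfg.n_nu // 2
        assert field[0, 0, c, c] == field.max()

    def test_far_tail_approaches_untuned_floor(self, grid_cfg):
        field = grid.translational_velocity_input(np.zeros(2), grid_cfg)
        corner = field[0, 0, 0, 0]  # |nu| = 0.42, >> sigma_t
        assert corner == pytest.approx(grid_cfg.I_t * (1 - grid_cfg.epsilon), abs=0.05)

    def test_tuning_center_placement(self, grid_cfg):
        u = grid.velocity_to_nu(np.array([10.0, 0.0]), grid_cfg)
        # (1/2) * arctan(2*pi*0.01*10/30), evaluated independently
        assert u[0] == pytest.approx(0.0104703, abs=1e-6)
        assert u[1] == 0.0

    def test_unrepresentable_velocity_raises(self, grid_cfg):
        with pytest.raises(VelocityRangeError):
            grid.translational_velocity_input(np.array([1e4, 0.0]), grid_cfg)


class TestDynamics:
    def test_zero_state_zero_input_is_fixed(self, grid_cfg, grid_kernel):
        shape = (grid_cfg.n_theta, grid_cfg.n_theta, grid_cfg.n_nu, grid_cfg.n_nu)
        st = grid.GridState(np.zeros(shape))
        out = grid.grid_step(st, np.zeros(shape), 0.0, grid_cfg, grid_kernel)
        assert not out.rates.any()

    def test_constructed_fixed_point_is_invariant(self, small_grid_cfg):
        kernel = grid.build_grid_weight_kernel(small_grid_cfg)
        cfg = small_grid_cfg
        rng = np.random.default_rng(2)
        m_star = 1.0 + rng.uniform(0, 1, (cfg.n_theta, cfg.n_theta, cfg.n_nu, cfg.n_nu))
        ext = m_star - kernel.drive(m_star)
        out = grid.grid_step(grid.GridState(m_star), ext, 0.0, cfg, kernel)
        np.testing.assert_allclose(out.rates, m_star, atol=1e-12)

    def test_divergent_input_raises(self, grid_cfg, grid_kernel, grid_settled):
        bad = np.full(grid_settled.rates.shape, np.inf)
        with pytest.raises(DivergenceError):
            grid.grid_step(grid_settled, bad, 0.0, grid_cfg, grid_kernel)

    def test_settled_pattern_has_k_squared_peaks(self, grid_cfg, grid_settled):
        from conftest import wrap_components

        c = grid_cfg.n_nu // 2
        sl = grid_settled.rates[:, :, c, c]
        n = wrap_components(sl > 0.5 * sl.max())
        assert n == grid_cfg.k**2 == 4

    def test_settled_pattern_is_velocity_centered(self, grid_cfg, grid_settled, axes):
        dec = grid.decode_grid_phases(grid_settled, axes, grid_cfg)
        spacing = 2 * grid_cfg.L_t / (grid_cfg.n_nu - 1)
        assert abs(dec.phi_x) < spacing and abs(dec.phi_y) < spacing

    def test_torus_equivariance(self, grid_cfg, grid_kernel, grid_settled, axes):
        """Shifting the pattern by lattice steps shifts the decoded phases."""
        shift = 3
        dth = 2 * np.pi * shift / grid_cfg.n_theta
        ext = grid.translational_velocity_input(np.zeros(2), grid_cfg)
        a = grid.GridState(grid_settled.rates.copy())
        b = grid.GridState(np.roll(grid_settled.rates, shift, axis=0))
        for _ in range(100):
            a = grid.grid_step(a, ext, 0.0, grid_cfg, grid_kernel)
            b = grid.grid_step(b, ext, 0.0, grid_cfg, grid_kernel)
        da = grid.decode_grid_phases(a, axes, grid_cfg)
        db = grid.decode_grid_phases(b, axes, grid_cfg)
        assert circ_err(db.theta_x_hat, da.theta_x_hat + dth, grid_cfg.k) < 1e-9
        assert circ_err(db.theta_y_hat, da.theta_y_hat, grid_cfg.k) < 1e-9


class TestDecoding:
    def test_analytic_patterns_decode_to_their_center(self, grid_cfg, axes):
        """Recovery modulo the pattern's translation symmetry group.

        The staggered k^2-bump pattern is invariant under (pi/k, 2*pi/k) as
        well as the per-axis periods, so a single-frame decode pins the
        centre only up to that joint lattice (the tracker resolves the rest
        through continuity).
        """
        rng = np.random.default_rng(3)
        spacing = 2 * np.pi / grid_cfg.n_theta
        k = grid_cfg.k
        for _ in range(100):
            t0x, t0y = rng.uniform(0, 2 * np.pi, 2)
            st = grid.GridState(triad_pattern(grid_cfg, axes, t0x, t0y))
            dec = grid.decode_grid_phases(st, axes, grid_cfg)
            ok = False
            for sx in (0.0, np.pi / k):  # the staggered translation, mod 2*pi/k
                ok = ok or (
                    circ_err(dec.theta_x_hat, t0x + sx, k) <= spacing
                    and circ_err(dec.theta_y_hat, t0y, k) <= spacing
                )
            assert ok

    def test_third_axis_reconstruction_agrees(self, grid_cfg, axes):
        """theta_x rebuilt from (psi1, psi3) matches the (psi1, psi2) route."""
        rng = np.random.default_rng(4)
        spacing = 2 * np.pi / grid_cfg.n_theta
        for _ in range(100):
            t0x, t0y = rng.uniform(0, 2 * np.pi, 2)
            st = grid.GridState(triad_pattern(grid_cfg, axes, t0x, t0y))
            d = grid.decode_grid_phases(st, axes, grid_cfg)
            alt = (
                -d.psi3 * axes.l[2] / np.sin(axes.alpha)
                - d.psi1 * axes.l[0] / np.tan(axes.alpha)
            )
            assert circ_err(alt, d.theta_x_hat, grid_cfg.k) <= spacing

    def test_pattern_shifted_by_period_decodes_identically(self, grid_cfg, axes):
        a = grid.GridState(triad_pattern(grid_cfg, axes, 0.9, 2.1))
        b = grid.GridState(triad_pattern(grid_cfg, axes, 0.9 + 2 * np.pi / grid_cfg.k, 2.1))
        da = grid.decode_grid_phases(a, axes, grid_cfg)
        db = grid.decode_grid_phases(b, axes, grid_cfg)
        assert da.theta_x_hat == pytest.approx(db.theta_x_hat, abs=1e-9)
        assert da.theta_y_hat == pytest.approx(db.theta_y_hat, abs=1e-9)

    def test_uniform_activity_is_undecodable(self, grid_cfg, axes):
        shape = (grid_cfg.n_theta, grid_cfg.n_theta, grid_cfg.n_nu, grid_cfg.n_nu)
        with pytest.raises(UndecodableStateError):
            grid.decode_grid_phases(grid.GridState(np.ones(shape)), axes, grid_cfg)


class TestUnwrapAndPosition:
    def test_unwrap_examples(self):
        assert grid.unwrap_phase(0.10, 0.11, 2) == pytest.approx(0.11)
        P = np.pi  # period for k = 2
        assert grid.unwrap_phase(P - 0.05, 0.02, 2) == pytest.approx(P + 0.02)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1.5, 1.5), min_size=2, max_size=60),
           st.integers(1, 3))
    def test_unwrap_recovers_random_walks(self, steps, k):
        """Steps below half a period: unwrapped minus true is constant."""
        period = 2 * np.pi / k
        steps = [s for s in steps if abs(s) < 0.49 * period]
        true = np.cumsum([1.0] + steps)
        cum = true[0]
        for t in true[1:]:
            cum = grid.unwrap_phase(cum, t % period, k)
            assert cum == pytest.approx(t, abs=1e-9)

    def test_phases_to_position_scale(self, grid_cfg):
        tr = grid.PositionTracker(grid_cfg)
        tr.cum_psi1, tr.cum_psi2 = 0.0, 0.0
        assert tr.position == (0.0, 0.0)
        # one torus period along x equals the grid scale S
        tr.cum_psi2 = 2 * np.pi / grid_cfg.k  # theta_x advances by a period
        assert tr.position[0] == pytest.approx(grid_cfg.S)
        tr.cum_psi2 = np.pi / grid_cfg.k
        assert tr.position[0] == pytest.approx(grid_cfg.S / 2)

    def test_tracker_is_continuous_across_wrap_boundaries(self, grid_cfg, axes):
        """The staggered symmetry of the k-bump pattern must not produce
        quarter-period jumps when theta_y crosses its wrap boundary."""
        tr = grid.PositionTracker(grid_cfg)
        t0x, t0y = 1.0, 0.02
        tr.begin(grid.decode_grid_phases(
            grid.GridState(triad_pattern(grid_cfg, axes, t0x, t0y)), axes, grid_cfg))
        p_prev = np.array(tr.position)
        for dy in np.linspace(0.0, -0.08, 9)[1:]:  # drive theta_y through 0
            st = grid.GridState(triad_pattern(grid_cfg, axes, t0x, t0y + dy))
            tr.update(grid.decode_grid_phases(st, axes, grid_cfg))
            p = np.array(tr.position)
            assert np.hypot(*(p - p_prev)) < 0.5  # metres; smooth, no jumps
            p_prev = p

    def test_velocity_decode_examples_and_round_trip(self, grid_cfg, axes):
        d = grid.GridDecoding(0, 0, 0, 0, 0, phi_x=0.0, phi_y=0.0,
                              resultants=np.ones(5))
        np.testing.assert_allclose(grid.decode_grid_velocity(d, grid_cfg), 0.0)
        d.phi_x = 0.1
        v = grid.decode_grid_velocity(d, grid_cfg)
        assert v[0] == pytest.approx(96.79, abs=0.01)  # 30*tan(0.2)/(2*pi*0.01)
        for vx, vy in [(3.0, -4.0), (12.0, 7.0)]:
            u = grid.velocity_to_nu(np.array([vx, vy]), grid_cfg)
            d.phi_x, d.phi_y = u
            np.testing.assert_allclose(
                grid.decode_grid_velocity(d, grid_cfg), [vx, vy], rtol=1e-12
            )

    def test_doubling_scale_halves_phase_advance_per_meter(self, grid_cfg):
        cfg2 = GridConfig(S=2 * grid_cfg.S)
        v = np.array([5.0, 0.0])
        u1 = grid.velocity_to_nu(v, grid_cfg)
        u2 = grid.velocity_to_nu(v, cfg2)
        assert u2[0] == pytest.approx(u1[0] / 2, rel=1e-3)

    def test_heading_speed_projection(self):
        np.testing.assert_allclose(grid.heading_speed_to_velocity(1.0, 0.0), [1, 0])
        np.testing.assert_allclose(
            grid.heading_speed_to_velocity(2.0, np.pi / 2), [0, 2], atol=1e-12
        )
        rng = np.random.default_rng(5)
        for _ in range(20):
            s, p = rng.uniform(0, 10), rng.uniform(0, 2 * np.pi)
            assert np.hypot(*grid.heading_speed_to_velocity(s, p)) == pytest.approx(s)
        with pytest.raises(ValueError):
            grid.heading_speed_to_velocity(-1.0, 0.0)


def test_maintained_integration_moves_with_commanded_velocity(
    grid_cfg, grid_kernel, axes, grid_settled
):
    """Under the maintenance current the pattern amplitude survives and the
    decoded position advances along the commanded direction (the magnitude
    is gain-distorted at the shipped parameters; see docs/methods.md)."""
    vel = np.tile([8.0, 0.0], (30, 1))  # 3 s
    pos, state, _ = grid.integrate_velocity_stream(
        vel, grid_cfg, grid_kernel, axes=axes,
        state=grid.GridState(grid_settled.rates.copy()),
    )
    dec = grid.decode_grid_phases(state, axes, grid_cfg)
    assert dec.resultants[0] > 0.05          # amplitude maintained
    assert pos[-1, 0] > 10.0                 # clearly moved in +x
    assert abs(pos[-1, 1]) < 2.0             # negligibly in y
    assert np.all(np.diff(pos[5:, 0]) > 0)   # monotone advance
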