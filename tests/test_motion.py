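"""Motion model: actions, spans, composition and position resolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blochflow import (
    AllSpins,
    FlowPath,
    HeartBeat,
    Motion,
    MotionError,
    NoMotion,
    Path,
    Phantom,
    Rotate,
    SpinRange,
    TimeCurve,
    Translate,
    displace_heartbeat,
    displace_path,
    displace_rotate,
    displace_translate,
    get_spin_coords,
    reset_events,
    time_range,
)


def simple_phantom(n=5, motion=None, rng=None):
    rng = rng or np.random.default_rng(0)
    return Phantom(
        x=rng.normal(0, 0.01, n),
        y=rng.normal(0, 0.01, n),
        z=rng.normal(0, 0.01, n),
        T1=1.0,
        T2=0.1,
        motion=motion if motion is not None else NoMotion(),
    )


class TestTranslate:
    @pytest.mark.parametrize(
        "u,expect",
        [(1.0, (0.01, 0.0, 0.0)), (0.0, (0.0, 0.0, 0.0)), (0.5, (0.005, 0.0, 0.0))],
    )
    def test_linear_scaling(self, u, expect):
        got = displace_translate(Translate(0.01, 0.0, 0.0), u)
        assert got == pytest.approx(expect)

    def test_full_translation_at_curve_end(self):
        motion = Motion(Translate(0.01, -0.02, 0.003), time_range(0.0, 1.0))
        ph = simple_phantom(motion=motion)
        xt, yt, zt = get_spin_coords(ph, [1.0])
        np.testing.assert_allclose(xt[:, 0], ph.x + 0.01, atol=1e-15)
        np.testing.assert_allclose(yt[:, 0], ph.y - 0.02, atol=1e-15)
        np.testing.assert_allclose(zt[:, 0], ph.z + 0.003, atol=1e-15)


class TestRotate:
    def test_zero_progress_is_identity(self):
        pos = np.random.default_rng(1).normal(0, 1, (4, 3))
        out = displace_rotate(Rotate(10, 20, 30), pos, 0.0, center=(0, 0, 0))
        np.testing.assert_allclose(out, pos, atol=1e-12)

    def test_yaw_quarter_turn(self):
        pos = np.array([[1.0, 0.0, 0.0]])
        out = displace_rotate(Rotate(0, 0, 90), pos, 1.0, center=(0, 0, 0))
        np.testing.assert_allclose(out[0], [0.0, 1.0, 0.0], atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
        u=st.floats(0, 1),
        seed=st.integers(0, 100),
    )
    def test_norm_preserved(self, angles, u, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 1, (6, 3))
        c = rng.normal(0, 1, 3)
        out = displace_rotate(Rotate(*angles), pos, u, center=c)
        before = np.linalg.norm(pos - c, axis=1)
        after = np.linalg.norm(out - c, axis=1)
        assert np.max(np.abs(after - before)) < 1e-12

    def test_empty_span_errors(self):
        with pytest.raises(MotionError):
            displace_rotate(Rotate(0, 0, 90), np.empty((0, 3)), 1.0)


class TestHeartBeat:
    def test_zero_strains_zero_displacement(self):
        pos = np.random.default_rng(2).normal(0, 0.01, (10, 3))
        ux, uy, uz = displace_heartbeat(HeartBeat(0, 0, 0), pos, 1.0)
        assert np.all(ux == 0) and np.all(uy == 0) and np.all(uz == 0)

    def test_outermost_spin_has_no_radial_term(self):
        # r == max(r): radial strain cannot contribute by construction
        pos = np.array([[0.02, 0.0, 0.0], [0.01, 0.0, 0.0]])
        ux, _, _ = displace_heartbeat(HeartBeat(0.0, 0.7, 0.0), pos, 1.0)
        assert ux[0] == pytest.approx(0.0, abs=1e-18)

    def test_hand_evaluated_cancellation(self):
        # r = {0.01, 0.02}, cs=0.1, rs=0.2: inner spin's circumferential and
        # radial terms cancel exactly
        pos = np.array([[0.01, 0.0, 0.0], [0.02, 0.0, 0.0]])
        ux, uy, uz = displace_heartbeat(HeartBeat(0.1, 0.2, 0.0), pos, 1.0)
        assert ux[0] == pytest.approx(0.0, abs=1e-18)
        assert uy[0] == uy[1] == 0.0
        # outer spin moves by d_circ = 0.1 * 0.02
        assert ux[1] == pytest.approx(0.002)

    def test_longitudinal_scaling(self):
        pos = np.array([[0.0, 0.0, 0.05]])
        _, _, uz = displace_heartbeat(HeartBeat(0, 0, 0.2), pos, 0.5)
        assert uz[0] == pytest.approx(0.2 * 0.05 * 0.5)


class TestPath:
    def test_endpoint_and_midpoint_interpolation(self):
        dx = np.array([[0.0, 0.01]])
        zeros = np.zeros_like(dx)
        action = Path(dx, zeros, zeros)
        assert displace_path(action, 0.0)[0][0] == 0.0
        assert displace_path(action, 1.0)[0][0] == pytest.approx(0.01)
        assert displace_path(action, 0.5)[0][0] == pytest.approx(0.005)
        # clamped outside [0, 1]
        assert displace_path(action, 1.7)[0][0] == pytest.approx(0.01)

    def test_forward_then_backward_curve_hits_midpoint(self):
        # forward in 1 s, back at double speed: at t = 1.25 s progress is 0.5
        curve = TimeCurve([0.0, 1.0, 1.5], [0.0, 1.0, 0.0])
        assert curve(1.25) == pytest.approx(0.5)

    def test_single_sample_matrix_rejected(self):
        with pytest.raises(MotionError):
            Path(np.zeros((2, 1)), np.zeros((2, 1)), np.zeros((2, 1)))


class TestResetEvents:
    def flow(self, reset):
        reset = np.atleast_2d(reset)
        z = np.zeros_like(reset, dtype=float)
        return FlowPath(z, z.copy(), z.copy(), reset)

    def test_all_zero_never_flags(self):
        action = self.flow(np.zeros((3, 5), dtype=int))
        assert not reset_events(action, 0.0, 1.0).any()

    def test_flag_exactly_when_sample_crossed(self):
        # reset mark at column 2 of 5 -> progress sample 0.5
        action = self.flow([[0, 0, 1, 0, 0]])
        nt = 5
        for k in range(nt):
            u_k = k / (nt - 1)
            for a, b in [(0.0, 0.3), (0.3, 0.55), (0.55, 1.0), (0.45, 0.5)]:
                flagged = reset_events(self.flow(np.eye(1, nt, k, dtype=int)), a, b)[0]
                assert flagged == (a < u_k <= b)

    def test_wrap_interval(self):
        action = self.flow([[0, 0, 0, 0, 1]])  # sample at u = 1
        assert reset_events(action, 0.9, 0.1)[0]  # wrapped across the period end
        assert not reset_events(action, 0.1, 0.9)[0]


class TestGetSpinCoords:
    def test_static_phantom_constant_columns(self):
        ph = simple_phantom()
        xt, yt, zt = get_spin_coords(ph, np.linspace(0, 2, 7))
        for mat, ref in ((xt, ph.x), (yt, ph.y), (zt, ph.z)):
            np.testing.assert_array_equal(mat, np.tile(ref[:, None], (1, 7)))

    def test_zero_progress_returns_initial_positions_exactly(self):
        motions = [
            Motion(Translate(0.01, 0, 0), time_range(1.0, 2.0)),
            Motion(Rotate(5, 10, 15), time_range(1.5, 2.5)),
            Motion(HeartBeat(0.1, 0.2, 0.05), time_range(1.2, 3.0)),
        ]
        ph = simple_phantom(motion=motions)
        xt, yt, zt = get_spin_coords(ph, [0.5])  # every curve still at u = 0
        np.testing.assert_array_equal(xt[:, 0], ph.x)
        np.testing.assert_array_equal(yt[:, 0], ph.y)
        np.testing.assert_array_equal(zt[:, 0], ph.z)

    def test_translate_list_order_independent(self):
        t1 = Motion(Translate(0.01, 0, 0), time_range(0, 1))
        t2 = Motion(Translate(0, 0.02, 0), time_range(0.2, 0.8))
        t3 = Motion(Translate(0, 0, -0.01), time_range(0.5, 2.0))
        t = np.linspace(0, 2, 9)
        ref = get_spin_coords(simple_phantom(motion=[t1, t2, t3]), t)
        for order in ([t2, t3, t1], [t3, t1, t2]):
            out = get_spin_coords(simple_phantom(motion=list(order)), t)
            for a, b in zip(out, ref):
                np.testing.assert_allclose(a, b, atol=1e-15)

    def test_forward_backward_curve_restores_positions(self):
        curve = TimeCurve([0.0, 1.0, 1.5], [0.0, 1.0, 0.0])
        rng = np.random.default_rng(3)
        mats = [rng.normal(0, 0.01, (5, 4)) for _ in range(3)]
        for m in mats:
            m[:, 0] = 0.0  # trajectories start at the initial positions
        motion = Motion(Path(*mats), curve)
        ph = simple_phantom(motion=motion)
        xt, yt, zt = get_spin_coords(ph, [1.5])
        assert np.max(np.abs(xt[:, 0] - ph.x)) < 1e-12
        assert np.max(np.abs(yt[:, 0] - ph.y)) < 1e-12
        assert np.max(np.abs(zt[:, 0] - ph.z)) < 1e-12

    def test_single_rotate_in_list_matches_direct_application(self):
        action = Rotate(10.0, -20.0, 35.0, center=(0.001, 0.0, -0.002))
        motion = Motion(action, time_range(0.0, 1.0))
        ph = simple_phantom(motion=motion)
        t = np.array([0.25, 0.6, 1.0])
        xt, yt, zt = get_spin_coords(ph, t)
        pos0 = np.column_stack([ph.x, ph.y, ph.z])
        for j, tj in enumerate(t):
            direct = displace_rotate(action, pos0, tj, center=action.center)
            np.testing.assert_allclose(
                np.column_stack([xt[:, j], yt[:, j], zt[:, j]]), direct, atol=1e-14
            )

    def test_rotation_preserves_pairwise_distances(self):
        motion = [
            Motion(Rotate(12, 34, 56), time_range(0, 1)),
            Motion(Rotate(-45, 0, 10), time_range(0.5, 1.5)),
        ]
        ph = simple_phantom(n=8, motion=motion)
        xt, yt, zt = get_spin_coords(ph, [1.3])
        p0 = np.column_stack([ph.x, ph.y, ph.z])
        p1 = np.column_stack([xt[:, 0], yt[:, 0], zt[:, 0]])
        d0 = np.linalg.norm(p0[:, None] - p0[None], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-12)

    def test_span_restricts_motion(self):
        motion = Motion(
            Translate(0.01, 0, 0), time_range(0, 1), span=SpinRange([0, 2])
        )
        ph = simple_phantom(motion=motion)
        xt, _, _ = get_spin_coords(ph, [1.0])
        moved = xt[:, 0] - ph.x
        np.testing.assert_allclose(moved[[0, 2]], 0.01, atol=1e-15)
        np.testing.assert_array_equal(moved[[1, 3, 4]], 0.0)

    def test_sequential_ordering_by_curve_start(self):
        # rotate about the origin first (starts at t=0), then heartbeat
        # (starts at t=1); applying them in reversed list order must not change
        # the result because ordering is by time-curve start
        rot = Motion(Rotate(0, 0, 90, center=(0, 0, 0)), time_range(0, 1))
        hb = Motion(HeartBeat(0.2, 0.1, 0.0), time_range(1.0, 2.0))
        t = np.linspace(0, 2, 5)
        a = get_spin_coords(simple_phantom(motion=[rot, hb]), t)
        b = get_spin_coords(simple_phantom(motion=[hb, rot]), t)
        for m1, m2 in zip(a, b):
            np.testing.assert_allclose(m1, m2, atol=1e-14)

    def test_path_row_count_must_match_span(self):
        dx = np.zeros((3, 2))
        motion = Motion(
            Path(dx, dx.copy(), dx.copy()), time_range(0, 1), span=SpinRange([0, 1])
        )
        with pytest.raises(MotionError):
            simple_phantom(motion=motion)

    def test_out_of_bounds_span_rejected(self):
        motion = Motion(Translate(0.01, 0, 0), time_range(0, 1), span=SpinRange([99]))
        with pytest.raises(MotionError):
            simple_phantom(motion=motion)


class TestPhantomInvariants:
    def test_vector_length_mismatch(self):
        with pytest.raises(ValueError):
            Phantom(x=[0, 1], y=[0], z=[0, 0], T1=1, T2=0.1)

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(ValueError):
            Phantom(x=[0], y=[0], z=[0], T1=0.0, T2=0.1)
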