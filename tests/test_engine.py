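"""Discrete-time Bloch solver: grids, kernels, closed forms and invariants."""

import numpy as np
import pytest

import blochflow as bf
from blochflow.constants import GAMMA
from blochflow.engine import block_time_grid


def single_spin(T1=1.0, T2=0.1, dw=0.0, pos=(0.0, 0.0, 0.0)):
    return bf.Phantom(
        x=[pos[0]], y=[pos[1]], z=[pos[2]], T1=[T1], T2=[T2], dw=[dw]
    )


def transverse_state(n=1):
    return bf.SpinState(mxy=np.ones(n, dtype=complex), mz=np.zeros(n))


class TestDiscretize:
    def test_gradient_block_point_count(self):
        # 1 ms gradient-only block at 10 us steps: at least 101 nodes incl. ends
        block = bf.Block(duration=1e-3, gz=bf.Gradient.rect(0.01, 1e-3))
        t, rf_active = block_time_grid(block, dt_rf=1e-6, dt_grad=1e-5)
        assert t.size >= 101
        assert t[0] == 0.0 and t[-1] == pytest.approx(1e-3)
        assert not rf_active.any()

    def test_adc_samples_on_grid(self):
        adc = bf.ADC(n=7, dwell=3.3e-5, delay=1.1e-4)
        block = bf.Block(duration=1e-3, adc=adc)
        t, _ = block_time_grid(block, 1e-6, 1e-5)
        for s in adc.times():
            assert np.min(np.abs(t - s)) < 1e-12

    def test_rf_window_uses_fine_step(self):
        rf = bf.hard_pulse(30, 5e-4, delay=2e-4)
        block = bf.Block(duration=1e-3, rf=rf)
        t, rf_active = block_time_grid(block, dt_rf=1e-6, dt_grad=1e-5)
        mids = 0.5 * (t[:-1] + t[1:])
        dts = np.diff(t)
        in_rf = (mids > 2e-4) & (mids < 7e-4)
        assert np.all(dts[in_rf] <= 1e-6 + 1e-12)
        assert np.array_equal(rf_active, in_rf)

    def test_sequence_grid_and_errors(self):
        seq = bf.Sequence([bf.Block(duration=1e-3), bf.Block(duration=2e-3)])
        t, _ = bf.discretize(seq, 1e-6, 1e-5)
        assert t[0] == 0.0 and t[-1] == pytest.approx(3e-3)
        assert np.all(np.diff(t) > 0)
        with pytest.raises(bf.SequenceError):
            bf.discretize(seq, dt_rf=0.0, dt_grad=1e-5)
        with pytest.raises(bf.SequenceError):
            bf.discretize(seq, dt_rf=1e-4, dt_grad=1e-5)  # dt_rf > dt_grad


class TestClosedForms:
    def test_hard_pulse_flip_angles(self):
        for flip in (30.0, 90.0, 123.0):
            seq = bf.Sequence([bf.Block(duration=1e-4, rf=bf.hard_pulse(flip, 1e-4))])
            _, st = bf.simulate(single_spin(), seq, relax=False, return_state=True)
            assert abs(st.mxy[0]) == pytest.approx(np.sin(np.deg2rad(flip)), abs=1e-9)
            assert st.mz[0] == pytest.approx(np.cos(np.deg2rad(flip)), abs=1e-9)

    def test_free_t2_decay(self):
        seq = bf.Sequence([bf.Block(duration=0.05)])
        _, st = bf.simulate(
            single_spin(), seq, init_state=transverse_state(), return_state=True
        )
        assert abs(st.mxy[0]) == pytest.approx(np.exp(-0.05 / 0.1), rel=1e-12)
        assert st.mz[0] == pytest.approx(1.0 - np.exp(-0.05 / 1.0), rel=1e-9)

    def test_off_resonance_full_turn(self):
        # dw = 2 pi 100 rad/s over 10 ms: phase advances by exactly -2 pi
        seq = bf.Sequence([bf.Block(duration=0.01)])
        _, st = bf.simulate(
            single_spin(dw=2 * np.pi * 100),
            seq,
            relax=False,
            init_state=transverse_state(),
            return_state=True,
        )
        assert np.angle(st.mxy[0]) == pytest.approx(0.0, abs=1e-9)

    def test_signal_amplitude_at_te(self):
        te = 5e-3
        seq = bf.Sequence(
            [
                bf.Block(duration=1e-4, rf=bf.hard_pulse(90, 1e-4)),
                bf.Block(duration=te, adc=bf.ADC(n=1, dwell=1e-6, delay=te - 1e-6)),
            ]
        )
        raw = bf.simulate(single_spin(), seq)
        # T2 decay runs from (mid-)pulse to the sample; allow the pulse-duration blur
        expect = np.exp(-te / 0.1)
        assert abs(raw.samples[0]) == pytest.approx(expect, rel=2e-3)

    def test_moving_spin_bipolar_first_moment_phase(self):
        v, tau, g = 0.3, 1e-3, 0.01
        zeros = np.zeros((1, 2))
        dz = np.array([[0.0, v * 2 * tau]])
        ph = bf.Phantom(
            x=[0], y=[0], z=[0], T1=[1.0], T2=[0.1],
            motion=bf.Motion(bf.Path(zeros, zeros.copy(), dz), bf.time_range(0, 2 * tau)),
        )
        seq = bf.Sequence(
            [
                bf.Block(duration=tau, gz=bf.Gradient.rect(g, tau)),
                bf.Block(duration=tau, gz=bf.Gradient.rect(-g, tau)),
            ]
        )
        _, st = bf.simulate(
            ph, seq, relax=False, init_state=transverse_state(), return_state=True,
            dt_grad=1e-5,
        )
        m1 = -g * tau**2
        assert np.angle(st.mxy[0]) == pytest.approx(-GAMMA * m1 * v, rel=1e-9)


class TestInvariants:
    def test_norm_preserved_without_relaxation(self):
        rng = np.random.default_rng(7)
        n = 10
        ph = bf.Phantom(
            x=rng.normal(0, 0.01, n), y=rng.normal(0, 0.01, n), z=rng.normal(0, 0.01, n),
            T1=1.0, T2=0.1, dw=rng.normal(0, 100, n),
        )
        rf = bf.make_sinc_pulse(70, 1e-3)
        seq = bf.Sequence(
            [bf.Block(duration=1e-3, rf=rf, gz=bf.Gradient.rect(5e-3, 1e-3))]
        )
        _, st = bf.simulate(ph, seq, relax=False, return_state=True)
        norm = np.sqrt(np.abs(st.mxy) ** 2 + st.mz**2)
        np.testing.assert_allclose(norm, 1.0, rtol=1e-12)

    def test_interval_splitting_semigroup(self):
        # halving the step inside constant fields leaves the result unchanged
        ph = single_spin(dw=2 * np.pi * 55)
        seq = bf.Sequence(
            [
                bf.Block(duration=2e-4, rf=bf.hard_pulse(90, 2e-4)),
                bf.Block(duration=4e-3, gz=bf.Gradient.rect(1e-3, 4e-3)),
            ]
        )
        _, a = bf.simulate(ph, seq, dt_rf=1e-5, dt_grad=1e-4, return_state=True)
        _, b = bf.simulate(ph, seq, dt_rf=1e-5, dt_grad=2.5e-5, return_state=True)
        # precession phase is exact for static spins, so only roundoff differs
        assert abs(a.mxy[0] - b.mxy[0]) < 1e-10
        assert abs(a.mz[0] - b.mz[0]) < 1e-10

    def test_doubling_rho_doubles_signal(self):
        seq = bf.Sequence(
            [
                bf.Block(duration=1e-4, rf=bf.hard_pulse(90, 1e-4)),
                bf.Block(duration=1e-3, adc=bf.ADC(n=4, dwell=2e-4, delay=1e-4)),
            ]
        )
        ph1 = bf.Phantom(x=[0.001], y=[0], z=[0], T1=[1], T2=[0.1], rho=[1.0])
        ph2 = bf.Phantom(x=[0.001], y=[0], z=[0], T1=[1], T2=[0.1], rho=[2.0])
        r1 = bf.simulate(ph1, seq)
        r2 = bf.simulate(ph2, seq)
        np.testing.assert_allclose(r2.samples, 2.0 * r1.samples, rtol=1e-12)

    def test_signal_invariant_under_spin_reordering(self):
        rng = np.random.default_rng(11)
        n = 6
        x, y, z = rng.normal(0, 0.01, (3, n))
        t1 = rng.uniform(0.5, 2, n)
        t2 = rng.uniform(0.02, 0.2, n)
        seq = bf.Sequence(
            [
                bf.Block(duration=1e-4, rf=bf.hard_pulse(60, 1e-4)),
                bf.Block(
                    duration=1e-3,
                    gx=bf.Gradient.rect(2e-3, 1e-3),
                    adc=bf.ADC(n=5, dwell=2e-4, delay=0.0),
                ),
            ]
        )
        perm = rng.permutation(n)
        ra = bf.simulate(bf.Phantom(x=x, y=y, z=z, T1=t1, T2=t2), seq)
        rb = bf.simulate(
            bf.Phantom(x=x[perm], y=y[perm], z=z[perm], T1=t1[perm], T2=t2[perm]), seq
        )
        np.testing.assert_allclose(ra.samples, rb.samples, rtol=1e-10)

    def test_empty_sequence_gives_empty_signal(self):
        raw = bf.simulate(single_spin(), bf.Sequence())
        assert raw.n == 0


class TestKernelOps:
    def test_step_excite_without_rf_reduces_to_precession(self):
        dw, dt = 2 * np.pi * 40.0, 1e-4
        pos = np.array([[0.0, 0.0, 0.002]])
        g = (0.0, 0.0, 3e-3)
        a = bf.SpinState(mxy=np.array([1.0 + 0j]), mz=np.array([0.3]))
        b = a.copy()
        bf.step_excite(a, 0.0, g, pos, dw, dt, T1=1.0, T2=0.1, m0=1.0)
        bf.step_precess(b, g, g, pos, pos, dw, dt, T1=1.0, T2=0.1, m0=1.0)
        assert abs(a.mxy[0] - b.mxy[0]) < 1e-14
        assert abs(a.mz[0] - b.mz[0]) < 1e-14

    def test_step_excite_hard_flip(self):
        st = bf.SpinState(mxy=np.zeros(1, dtype=complex), mz=np.ones(1))
        b1 = 5e-6  # T, along x
        dt = (np.pi / 2) / (GAMMA * b1)
        bf.step_excite(st, b1, (0, 0, 0), [[0, 0, 0]], 0.0, dt, T1=1.0, T2=0.1, relax=False)
        assert abs(st.mxy[0]) == pytest.approx(1.0, abs=1e-12)
        assert st.mz[0] == pytest.approx(0.0, abs=1e-12)


class TestFlowReset:
    def test_apply_flow_reset_states(self):
        st = bf.SpinState(mxy=np.array([1j, 0.5 + 0j]), mz=np.array([0.2, -0.3]))
        out = bf.apply_flow_reset(st, [False, False], rho=np.array([1.0, 1.0]))
        assert out.mxy[0] == 1j and out.mz[1] == -0.3
        out = bf.apply_flow_reset(st, [True, True], rho=np.array([1.0, 2.0]))
        assert np.all(out.mxy == 0)
        np.testing.assert_array_equal(out.mz, [1.0, 2.0])

    def test_reset_spin_restarts_from_equilibrium(self):
        """A mid-sequence reinjected spin continues exactly like a fresh spin."""
        length, v = 0.02, 0.5
        duration = 0.05
        # spin crosses the upper boundary at t = (length/2 - z0)/v = 0.03 s
        z0 = -0.005
        t_cross = (0.5 * length - z0) / v
        nt = 101
        t_k = np.linspace(0, duration, nt)
        z_un = z0 + v * t_k
        z_wr = np.mod(z_un + 0.5 * length, length) - 0.5 * length
        reset = np.zeros((1, nt), dtype=np.uint8)
        reset[0, 1:] = (np.diff(np.round((z_un - z_wr) / length)) != 0).astype(np.uint8)
        zeros = np.zeros((1, nt))
        fp = bf.FlowPath(zeros, zeros.copy(), (z_wr - z0)[None, :], reset)
        ph = bf.Phantom(
            x=[0], y=[0], z=[z0], T1=[1.0], T2=[0.1],
            motion=bf.Motion(fp, bf.time_range(0, duration)),
        )
        seq = bf.Sequence(
            [
                bf.Block(duration=1e-4, rf=bf.hard_pulse(90, 1e-4)),
                bf.Block(duration=duration - 1e-4),
            ]
        )
        _, st = bf.simulate(ph, seq, return_state=True, dt_grad=1e-4)
        # after the reset the spin saw no further RF: Mxy = 0 and Mz relaxed
        # from equilibrium (i.e. still equilibrium)
        assert st.mxy[0] == 0.0
        assert st.mz[0] == pytest.approx(1.0)

    def test_spin_count_constant_through_resets(self):
        ph = bf.make_cylinder_flow_phantom(0.003, 0.01, 0.05, 2e9, seed=5)
        n0 = ph.n_spins
        seq = bf.Sequence([bf.Block(duration=0.5)])
        _, st = bf.simulate(ph, seq, return_state=True, dt_grad=1e-3)
        assert st.n_spins == n0


class TestRawSignalIO:
    def test_save_load_roundtrip(self, tmp_path):
        raw = bf.RawSignal(
            samples=np.array([1 + 2j, -0.5j]), times=np.array([0.0, 1e-3])
        )
        p = tmp_path / "raw.h5"
        bf.save_raw(raw, p, metadata={"seq": "test"})
        back = bf.load_raw(p)
        np.testing.assert_array_equal(back.samples, raw.samples)
        np.testing.assert_array_equal(back.times, raw.times)
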