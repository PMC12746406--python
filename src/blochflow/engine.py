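"""Discrete-time Bloch solver with sequence-aware time stepping.

The solver advances per-spin magnetization (complex transverse ``Mxy``,
longitudinal ``Mz``) through the blocks of a :class:`~blochflow.sequence.Sequence`
on a *sequence-aware* time grid: every block boundary, gradient vertex and ADC
sample time is a grid node, and grid spacing never exceeds ``dt_rf`` while an
RF pulse is active or ``dt_grad`` elsewhere.

Each sub-interval applies an operator-split update: an exact rotation of the
magnetization about the effective field held constant at its mid-interval
value, followed by exponential T1/T2 relaxation.  The effective field of a
spin at position ``r`` is ``(Re b1, Im b1, G . r + dw / gamma)`` in Tesla.
During RF-free stretches the z-rotation commutes with relaxation, so whole
blocks are evaluated in closed form: the precession phase
``phi = -gamma * int G(t) . r(t) dt - dw * dt`` is accumulated with
trapezoidal quadrature over the grid (spin positions from
:func:`~blochflow.phantom.get_spin_coords` at the grid nodes) and applied to
``Mxy`` together with T2 decay.

Flow support: spins flagged by a FlowPath ``spin_reset`` traversal are
reinjected with their magnetic state reset to the unexcited state
(``Mxy = 0``, ``Mz`` = equilibrium); the spin count never changes.

The raw signal is the unweighted sum of ``Mxy`` over all spins at the ADC
sample times (single uniform receive coil).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constants import GAMMA
from .phantom import Phantom, flow_reset_flags, get_spin_coords
from .sequence import Block, Sequence, SequenceError

__all__ = [
    "SpinState",
    "RawSignal",
    "discretize",
    "step_excite",
    "step_precess",
    "apply_flow_reset",
    "simulate",
    "save_raw",
    "load_raw",
]

_GRID_MERGE_TOL = 1e-12  # s; grid nodes closer than this are merged
_ADC_MATCH_TOL = 1e-9  # s; ADC samples must coincide with grid nodes


@dataclass
class SpinState:
    """Per-spin magnetization state."""

    mxy: np.ndarray  # complex transverse magnetization
    mz: np.ndarray  # longitudinal magnetization

    @classmethod
    def equilibrium(cls, rho) -> "SpinState":
        rho = np.atleast_1d(np.asarray(rho, dtype=float))
        return cls(mxy=np.zeros(rho.size, dtype=complex), mz=rho.copy())

    def copy(self) -> "SpinState":
        return SpinState(self.mxy.copy(), self.mz.copy())

    @property
    def n_spins(self) -> int:
        return int(self.mxy.size)


@dataclass
class RawSignal:
    """Complex signal samples collected over all ADC events, with their times."""

    samples: np.ndarray
    times: np.ndarray

    @property
    def n(self) -> int:
        return int(self.samples.size)


# ----------------------------------------------------------------------
# Time discretization
# ----------------------------------------------------------------------
def _merge_sorted(points: np.ndarray) -> np.ndarray:
    points = np.sort(points)
    keep = np.concatenate(([True], np.diff(points) > _GRID_MERGE_TOL))
    return points[keep]


def block_time_grid(block: Block, dt_rf: float, dt_grad: float):
    """Simulation grid for one block (times relative to the block start).

    Returns ``(t, rf_active)`` where ``t`` contains both block ends, every
    gradient vertex and every ADC sample time, subdivided so spacing is at
    most ``dt_rf`` inside the RF window and ``dt_grad`` elsewhere, and
    ``rf_active`` flags each of the ``len(t) - 1`` intervals.
    """
    if dt_rf <= 0 or dt_grad <= 0:
        raise SequenceError("time steps must be positive")
    if dt_rf > dt_grad:
        raise SequenceError("dt_rf must not exceed dt_grad")
    dur = block.duration
    pts = [np.array([0.0, dur])]
    for g in block.gradients:
        if g is not None:
            v = g.times[(g.times > 0.0) & (g.times < dur)]
            pts.append(v)
    if block.adc is not None:
        pts.append(block.adc.times())
    rf_lo, rf_hi = (-1.0, -1.0)
    if block.rf is not None:
        rf_lo, rf_hi = block.rf.delay, min(block.rf.end, dur)
        pts.append(np.array([rf_lo, rf_hi]))
    anchors = _merge_sorted(np.concatenate(pts))
    anchors = anchors[(anchors >= -_GRID_MERGE_TOL) & (anchors <= dur + _GRID_MERGE_TOL)]

    out = [np.array([anchors[0]])]
    for a, b in zip(anchors[:-1], anchors[1:]):
        mid = 0.5 * (a + b)
        step = dt_rf if (block.rf is not None and rf_lo - 1e-15 <= mid <= rf_hi + 1e-15) else dt_grad
        n_sub = max(int(np.ceil((b - a) / step - 1e-9)), 1)
        out.append(np.linspace(a, b, n_sub + 1)[1:])
    t = np.concatenate(out)
    mids = 0.5 * (t[:-1] + t[1:])
    rf_active = (block.rf is not None) & (mids >= rf_lo - 1e-15) & (mids <= rf_hi + 1e-15)
    return t, rf_active


def discretize(seq: Sequence, dt_rf: float = 1e-6, dt_grad: float = 1e-5):
    """Full simulation grid of a sequence.

    Returns ``(times, rf_active)``: absolute grid times and, per interval, a
    flag marking RF-active stepping.
    """
    times = [np.array([0.0])]
    flags = []
    t0 = 0.0
    for block in seq.blocks:
        tg, fa = block_time_grid(block, dt_rf, dt_grad)
        times.append(t0 + tg[1:])
        flags.append(fa)
        t0 += block.duration
    return np.concatenate(times), (
        np.concatenate(flags) if flags else np.empty(0, dtype=bool)
    )


# ----------------------------------------------------------------------
# Kernels
# ----------------------------------------------------------------------
def _rotate(mx, my, mz, bx, by, bz, dt):
    """Exact rotation of (Mx, My, Mz) about the field (bx, by, bz) for dt.

    Rodrigues formula with rotation angle ``-gamma * |B| * dt`` (the Bloch
    torque ``dM/dt = gamma M x B``).  Norm-preserving.
    """
    b2 = bx * bx + by * by + bz * bz
    nb = np.sqrt(b2)
    safe = np.where(nb > 0.0, nb, 1.0)
    kx, ky, kz = bx / safe, by / safe, bz / safe
    ang = -GAMMA * nb * dt
    c, s = np.cos(ang), np.sin(ang)
    one_c = 1.0 - c
    kdotm = kx * mx + ky * my + kz * mz
    cx = ky * mz - kz * my
    cy = kz * mx - kx * mz
    cz = kx * my - ky * mx
    rx = mx * c + cx * s + kx * kdotm * one_c
    ry = my * c + cy * s + ky * kdotm * one_c
    rz = mz * c + cz * s + kz * kdotm * one_c
    still = nb == 0.0
    if np.any(still):
        rx = np.where(still, mx, rx)
        ry = np.where(still, my, ry)
        rz = np.where(still, mz, rz)
    return rx, ry, rz


def _relax(state: SpinState, dt, T1, T2, m0):
    state.mxy *= np.exp(-dt / T2)
    state.mz = m0 + (state.mz - m0) * np.exp(-dt / T1)


def step_excite(state: SpinState, b1, gxyz, pos, dw, dt, T1, T2, m0=None, relax=True) -> SpinState:
    """One excitation sub-step: exact rotation about the effective field, then relaxation.

    ``b1`` is the complex RF amplitude (T) held constant over ``dt``; ``gxyz``
    the gradient triplet (T/m); ``pos`` the spin positions ``(Ns, 3)`` (m);
    ``dw`` the off-resonance (rad/s).  Mutates and returns ``state``.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    if m0 is None:
        m0 = 1.0  # unit equilibrium; pass rho for weighted spins
    bz = pos[:, 0] * gxyz[0] + pos[:, 1] * gxyz[1] + pos[:, 2] * gxyz[2] + np.asarray(dw) / GAMMA
    bx = np.broadcast_to(np.real(b1), bz.shape)
    by = np.broadcast_to(np.imag(b1), bz.shape)
    mx, my, mz = _rotate(state.mxy.real, state.mxy.imag, state.mz, bx, by, bz, dt)
    state.mxy = mx + 1j * my
    state.mz = mz
    if relax:
        _relax(state, dt, T1, T2, m0)
    return state


def step_precess(
    state: SpinState, g0, g1, pos0, pos1, dw, dt, T1, T2, m0=None, relax=True
) -> SpinState:
    """One RF-free sub-step: trapezoidal precession phase, then relaxation.

    Gradients and positions are supplied at the sub-interval endpoints; the
    phase increment is ``-gamma * int G.r dt`` (trapezoid) minus ``dw * dt``.
    """
    pos0 = np.atleast_2d(np.asarray(pos0, dtype=float))
    pos1 = np.atleast_2d(np.asarray(pos1, dtype=float))
    f0 = pos0[:, 0] * g0[0] + pos0[:, 1] * g0[1] + pos0[:, 2] * g0[2]
    f1 = pos1[:, 0] * g1[0] + pos1[:, 1] * g1[1] + pos1[:, 2] * g1[2]
    phi = -(GAMMA * 0.5 * (f0 + f1) + np.asarray(dw)) * dt
    state.mxy = state.mxy * np.exp(1j * phi)
    if relax:
        if m0 is None:
            m0 = 1.0  # unit equilibrium; pass rho for weighted spins
        _relax(state, dt, T1, T2, m0)
    return state


def apply_flow_reset(state: SpinState, flags, rho) -> SpinState:
    """Reset flagged spins to the unexcited state (Mxy = 0, Mz = rho)."""
    flags = np.asarray(flags, dtype=bool)
    if flags.any():
        rho = np.broadcast_to(np.asarray(rho, dtype=float), state.mz.shape)
        state.mxy[flags] = 0.0
        state.mz[flags] = rho[flags]
    return state


# ----------------------------------------------------------------------
# Block runners
# ----------------------------------------------------------------------
def _grad_values(block: Block, t):
    out = []
    for g in block.gradients:
        out.append(g.value(t) if g is not None else np.zeros(np.shape(t)))
    return out


def _adc_indices(block: Block, tg: np.ndarray) -> np.ndarray:
    at = block.adc.times()
    idx = np.searchsorted(tg, at - _ADC_MATCH_TOL)
    if np.any(np.abs(tg[np.clip(idx, 0, tg.size - 1)] - at) > _ADC_MATCH_TOL):
        raise SequenceError("internal error: ADC sample missing from the time grid")
    return idx


def _slab_mask(block: Block, xt, yt, zt):
    comp = {"x": xt, "y": yt, "z": zt}[block.slab.axis][:, 0]
    return np.abs(comp - block.slab.center) <= 0.5 * block.slab.thickness


def _run_rf_block(block, tg, xt, yt, zt, flags, state, T1, T2, m0, dw, relax, collect):
    mids = 0.5 * (tg[:-1] + tg[1:])
    dts = np.diff(tg)
    b1m = block.rf.b1(mids)
    gxm, gym, gzm = _grad_values(block, mids)
    in_slab = _slab_mask(block, xt, yt, zt) if block.slab is not None else None
    static = xt.shape[1] == 1
    adc_idx = _adc_indices(block, tg) if block.adc is not None else np.empty(0, dtype=np.int64)
    adc_ptr = 0
    if adc_ptr < adc_idx.size and adc_idx[adc_ptr] == 0:
        collect(state.mxy.sum(), tg[0])
        adc_ptr += 1
    dwg = dw / GAMMA
    for j in range(dts.size):
        if static:
            xm, ym, zm = xt[:, 0], yt[:, 0], zt[:, 0]
        else:
            xm = 0.5 * (xt[:, j] + xt[:, j + 1])
            ym = 0.5 * (yt[:, j] + yt[:, j + 1])
            zm = 0.5 * (zt[:, j] + zt[:, j + 1])
        dt = dts[j]
        bz = gxm[j] * xm + gym[j] * ym + gzm[j] * zm + dwg
        b1 = b1m[j]
        if b1 != 0.0:
            bx = np.full(bz.shape, b1.real)
            by = np.full(bz.shape, b1.imag)
            if in_slab is not None:
                bx[~in_slab] = 0.0
                by[~in_slab] = 0.0
            mx, my, mz = _rotate(state.mxy.real, state.mxy.imag, state.mz, bx, by, bz, dt)
            state.mxy = mx + 1j * my
            state.mz = mz
        else:
            state.mxy = state.mxy * np.exp(-1j * GAMMA * bz * dt)
        if relax:
            _relax(state, dt, T1, T2, m0)
        if flags is not None:
            apply_flow_reset(state, flags[:, j], m0)
        if adc_ptr < adc_idx.size and adc_idx[adc_ptr] == j + 1:
            collect(state.mxy.sum(), tg[j + 1])
            adc_ptr += 1


def _run_precession_block(block, tg, xt, yt, zt, flags, state, T1, T2, m0, dw, relax, collect):
    gxv, gyv, gzv = _grad_values(block, tg)
    # rad/s seen by each spin at each grid node
    omega = GAMMA * (gxv[None, :] * xt + gyv[None, :] * yt + gzv[None, :] * zt) + dw[:, None]
    dts = np.diff(tg)
    dphi = -0.5 * (omega[:, :-1] + omega[:, 1:]) * dts[None, :]
    phi = np.concatenate([np.zeros((omega.shape[0], 1)), np.cumsum(dphi, axis=1)], axis=1)
    rel_t = tg - tg[0]
    mxy_t = state.mxy[:, None] * np.exp(1j * phi)
    if relax:
        mxy_t *= np.exp(-rel_t[None, :] / T2[:, None])
    if flags is not None and flags.any():
        gone = np.cumsum(flags, axis=1) > 0  # spin reset at or before interval j
        mxy_t[:, 1:][gone] = 0.0
    if block.adc is not None:
        idx = _adc_indices(block, tg)
        sig = mxy_t[:, idx].sum(axis=0)
        for s, t in zip(sig, tg[idx]):
            collect(s, t)
    state.mxy = mxy_t[:, -1].copy()
    if relax:
        state.mz = m0 + (state.mz - m0) * np.exp(-rel_t[-1] / T1)
    if flags is not None and flags.any():
        reset_any = flags.any(axis=1)
        state.mz[reset_any] = m0[reset_any]


# ----------------------------------------------------------------------
def simulate(
    phantom: Phantom,
    seq: Sequence,
    dt_rf: float = 1e-6,
    dt_grad: float = 1e-5,
    relax: bool = True,
    init_state: Optional[SpinState] = None,
    return_state: bool = False,
):
    """Run the Bloch simulation of ``phantom`` under ``seq``.

    Deterministic given its inputs.  Returns the :class:`RawSignal` (all ADC
    samples in order); with ``return_state=True`` also returns the final
    :class:`SpinState`.
    """
    state = init_state.copy() if init_state is not None else SpinState.equilibrium(phantom.rho)
    if state.n_spins != phantom.n_spins:
        raise ValueError("initial state size does not match the phantom spin count")
    m0, T1, T2, dw = phantom.rho, phantom.T1, phantom.T2, phantom.dw
    has_flow = phantom.has_flow
    static = phantom.is_static

    samples, stimes = [], []

    def collect(s, t_abs):
        samples.append(s)
        stimes.append(t_abs)

    t0 = 0.0
    for block in seq.blocks:
        tg, _ = block_time_grid(block, dt_rf, dt_grad)
        ta = t0 + tg
        if static:
            xt = phantom.x[:, None]
            yt = phantom.y[:, None]
            zt = phantom.z[:, None]
        else:
            xt, yt, zt = get_spin_coords(phantom, ta)
        flags = flow_reset_flags(phantom, ta) if has_flow else None

        def collect_abs(s, t_rel, _t0=t0):
            collect(s, _t0 + t_rel)

        if block.rf is not None:
            _run_rf_block(block, tg, xt, yt, zt, flags, state, T1, T2, m0, dw, relax, collect_abs)
        else:
            if static:
                xt = np.broadcast_to(xt, (phantom.n_spins, tg.size))
                yt = np.broadcast_to(yt, (phantom.n_spins, tg.size))
                zt = np.broadcast_to(zt, (phantom.n_spins, tg.size))
            _run_precession_block(
                block, tg, xt, yt, zt, flags, state, T1, T2, m0, dw, relax, collect_abs
            )
        if block.spoil:
            state.mxy[:] = 0.0
        t0 += block.duration

    raw = RawSignal(
        samples=np.asarray(samples, dtype=complex), times=np.asarray(stimes, dtype=float)
    )
    if raw.n != seq.n_adc:
        raise SequenceError("collected sample count does not match the sequence ADC total")
    return (raw, state) if return_state else raw


# ----------------------------------------------------------------------
# Raw-signal export (simple HDF5 container)
# ----------------------------------------------------------------------
def save_raw(raw: RawSignal, path, metadata: Optional[dict] = None) -> None:
    """Write a raw signal to an HDF5 file (samples, times, optional metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["Format"] = "blochflow-raw"
        f.attrs["Version"] = "1.0"
        f.create_dataset("samples", data=np.asarray(raw.samples, dtype=complex))
        f.create_dataset("times", data=np.asarray(raw.times, dtype=float))
        for k, v in (metadata or {}).items():
            f.attrs[k] = v


def load_raw(path) -> RawSignal:
    """Read a raw signal written by :func:`save_raw`."""
    import h5py

    with h5py.File(path, "r") as f:
        return RawSignal(samples=f["samples"][()], times=f["times"][()])
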