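"""Pulse-sequence builders: slice-selective excitation, bSSFP cine, velocity-encoded GRE, SPAMM.

All builders are deterministic and return :class:`~blochflow.sequence.Sequence`
objects built from rectangular gradient lobes and either hard pulses or an
apodized-sinc slice-selective pulse.  Cartesian encoding follows the
convention used by :func:`blochflow.recon.recon_cartesian`: phase-encode line
``l`` (of ``n``) sits at ``ky = (l - n/2) * dk``, readout sample ``m`` at
``kx = (m - n/2) * dk`` with ``dk = 2 pi / FOV`` (rad/m).
"""

from __future__ import annotations

import numpy as np

from .constants import GAMMA
from .recon import VelocityEncoding
from .sequence import ADC, Block, Gradient, RF, Sequence, SequenceError, Slab, hard_pulse

__all__ = [
    "make_sinc_pulse",
    "build_slice_select",
    "build_bssfp_cine",
    "build_gre_pc",
    "build_spamm_prep",
]


def make_sinc_pulse(
    flip_deg: float,
    duration: float = 3e-3,
    tbw: float = 4.0,
    phase_deg: float = 0.0,
) -> RF:
    """Hann-apodized sinc pulse with the given flip angle and time-bandwidth product.

    The envelope is a continuous callable, so the Bloch solver samples it at
    its own sub-step midpoints and the discretization error is governed by the
    simulation time step.
    """

    def shape(tau):
        tau = np.asarray(tau, dtype=float)
        xarg = tbw * (tau / duration - 0.5)
        hann = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / duration))
        return np.sinc(xarg) * hann

    # normalize the area to the requested flip (dense trapezoid; the envelope
    # is smooth so this converges far below solver accuracy)
    tt = np.linspace(0.0, duration, 8193)
    area = np.trapezoid(shape(tt), tt)
    amp = np.deg2rad(flip_deg) / (GAMMA * area)
    phase = np.exp(1j * np.deg2rad(phase_deg))

    def envelope(tau, _a=amp * phase):
        return _a * shape(tau)

    return RF(envelope=envelope, duration=duration)


def build_slice_select(
    flip_deg: float = 90.0,
    rf_duration: float = 3e-3,
    tbw: float = 4.0,
    slab_thickness: float = 0.01,
    rewind: bool = True,
) -> Sequence:
    """Slice-selective excitation: apodized sinc + slice gradient + rewinder.

    The slice gradient amplitude maps the pulse bandwidth ``tbw / rf_duration``
    onto ``slab_thickness``; the rewinder has minus half the slice-gradient
    area (amplitude ``-G``, duration ``rf_duration / 2``).
    """
    bw = tbw / rf_duration  # Hz
    g_ss = 2.0 * np.pi * bw / (GAMMA * slab_thickness)
    rf = make_sinc_pulse(flip_deg, rf_duration, tbw)
    seq = Sequence(name="slice-select")
    seq.append(
        Block(
            duration=rf_duration,
            rf=rf,
            gz=Gradient.rect(g_ss, rf_duration),
            label="excite",
        )
    )
    if rewind:
        seq.append(
            Block(
                duration=0.5 * rf_duration,
                gz=Gradient.rect(-g_ss, 0.5 * rf_duration),
                label="rewind",
            )
        )
    return seq


# ----------------------------------------------------------------------
# Cartesian imaging helpers
# ----------------------------------------------------------------------
def _readout_block(fov: float, n: int, dwell: float, extra_g=None) -> Block:
    """Readout block: flat Gx covering n ADC samples, kx = (m - n/2) dk at sample m.

    Assumes the prephaser already placed kx at ``-(n/2) dk`` when the block
    starts; sample ``m`` is taken at ``t = m * dwell``.
    """
    dk = 2.0 * np.pi / fov
    g_read = dk / (GAMMA * dwell)
    dur = n * dwell
    kwargs = dict(extra_g or {})
    return Block(
        duration=dur,
        gx=Gradient.rect(g_read, dur),
        adc=ADC(n=n, dwell=dwell, delay=0.0),
        label="readout",
        **kwargs,
    )


def _lobe(area: float, duration: float) -> Gradient:
    return Gradient.rect(area / duration, duration)


def build_bssfp_cine(
    fov: float,
    n_matrix: int,
    tr: float = 5e-3,
    te: float = None,
    flip_deg: float = 50.0,
    n_phases: int = 1,
    dwell: float = 2e-5,
    rf_duration: float = 2e-4,
    slab: Slab = None,
    catalyze: bool = False,
) -> Sequence:
    """Balanced SSFP cine: ``n_phases`` frames of ``n_matrix`` Cartesian lines.

    Every TR is fully balanced (zero net gradient area on all axes) and the RF
    phase alternates 0/180 degrees from TR to TR, so the echo sign alternates;
    :func:`blochflow.recon.recon_cartesian` callers should demodulate with
    ``(-1)**line_counter`` (global TR index).  ``te`` defaults to ``tr / 2``.
    With ``catalyze=True`` an ``alpha/2 - tr/2`` preparation block is
    prepended to damp the transient.
    """
    te = tr / 2.0 if te is None else te
    dk = 2.0 * np.pi / fov
    t_read = n_matrix * dwell
    t_pre = te - 0.5 * rf_duration - 0.5 * t_read
    t_post = tr - rf_duration - t_pre - t_read
    if t_pre <= 0 or t_post <= 0:
        raise SequenceError("TR/TE leave no room for the encoding lobes")
    read_pre_area = -(n_matrix / 2.0) * dk / GAMMA
    read_area = n_matrix * dk / GAMMA
    read_post_area = -read_area - read_pre_area  # balance Gx exactly

    seq = Sequence(name="bssfp-cine")
    tr_index = 0
    if catalyze:
        seq.append(
            Block(
                duration=tr / 2.0,
                rf=hard_pulse(flip_deg / 2.0, rf_duration, phase_deg=180.0),
                slab=slab,
                label="catalyze",
            )
        )
        tr_index = 1
    for _ in range(n_phases):
        for line in range(n_matrix):
            ky = (line - n_matrix / 2.0) * dk
            pe_area = ky / GAMMA
            phase = 180.0 * (tr_index % 2)
            seq.append(
                Block(duration=rf_duration, rf=hard_pulse(flip_deg, rf_duration, phase),
                      slab=slab, label=f"rf l={line}")
            )
            seq.append(
                Block(duration=t_pre, gx=_lobe(read_pre_area, t_pre),
                      gy=_lobe(pe_area, t_pre), label="encode")
            )
            seq.append(_readout_block(fov, n_matrix, dwell))
            seq.append(
                Block(duration=t_post, gx=_lobe(read_post_area, t_post),
                      gy=_lobe(-pe_area, t_post), label="rewind")
            )
            tr_index += 1
    return seq


def build_gre_pc(
    fov: float,
    n_matrix: int,
    tr: float = 1e-2,
    te: float = 6e-3,
    flip_deg: float = 15.0,
    enc: VelocityEncoding = None,
    sign: int = +1,
    dwell: float = 2e-5,
    rf_duration: float = 2e-4,
    bipolar_lobe: float = 1e-3,
    slab: Slab = None,
) -> Sequence:
    """Velocity-encoded spoiled GRE: bipolar lobes between excitation and readout.

    The two acquisitions of a phase-contrast pair use ``sign = +1`` and
    ``sign = -1``; their gradient first moments along ``enc.direction`` differ
    by ``M1 = pi / (gamma * venc)``, so a spin moving at ``v = venc`` along
    the encoding direction accrues a phase difference of pi.  Each TR ends
    with an ideal spoiler (transverse magnetization zeroed).
    """
    if enc is None:
        raise SequenceError("build_gre_pc requires a VelocityEncoding")
    if sign not in (+1, -1):
        raise SequenceError("sign must be +1 or -1")
    dk = 2.0 * np.pi / fov
    tau = bipolar_lobe
    # bipolar (+g, -g) has first moment -g tau^2 (area-free, origin independent);
    # the +1 acquisition carries moment -M1/2, the -1 acquisition +M1/2.
    g_amp = sign * enc.m1 / (2.0 * tau**2)
    t_read = n_matrix * dwell
    t_pre = te - 0.5 * rf_duration - 2.0 * tau - 0.5 * t_read
    t_spoil = tr - rf_duration - 2.0 * tau - t_pre - t_read
    if t_pre <= 0 or t_spoil <= 0:
        raise SequenceError("TR/TE leave no room for the velocity-encoding lobes")
    read_pre_area = -(n_matrix / 2.0) * dk / GAMMA

    ex, ey, ez = enc.direction

    def lobe(component, polarity):
        if component == 0.0:
            return None
        return Gradient.rect(polarity * g_amp * component, tau)

    seq = Sequence(name=f"gre-pc{'+' if sign > 0 else '-'}")
    for line in range(n_matrix):
        ky = (line - n_matrix / 2.0) * dk
        seq.append(Block(duration=rf_duration, rf=hard_pulse(flip_deg, rf_duration),
                         slab=slab, label=f"rf l={line}"))
        # bipolar pair as two rect blocks (field steps sit on block boundaries,
        # where the solver grid is exact)
        seq.append(Block(duration=tau, gx=lobe(ex, +1), gy=lobe(ey, +1),
                         gz=lobe(ez, +1), label="venc+"))
        seq.append(Block(duration=tau, gx=lobe(ex, -1), gy=lobe(ey, -1),
                         gz=lobe(ez, -1), label="venc-"))
        seq.append(
            Block(duration=t_pre, gx=_lobe(read_pre_area, t_pre),
                  gy=_lobe(ky / GAMMA, t_pre), label="encode")
        )
        seq.append(_readout_block(fov, n_matrix, dwell))
        seq.append(
            Block(duration=t_spoil, gz=Gradient.rect(20e-3, 0.5 * t_spoil),
                  spoil=True, label="spoil")
        )
    return seq


def build_spamm_prep(
    grid_spacing: float,
    axis: str = "x",
    flip_deg: float = 90.0,
    rf_duration: float = 1e-4,
    grad_duration: float = 1e-3,
    spoil_duration: float = 1e-3,
) -> Sequence:
    """1-1 SPAMM tagging preparation: 90 - tagging gradient - 90 - spoiler.

    Leaves the longitudinal magnetization modulated as
    ``Mz proportional to cos(2 pi s / grid_spacing)`` along the chosen axis
    ``s`` (for relaxation-free spins), imprinting parallel tag lines of the
    requested spatial period.
    """
    if axis not in ("x", "y", "z"):
        raise SequenceError("axis must be 'x', 'y' or 'z'")
    area = 2.0 * np.pi / (GAMMA * grid_spacing)
    tag = {f"g{axis}": _lobe(area, grad_duration)}
    seq = Sequence(name="spamm-1-1")
    seq.append(Block(duration=rf_duration, rf=hard_pulse(flip_deg, rf_duration), label="tip"))
    seq.append(Block(duration=grad_duration, **tag, label="tag"))
    seq.append(Block(duration=rf_duration, rf=hard_pulse(flip_deg, rf_duration), label="tip-back"))
    seq.append(Block(duration=spoil_duration, spoil=True, label="spoil"))
    return seq
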