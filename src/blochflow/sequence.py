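"""Pulse-sequence representation: blocks of RF, gradients and ADC events.

A :class:`Sequence` is an ordered list of :class:`Block` objects.  Each block
may carry

* an RF pulse (:class:`RF`) -- a complex envelope in Tesla, given either as a
  callable of time (continuous waveform, sampled by the solver at its own
  grid) or as samples on a uniform raster (sample-and-hold),
* up to three gradient channels (:class:`Gradient`) -- piecewise-linear
  amplitude waveforms in T/m defined by vertex times within the block,
* an ADC window (:class:`ADC`) -- uniformly spaced complex signal samples,
* an optional ideal slice slab (:class:`Slab`) restricting the RF rotation to
  spins inside the slab (ideal slice profile), and
* an optional ideal spoiler flag (transverse magnetization zeroed at the end
  of the block).

Times inside a block are relative to the block start, in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Union

import numpy as np

from .constants import GAMMA

__all__ = ["RF", "Gradient", "ADC", "Slab", "Block", "Sequence", "hard_pulse", "SequenceError"]


class SequenceError(ValueError):
    """Raised for invalid sequence definitions."""


@dataclass
class Gradient:
    """Piecewise-linear gradient waveform on one axis.

    ``times`` are strictly increasing vertex times (s, relative to the block
    start) and ``amps`` the amplitudes (T/m) at those vertices.  The waveform
    is zero outside ``[times[0], times[-1]]``.
    """

    times: np.ndarray
    amps: np.ndarray

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        g = np.atleast_1d(np.asarray(self.amps, dtype=float))
        if t.size != g.size or t.size < 2:
            raise SequenceError("gradient needs >= 2 vertices with matching amplitudes")
        if np.any(np.diff(t) <= 0):
            raise SequenceError("gradient vertex times must be strictly increasing")
        self.times, self.amps = t, g

    def value(self, t):
        t = np.asarray(t, dtype=float)
        v = np.interp(t, self.times, self.amps)
        return np.where((t < self.times[0]) | (t > self.times[-1]), 0.0, v)

    def area(self) -> float:
        """Zeroth moment integral G dt (T*s/m)."""
        return float(np.trapezoid(self.amps, self.times))

    def first_moment(self, origin: float = 0.0) -> float:
        """First moment integral G(t) (t - origin) dt (T*s^2/m).

        Exact for the piecewise-linear waveform (Simpson per segment, the
        integrand being quadratic there).
        """
        t, g = self.times, self.amps
        tm = 0.5 * (t[:-1] + t[1:])
        gm = 0.5 * (g[:-1] + g[1:])
        f0 = g[:-1] * (t[:-1] - origin)
        f1 = g[1:] * (t[1:] - origin)
        fm = gm * (tm - origin)
        return float(np.sum((t[1:] - t[:-1]) / 6.0 * (f0 + 4.0 * fm + f1)))

    @classmethod
    def rect(cls, amp: float, duration: float, delay: float = 0.0) -> "Gradient":
        """Rectangular lobe of the given amplitude and duration."""
        return cls(np.array([delay, delay + duration]), np.array([amp, amp]))


@dataclass
class RF:
    """RF pulse: complex B1 envelope (T) with a carrier at the Larmor frequency.

    ``envelope`` is either a callable mapping time since the pulse start to
    complex B1 (evaluated at the solver's sub-step midpoints), or an array of
    complex samples on a uniform raster of ``raster`` seconds
    (sample-and-hold).
    """

    envelope: Union[Callable, np.ndarray]
    duration: float
    delay: float = 0.0
    raster: Optional[float] = None

    def __post_init__(self):
        if self.duration <= 0:
            raise SequenceError("RF duration must be positive")
        if not callable(self.envelope):
            samp = np.atleast_1d(np.asarray(self.envelope, dtype=complex))
            if samp.size < 1:
                raise SequenceError("sampled RF envelope must hold at least one sample")
            if self.raster is None:
                self.raster = self.duration / samp.size
            self.envelope = samp

    def b1(self, t):
        """Complex B1 at block-relative times ``t`` (zero outside the pulse)."""
        t = np.asarray(t, dtype=float)
        tau = t - self.delay
        inside = (tau >= 0.0) & (tau <= self.duration)
        if callable(self.envelope):
            out = np.where(inside, self.envelope(np.clip(tau, 0.0, self.duration)), 0.0)
        else:
            idx = np.clip((tau / self.raster).astype(np.int64), 0, self.envelope.size - 1)
            out = np.where(inside, self.envelope[idx], 0.0)
        return out + 0.0j

    @property
    def end(self) -> float:
        return self.delay + self.duration


@dataclass
class ADC:
    """ADC window: ``n`` samples spaced ``dwell`` seconds, first at ``delay``."""

    n: int
    dwell: float
    delay: float = 0.0

    def __post_init__(self):
        if self.n < 1 or self.dwell <= 0:
            raise SequenceError("ADC needs n >= 1 samples and a positive dwell")

    def times(self) -> np.ndarray:
        return self.delay + np.arange(self.n) * self.dwell


@dataclass
class Slab:
    """Ideal slice slab: RF rotates only spins with |axis - center| <= thickness/2."""

    center: float = 0.0
    thickness: float = 0.01
    axis: str = "z"

    def __post_init__(self):
        if self.axis not in ("x", "y", "z"):
            raise SequenceError("slab axis must be 'x', 'y' or 'z'")
        if self.thickness <= 0:
            raise SequenceError("slab thickness must be positive")


@dataclass
class Block:
    """One sequence block with optional RF, gradients, ADC, slab and spoiler."""

    duration: float
    rf: Optional[RF] = None
    gx: Optional[Gradient] = None
    gy: Optional[Gradient] = None
    gz: Optional[Gradient] = None
    adc: Optional[ADC] = None
    slab: Optional[Slab] = None
    spoil: bool = False
    label: str = ""

    def __post_init__(self):
        if self.duration <= 0:
            raise SequenceError("block duration must be positive")
        if self.rf is not None and self.rf.end > self.duration + 1e-12:
            raise SequenceError("RF pulse extends past the block end")
        if self.adc is not None:
            t_last = self.adc.times()[-1]
            if self.adc.delay < -1e-15 or t_last > self.duration + 1e-12:
                raise SequenceError("ADC window must lie within its block")

    @property
    def gradients(self):
        return self.gx, self.gy, self.gz


class Sequence:
    """Ordered list of blocks with helper accessors."""

    def __init__(self, blocks: Optional[List[Block]] = None, name: str = "sequence"):
        self.blocks: List[Block] = list(blocks) if blocks else []
        self.name = name

    def append(self, block: Block) -> "Sequence":
        self.blocks.append(block)
        return self

    def extend(self, blocks) -> "Sequence":
        for b in blocks:
            self.append(b)
        return self

    @property
    def duration(self) -> float:
        return float(sum(b.duration for b in self.blocks))

    @property
    def n_adc(self) -> int:
        return sum(b.adc.n for b in self.blocks if b.adc is not None)

    def block_starts(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum([b.duration for b in self.blocks])))[:-1]

    def adc_times(self) -> np.ndarray:
        """Absolute times of every ADC sample in order."""
        out = []
        for start, b in zip(self.block_starts(), self.blocks):
            if b.adc is not None:
                out.append(start + b.adc.times())
        return np.concatenate(out) if out else np.empty(0)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __repr__(self) -> str:
        return f"Sequence(name={self.name!r}, n_blocks={len(self.blocks)}, duration={self.duration:.6g} s)"


def hard_pulse(flip_deg: float, duration: float, phase_deg: float = 0.0, delay: float = 0.0) -> RF:
    """Constant-envelope (hard) pulse producing the requested on-resonance flip."""
    amp = np.deg2rad(flip_deg) / (GAMMA * duration)
    b1 = amp * np.exp(1j * np.deg2rad(phase_deg))
    return RF(envelope=lambda t, _b=b1: np.full(np.shape(t), _b), duration=duration, delay=delay)
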