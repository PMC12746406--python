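"""Digital phantom container and spin-position resolution.

A :class:`Phantom` is a set of isochromats ("spins") with initial positions
``(x, y, z)`` in meters, tissue parameters (``T1``, ``T2``, ``T2s`` in
seconds, proton density ``rho`` in arbitrary units), per-spin off-resonance
``dw`` (rad/s) and a motion specification (``NoMotion``, a single ``Motion``
or a motion list).

:func:`get_spin_coords` resolves the positions of every spin at a vector of
query times.  Composition follows the dependency rule of the motion model:
rotations and heart-beat deformations depend on updated positions and are
applied sequentially (ordered by the start time of their time curves, ties
broken by list order), each acting on the positions produced so far;
translations and path displacements are position-independent, so they are
computed from the initial coordinates and summed onto the result.  Spins
outside a motion's span are unaffected by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .motion import (
    FlowPath,
    HeartBeat,
    Motion,
    MotionError,
    NoMotion,
    Path,
    Rotate,
    Translate,
    as_motion_list,
    displace_heartbeat,
    displace_path,
    displace_rotate,
    displace_translate,
    reset_flags_on_grid,
)

__all__ = ["Phantom", "get_spin_coords", "flow_reset_flags"]


@dataclass
class Phantom:
    """Per-spin positions, tissue parameters and a motion specification."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    T2s: np.ndarray = None
    rho: np.ndarray = None
    dw: np.ndarray = None
    motion: Union[NoMotion, Motion, list] = field(default_factory=NoMotion)
    name: str = "phantom"

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        n = self.x.size
        if n < 1:
            raise ValueError("a phantom needs at least one spin")

        def vec(v, default=None):
            if v is None:
                v = default
            a = np.asarray(v, dtype=float)
            if a.ndim == 0:
                a = np.full(n, float(a))
            if a.shape != (n,):
                raise ValueError(f"per-spin vectors must share length {n}, got {a.shape}")
            return a

        self.y = vec(self.y)
        self.z = vec(self.z)
        self.T1 = vec(self.T1)
        self.T2 = vec(self.T2)
        self.T2s = vec(self.T2s, self.T2)
        self.rho = vec(self.rho, 1.0)
        self.dw = vec(self.dw, 0.0)
        if np.any(self.T1 <= 0) or np.any(self.T2 <= 0):
            raise ValueError("T1 and T2 must be positive")
        if np.any(self.rho < 0):
            raise ValueError("proton density rho must be non-negative")
        # validate motion entries against the spin count
        for m in as_motion_list(self.motion):
            idx = m.span.resolve(n)
            if isinstance(m.action, Path) and m.action.n_spins != idx.size:
                raise MotionError(
                    f"Path displacement rows ({m.action.n_spins}) must match the "
                    f"span size ({idx.size})"
                )

    # ------------------------------------------------------------------
    @property
    def n_spins(self) -> int:
        return int(self.x.size)

    @property
    def is_static(self) -> bool:
        return len(as_motion_list(self.motion)) == 0

    @property
    def has_flow(self) -> bool:
        return any(isinstance(m.action, FlowPath) for m in as_motion_list(self.motion))

    def get_spin_coords(self, t):
        return get_spin_coords(self, t)

    def __repr__(self) -> str:
        n_motion = len(as_motion_list(self.motion))
        return f"Phantom(name={self.name!r}, n_spins={self.n_spins}, n_motions={n_motion})"


# ----------------------------------------------------------------------
def _apply_sequential(phantom: Phantom, motions, t: np.ndarray) -> np.ndarray:
    """Apply the sequential (rotation/deformation) chain at times ``t``.

    Returns positions ``(Ns, 3, Nt)``.  ``motions`` is the already-ordered
    sequential sub-list.  Reference quantities that the spec ties to the
    motion's start (rotation center of mass, heart-beat max radius) are
    computed from the chain state of the *earlier* motions evaluated at that
    start time.
    """
    ns = phantom.n_spins
    pos = np.empty((ns, 3, t.size))
    pos[:, 0, :] = phantom.x[:, None]
    pos[:, 1, :] = phantom.y[:, None]
    pos[:, 2, :] = phantom.z[:, None]
    for i, m in enumerate(motions):
        idx = m.span.resolve(ns)
        u = np.atleast_1d(m.time_curve(t))
        if isinstance(m.action, Rotate):
            center = m.action.center
            if center is None:
                ref = _apply_sequential(
                    phantom, motions[:i], np.array([m.time_curve.t_start])
                )
                center = ref[idx, :, 0].mean(axis=0)
            pos[idx] = displace_rotate(m.action, pos[idx], u, center=center)
        else:  # HeartBeat
            ref = _apply_sequential(phantom, motions[:i], np.array([m.time_curve.t_start]))
            max_r = float(np.hypot(ref[idx, 0, 0], ref[idx, 1, 0]).max())
            ux, uy, uz = displace_heartbeat(m.action, pos[idx], u, max_r=max_r)
            pos[idx, 0, :] += ux
            pos[idx, 1, :] += uy
            pos[idx, 2, :] += uz
    return pos


def get_spin_coords(phantom: Phantom, t):
    """Spin coordinates ``(xt, yt, zt)`` at the query times ``t``.

    Each returned matrix has shape ``(Ns, Nt)`` (meters).  A static phantom
    returns its initial positions broadcast over time.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    motions = as_motion_list(phantom.motion)
    ns = phantom.n_spins

    sequential = sorted(
        (m for m in motions if m.is_sequential), key=lambda m: m.time_curve.t_start
    )  # sorted() is stable: list order breaks ties
    pos = _apply_sequential(phantom, sequential, t_arr)

    for m in motions:
        if m.is_sequential:
            continue
        idx = m.span.resolve(ns)
        u = np.atleast_1d(m.time_curve(t_arr))
        if isinstance(m.action, Translate):
            ux, uy, uz = displace_translate(m.action, u)
            pos[idx, 0, :] += ux[None, :]
            pos[idx, 1, :] += uy[None, :]
            pos[idx, 2, :] += uz[None, :]
        else:  # Path / FlowPath
            dx, dy, dz = displace_path(m.action, u)
            pos[idx, 0, :] += dx
            pos[idx, 1, :] += dy
            pos[idx, 2, :] += dz
    return pos[:, 0, :], pos[:, 1, :], pos[:, 2, :]


def flow_reset_flags(phantom: Phantom, t_grid) -> np.ndarray:
    """Boolean ``(Ns, len(t_grid) - 1)`` matrix of reinjection events.

    Entry ``(s, j)`` is true when spin ``s`` traverses a ``spin_reset`` sample
    of one of its :class:`FlowPath` motions during the grid interval
    ``(t_grid[j], t_grid[j+1]]``; the Bloch engine then resets that spin to
    the unexcited state.
    """
    t_arr = np.atleast_1d(np.asarray(t_grid, dtype=float))
    flags = np.zeros((phantom.n_spins, max(t_arr.size - 1, 0)), dtype=bool)
    for m in as_motion_list(phantom.motion):
        if not isinstance(m.action, FlowPath):
            continue
        u = np.atleast_1d(m.time_curve(t_arr))
        idx = m.span.resolve(phantom.n_spins)
        local = reset_flags_on_grid(m.action, u)
        flags[idx] |= local
    return flags
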