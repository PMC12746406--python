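"""Motion actions, spin spans and displacement primitives.

A phantom's motion is specified as a list of :class:`Motion` entries, each the
combination of

* an *action* -- what moves and how (:class:`Translate`, :class:`Rotate`,
  :class:`HeartBeat` are parametric "simple" actions; :class:`Path` and
  :class:`FlowPath` carry arbitrary per-spin displacement matrices),
* a *time curve* -- when and how fast the action progresses
  (:class:`~blochflow.timecurve.TimeCurve`), and
* a *spin span* -- which spins it affects (:class:`AllSpins` or
  :class:`SpinRange`).

Composition semantics (resolved by :func:`blochflow.phantom.get_spin_coords`):
rotations and heart-beat deformations act sequentially on positions updated so
far, ordered by the start time of their time curves; translations and
path-type displacements are computed from the initial positions and summed
onto the result.

:class:`FlowPath` adds flow support: spins leaving the volume are reinjected
(the trajectory wraps) and a binary ``spin_reset`` matrix marks, per spin and
trajectory sample, the reinjection instants at which the spin's magnetization
must be reset to the unexcited state.  The spin count never changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as TySequence, Union

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .timecurve import TimeCurve

__all__ = [
    "Translate",
    "Rotate",
    "HeartBeat",
    "Path",
    "FlowPath",
    "AllSpins",
    "SpinRange",
    "Motion",
    "NoMotion",
    "MotionError",
    "displace_translate",
    "displace_rotate",
    "displace_heartbeat",
    "displace_path",
    "reset_events",
]


class MotionError(ValueError):
    """Raised for invalid motion specifications."""


# ----------------------------------------------------------------------
# Spin spans
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AllSpins:
    """Span selecting every spin of the phantom."""

    def resolve(self, n_spins: int) -> np.ndarray:
        return np.arange(n_spins)


class SpinRange:
    """Span selecting an explicit set of spins (0-based indices in memory).

    Serialized `.phantom` files store these 1-based, following the convention
    of the originating simulator ecosystem.
    """

    def __init__(self, indices):
        idx = np.unique(np.asarray(indices, dtype=np.int64).ravel())
        if idx.size == 0:
            raise MotionError("SpinRange must select at least one spin")
        if np.any(idx < 0):
            raise MotionError("SpinRange indices must be non-negative (0-based)")
        idx.setflags(write=False)
        self.indices = idx

    def resolve(self, n_spins: int) -> np.ndarray:
        if self.indices[-1] >= n_spins:
            raise MotionError(
                f"SpinRange index {self.indices[-1]} out of bounds for {n_spins} spins"
            )
        return self.indices

    def __len__(self) -> int:
        return int(self.indices.size)

    def __repr__(self) -> str:
        return f"SpinRange(n={self.indices.size})"


SpinSpan = Union[AllSpins, SpinRange]


# ----------------------------------------------------------------------
# Actions
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Translate:
    """Rigid translation by a total displacement (dx, dy, dz) in meters."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.dx, self.dy, self.dz])):
            raise MotionError("Translate displacements must be finite")


@dataclass(frozen=True)
class Rotate:
    """Rigid rotation by total angles (pitch, roll, yaw) in degrees.

    The Euler convention is intrinsic yaw (z), then pitch (y), then roll (x).
    ``center`` is the rotation center in meters; when omitted it defaults to
    the center of mass (unweighted mean) of the affected span, evaluated at
    the motion's start time.
    """

    pitch: float
    roll: float
    yaw: float
    center: Optional[tuple] = None

    def __post_init__(self):
        if not np.all(np.isfinite([self.pitch, self.roll, self.yaw])):
            raise MotionError("Rotate angles must be finite")
        if self.center is not None:
            c = tuple(float(v) for v in self.center)
            if len(c) != 3 or not np.all(np.isfinite(c)):
                raise MotionError("Rotate center must be a finite 3-vector")
            object.__setattr__(self, "center", c)


@dataclass(frozen=True)
class HeartBeat:
    """Cardiac-like contraction in cylindrical coordinates.

    With ``(r, theta, z)`` the cylindrical coordinates of the affected spins
    and ``max(r)`` their largest radius (fixed at the motion's start), the
    displacements at progress ``u`` are::

        d_circ = circumferential_strain * max(r)
        d_rad  = -radial_strain * (max(r) - r)
        d_r    = (d_circ + d_rad) * u
        ux     = d_r * cos(theta)
        uy     = d_r * sin(theta)
        uz     = longitudinal_strain * z * u

    ``theta`` at the axis (r = 0) follows the ``atan2(0, 0) = 0`` convention.
    """

    circumferential_strain: float
    radial_strain: float
    longitudinal_strain: float

    def __post_init__(self):
        if not np.all(
            np.isfinite(
                [self.circumferential_strain, self.radial_strain, self.longitudinal_strain]
            )
        ):
            raise MotionError("HeartBeat strains must be finite")


class Path:
    """Arbitrary per-spin trajectories as displacement matrices.

    ``dx, dy, dz`` have one row per spin of the span and ``Nt >= 2`` columns
    holding displacements (m) at equispaced samples of trajectory progress
    ``u in {0, 1/(Nt-1), ..., 1}``.  Evaluation at intermediate progress is
    linear interpolation between adjacent columns; progress outside ``[0, 1]``
    is clamped to the endpoints.  Velocity and traversal direction are set by
    the motion's time curve, not by the matrices.
    """

    def __init__(self, dx, dy, dz):
        dx = np.atleast_2d(np.asarray(dx, dtype=float))
        dy = np.atleast_2d(np.asarray(dy, dtype=float))
        dz = np.atleast_2d(np.asarray(dz, dtype=float))
        if not (dx.shape == dy.shape == dz.shape):
            raise MotionError("Path displacement matrices must share one shape")
        if dx.ndim != 2 or dx.shape[1] < 2:
            raise MotionError("Path matrices need at least two progress samples (Nt >= 2)")
        self.dx, self.dy, self.dz = dx, dy, dz

    @property
    def n_spins(self) -> int:
        return self.dx.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dx.shape[1]

    def __repr__(self) -> str:
        return f"{type(self).__name__}(n_spins={self.n_spins}, n_samples={self.n_samples})"


class FlowPath(Path):
    """A :class:`Path` with reinjection: ``spin_reset`` flags wrap instants.

    ``spin_reset`` is a binary matrix of the same shape as ``dx`` with a 1 in
    the progress sample at which a spin leaves the volume and is reinjected;
    the Bloch engine resets the magnetization of such spins to the unexcited
    state (Mxy = 0, Mz = equilibrium) when the trajectory traverses that
    sample.
    """

    def __init__(self, dx, dy, dz, spin_reset):
        super().__init__(dx, dy, dz)
        sr = np.atleast_2d(np.asarray(spin_reset))
        if sr.shape != self.dx.shape:
            raise MotionError("spin_reset must have the same shape as the displacement matrices")
        if not np.isin(sr, (0, 1)).all():
            raise MotionError("spin_reset entries must be 0 or 1")
        self.spin_reset = sr.astype(np.uint8)


Action = Union[Translate, Rotate, HeartBeat, Path, FlowPath]
_SEQUENTIAL_ACTIONS = (Rotate, HeartBeat)
_ADDITIVE_ACTIONS = (Translate, Path, FlowPath)


# ----------------------------------------------------------------------
# Motion entries
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class NoMotion:
    """Marker for static phantoms."""


@dataclass(frozen=True)
class Motion:
    """One motion entry: an action, a time curve and a spin span."""

    action: Action
    time_curve: TimeCurve
    span: SpinSpan = AllSpins()

    def __post_init__(self):
        if not isinstance(self.action, (Translate, Rotate, HeartBeat, Path)):
            raise MotionError(f"unknown action type {type(self.action).__name__}")
        if not isinstance(self.time_curve, TimeCurve):
            raise MotionError("time_curve must be a TimeCurve")
        if not isinstance(self.span, (AllSpins, SpinRange)):
            raise MotionError("span must be AllSpins or SpinRange")

    @property
    def is_sequential(self) -> bool:
        """Whether the action must act on updated positions (rotation/deformation)."""
        return isinstance(self.action, _SEQUENTIAL_ACTIONS)


MotionSpec = Union[NoMotion, Motion, TySequence]


def as_motion_list(motion: MotionSpec) -> list:
    """Normalize a motion field (NoMotion | Motion | list of Motion) to a list."""
    if motion is None or isinstance(motion, NoMotion):
        return []
    if isinstance(motion, Motion):
        return [motion]
    out = list(motion)
    for m in out:
        if not isinstance(m, Motion):
            raise MotionError("MotionList entries must be Motion instances")
    return out


# ----------------------------------------------------------------------
# Displacement primitives
# ----------------------------------------------------------------------
def displace_translate(action: Translate, u):
    """Translation displacement at progress ``u``: ``(dx, dy, dz) * u``.

    Returns three arrays shaped like ``u`` (identical for every spin in the
    span).
    """
    u = np.asarray(u, dtype=float)
    return action.dx * u, action.dy * u, action.dz * u


def _euler_matrices(action: Rotate, u):
    """Stack of rotation matrices at each progress value (intrinsic z-y-x)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    angles = np.column_stack([action.yaw * u, action.pitch * u, action.roll * u])
    return _Rotation.from_euler("ZYX", angles, degrees=True).as_matrix()


def displace_rotate(action: Rotate, positions, u, center=None):
    """Rotate ``positions`` about ``center`` by the action's angles scaled by ``u``.

    Parameters
    ----------
    positions:
        Array ``(n, 3)`` of current coordinates (m), or ``(n, 3, Nt)`` with a
        trailing time axis matching ``u``.
    u:
        Scalar progress or vector of length ``Nt``.
    center:
        Rotation center; defaults to ``action.center`` and, failing that, the
        unweighted mean of ``positions`` (their first time column).

    Returns the rotated coordinates with the input shape.  Distances to the
    center are preserved (orthogonal map).
    """
    pos = np.asarray(positions, dtype=float)
    squeeze_time = pos.ndim == 2
    if squeeze_time:
        pos = pos[:, :, None]
    if pos.shape[0] == 0:
        raise MotionError("cannot rotate an empty span")
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if u_arr.size not in (1, pos.shape[2]):
        raise MotionError("u must be scalar or match the number of time columns")
    if center is None:
        center = action.center
    if center is None:
        center = pos[:, :, 0].mean(axis=0)
    c = np.asarray(center, dtype=float).reshape(1, 3, 1)
    mats = _euler_matrices(action, u_arr if u_arr.size == pos.shape[2] else np.full(pos.shape[2], u_arr[0]))
    rel = pos - c
    rotated = np.einsum("tab,nbt->nat", mats, rel) + c
    # zero progress must reproduce the input bit-exactly (no center round trip)
    u_cols = u_arr if u_arr.size == pos.shape[2] else np.full(pos.shape[2], u_arr[0])
    still = u_cols == 0.0
    if still.any():
        rotated[:, :, still] = pos[:, :, still]
    return rotated[:, :, 0] if squeeze_time else rotated


def displace_heartbeat(action: HeartBeat, positions, u, max_r=None):
    """Heart-beat displacement triplets for the span's current ``positions``.

    ``positions`` is ``(n, 3)`` or ``(n, 3, Nt)``; ``u`` a scalar or length-Nt
    vector.  ``max_r`` is the reference maximal radius of the span; when
    omitted it is taken from the supplied positions (first time column).
    Returns ``(ux, uy, uz)`` displacement arrays of shape ``(n,)`` or
    ``(n, Nt)``.
    """
    pos = np.asarray(positions, dtype=float)
    squeeze_time = pos.ndim == 2
    if squeeze_time:
        pos = pos[:, :, None]
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    x, y, z = pos[:, 0, :], pos[:, 1, :], pos[:, 2, :]
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    if max_r is None:
        max_r = float(r[:, 0].max()) if r.size else 0.0
    d_circ = action.circumferential_strain * max_r
    d_rad = -action.radial_strain * (max_r - r)
    d_r = (d_circ + d_rad) * u_arr[None, :]
    ux = d_r * np.cos(theta)
    uy = d_r * np.sin(theta)
    uz = action.longitudinal_strain * z * u_arr[None, :]
    if squeeze_time:
        return ux[:, 0], uy[:, 0], uz[:, 0]
    return ux, uy, uz


def displace_path(action: Path, u):
    """Per-spin displacement triplets at progress ``u`` (linear interpolation).

    ``u`` outside ``[0, 1]`` is clamped to the endpoints (flat extrapolation,
    mirroring the time-curve behavior).  Returns three ``(n_spins, Nu)``
    arrays (``(n_spins,)`` for scalar ``u``).
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    scalar = np.asarray(u).ndim == 0
    nt = action.n_samples
    s = np.clip(u_arr, 0.0, 1.0) * (nt - 1)
    k = np.minimum(s.astype(np.int64), nt - 2)
    f = s - k
    out = []
    for mat in (action.dx, action.dy, action.dz):
        d = mat[:, k] * (1.0 - f) + mat[:, k + 1] * f
        out.append(d[:, 0] if scalar else d)
    return tuple(out)


def reset_events(action: FlowPath, u_prev: float, u_now: float) -> np.ndarray:
    """Per-spin reset flags for the traversed progress interval ``(u_prev, u_now]``.

    A spin is flagged iff its ``spin_reset`` row holds a 1 in a column whose
    progress sample lies in the traversed interval.  When ``u_now < u_prev``
    (periodic wrap of a forward-traversed curve) the interval is taken as
    ``(u_prev, 1] U [0, u_now]``.
    """
    if not isinstance(action, FlowPath):
        raise MotionError("reset_events requires a FlowPath action")
    nt = action.n_samples
    samples = np.arange(nt) / (nt - 1)
    if u_now >= u_prev:
        cols = (samples > u_prev) & (samples <= u_now)
    else:
        cols = (samples > u_prev) | (samples <= u_now)
    return (action.spin_reset[:, cols] == 1).any(axis=1)


def reset_flags_on_grid(action: FlowPath, u_grid: np.ndarray) -> np.ndarray:
    """Vectorized :func:`reset_events` over consecutive progress samples.

    ``u_grid`` holds the motion's progress at the simulation grid nodes
    (length ``Ng``); returns a boolean ``(n_spins, Ng - 1)`` matrix flagging,
    per grid interval, the spins whose reset sample is traversed.
    """
    u = np.asarray(u_grid, dtype=float)
    n_int = u.size - 1
    flags = np.zeros((action.n_spins, n_int), dtype=bool)
    rows, cols = np.nonzero(action.spin_reset)
    if rows.size == 0 or n_int <= 0:
        return flags
    ue = cols / (action.n_samples - 1)  # progress of each reset entry
    a, b = u[:-1], u[1:]
    fwd = b >= a
    # (entries x intervals) traversal test; entry counts are small (one or a
    # few wraps per spin) so the dense broadcast stays cheap.
    hit = np.where(
        fwd[None, :],
        (ue[:, None] > a[None, :]) & (ue[:, None] <= b[None, :]),
        (ue[:, None] > a[None, :]) | (ue[:, None] <= b[None, :]),
    )
    np.logical_or.at(flags, rows, hit)
    return flags
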