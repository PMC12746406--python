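"""Piecewise-linear animation time curves.

A :class:`TimeCurve` maps absolute simulation time ``t`` (seconds) to a
normalized trajectory progress ``u`` (conventionally in ``[0, 1]``, where 0 is
the start of a trajectory and 1 its end).  The mapping is the piecewise-linear
interpolation of user-supplied nodes, optionally extended beyond the base
interval:

* ``periodic=False`` -- flat extrapolation: before the pattern the curve holds
  its first node value, after it the value at the end of the last repetition.
* ``periodic=True`` -- the whole pattern repeats indefinitely.
* ``periods`` -- a vector of positive scale factors producing a
  *pseudo-periodic* extension with time warping: repetition ``i`` of the base
  curve is stretched to last ``periods[i] * D`` seconds (``D`` is the base
  duration), and repetitions are placed back to back.  ``periods=[1]`` is the
  plain curve.

These curves play the role of animation curves in animation software: the same
node pattern can drive a translation, a rotation, a cardiac contraction or the
traversal of an arbitrary per-spin trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeCurve", "TimeCurveError", "time_range", "unit_time"]

# Relative tolerance used to snap evaluations sitting a hair past a period
# boundary back onto it (guards floating-point modulo at boundaries).
_BOUNDARY_RTOL = 1e-12


class TimeCurveError(ValueError):
    """Raised for invalid time-curve definitions."""


@dataclass(frozen=True, eq=False)
class TimeCurve:
    """Node-based mapping from absolute time to normalized progress.

    Parameters
    ----------
    t_nodes:
        Strictly increasing absolute times of the nodes (s); at least two.
    u_nodes:
        Normalized progress value at each node (dimensionless).  Values
        outside ``[0, 1]`` are permitted (overshoot), though the built-in
        generators only emit values inside the unit interval.
    periodic:
        If true, the (possibly warped) pattern repeats indefinitely.
    periods:
        Positive scale factors for the pseudo-periodic extension.
    """

    t_nodes: np.ndarray
    u_nodes: np.ndarray
    periodic: bool = False
    periods: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.t_nodes, dtype=float))
        u = np.atleast_1d(np.asarray(self.u_nodes, dtype=float))
        p = np.atleast_1d(np.asarray(self.periods, dtype=float))
        if t.ndim != 1 or u.ndim != 1 or t.size != u.size or t.size < 2:
            raise TimeCurveError(
                "t_nodes and u_nodes must be 1-D, equal length and hold at "
                f"least two nodes (got {t.size} and {u.size})"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(u)):
            raise TimeCurveError("time-curve nodes must be finite")
        if np.any(np.diff(t) <= 0):
            raise TimeCurveError("t_nodes must be strictly increasing")
        if p.ndim != 1 or p.size < 1 or np.any(~np.isfinite(p)) or np.any(p <= 0):
            raise TimeCurveError("periods must be a vector of positive scale factors")
        t.setflags(write=False)
        u.setflags(write=False)
        p.setflags(write=False)
        object.__setattr__(self, "t_nodes", t)
        object.__setattr__(self, "u_nodes", u)
        object.__setattr__(self, "periodic", bool(self.periodic))
        object.__setattr__(self, "periods", p)

    # ------------------------------------------------------------------
    @property
    def duration(self) -> float:
        """Base duration ``D`` of the node pattern (s)."""
        return float(self.t_nodes[-1] - self.t_nodes[0])

    @property
    def pattern_duration(self) -> float:
        """Total duration of one full pseudo-periodic pattern, ``D * sum(periods)``."""
        return self.duration * float(np.sum(self.periods))

    @property
    def t_start(self) -> float:
        """Absolute time at which the pattern begins (first node)."""
        return float(self.t_nodes[0])

    def __call__(self, t):
        return unit_time(t, self)

    def __repr__(self) -> str:  # compact, node counts only
        return (
            f"TimeCurve(n_nodes={self.t_nodes.size}, t=[{self.t_nodes[0]:g}, "
            f"{self.t_nodes[-1]:g}] s, periodic={self.periodic}, "
            f"periods={np.array2string(self.periods, precision=3)})"
        )


def time_range(t_start: float, t_end: float, *, periodic: bool = False) -> TimeCurve:
    """Identity-mapping curve: progress ramps linearly from 0 at ``t_start`` to 1 at ``t_end``."""
    return TimeCurve(np.array([t_start, t_end]), np.array([0.0, 1.0]), periodic=periodic)


def unit_time(t, curve: TimeCurve):
    """Evaluate a :class:`TimeCurve` at the query times ``t``.

    Returns an array with the shape of ``t`` (a scalar input returns a 0-d
    float).  Within one repetition the output is the piecewise-linear
    interpolation of the nodes evaluated at the proportionally rescaled local
    time; evaluation exactly at a node takes the node value.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    tq = np.atleast_1d(t_arr)

    D = curve.duration
    p = curve.periods
    bounds = D * np.concatenate(([0.0], np.cumsum(p)))  # repetition boundaries
    t_pattern = bounds[-1]
    tol = _BOUNDARY_RTOL * D

    tau = tq - curve.t_nodes[0]
    out = np.empty_like(tau)

    if curve.periodic:
        tau = np.mod(tau, t_pattern)
        # snap values a hair below the upper boundary onto the pattern start
        tau = np.where(t_pattern - tau < tol, 0.0, tau)
        before = np.zeros(tau.shape, dtype=bool)
        after = np.zeros(tau.shape, dtype=bool)
    else:
        before = tau < 0.0
        after = tau > t_pattern
        out[before] = curve.u_nodes[0]
        out[after] = curve.u_nodes[-1]

    mid = ~(before | after)
    if np.any(mid):
        tm = tau[mid]
        # an exact internal repetition boundary takes the value of the ending
        # repetition (left-continuous); the pattern start itself maps to rep 0
        rep = np.clip(np.searchsorted(bounds, tm, side="left") - 1, 0, p.size - 1)
        local = (tm - bounds[rep]) / p[rep]  # rescaled to [0, D]
        out[mid] = np.interp(local, curve.t_nodes - curve.t_nodes[0], curve.u_nodes)

    return float(out[0]) if scalar else out
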