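"""Synthetic phantom generators for flow and motion experiments.

All generators take explicit seeds (where they sample positions) and return
fully specified :class:`~blochflow.phantom.Phantom` objects.  Flowing phantoms
implement flow with a :class:`~blochflow.motion.FlowPath`: per-spin axial
trajectories that wrap around at the tube ends (reinjection), with the
``spin_reset`` matrix marking each wrap so the Bloch engine resets the
reinjected spin to the unexcited state.

Default tissue parameters are blood-like (T1 = 1.2 s, T2 = 0.1 s) unless
stated otherwise.
"""

from __future__ import annotations

import numpy as np

from .motion import FlowPath, HeartBeat, Motion, Path, SpinRange
from .phantom import Phantom
from .timecurve import TimeCurve, time_range

__all__ = [
    "make_cylinder_flow_phantom",
    "make_1d_flow_segment",
    "make_two_tube_phantom",
    "make_heartbeat_annulus",
]


def _wrap_interval(z, length):
    """Wrap coordinates into [-length/2, length/2)."""
    return np.mod(z + 0.5 * length, length) - 0.5 * length


def _axial_flow_path(z0, velocities, length, duration, n_samples):
    """FlowPath matrices for axial flow with wrap-around reinjection.

    ``z0``: initial axial positions; ``velocities``: per-spin axial velocity
    (m/s, may be negative); trajectories sampled at ``n_samples`` equispaced
    progress points spanning ``duration`` seconds.  Returns a FlowPath whose
    ``spin_reset`` holds a 1 in every column at which a spin wrapped.
    """
    t_k = np.linspace(0.0, duration, n_samples)
    z_unwrapped = z0[:, None] + velocities[:, None] * t_k[None, :]
    z_wrapped = _wrap_interval(z_unwrapped, length)
    dz = z_wrapped - z0[:, None]
    # wrap count changes exactly where a spin left the tube and was reinjected
    n_wraps = np.round((z_unwrapped - z_wrapped) / length).astype(np.int64)
    reset = np.zeros_like(dz, dtype=np.uint8)
    reset[:, 1:] = (np.diff(n_wraps, axis=1) != 0).astype(np.uint8)
    zeros = np.zeros_like(dz)
    return FlowPath(zeros, zeros.copy(), dz, reset)


def _cylinder_positions(rng, n, radius, length):
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    z = rng.uniform(-0.5 * length, 0.5 * length, size=n)
    return r * np.cos(phi), r * np.sin(phi), z


def make_cylinder_flow_phantom(
    radius: float,
    length: float,
    vz: float,
    spin_density: float,
    seed: int = 0,
    n_path_samples: int = 64,
    T1: float = 1.2,
    T2: float = 0.1,
) -> Phantom:
    """Vertical cylinder with continuous plug flow in +z and reinjection.

    The cylinder is aligned with the z axis and filled with
    ``spin_density * volume`` uniformly seeded spins, all moving at ``vz``
    (m/s).  The time curve is periodic with period ``length / vz`` so the
    cylinder length is traversed in exactly one period, and spins reaching the
    upper boundary are reinjected at the bottom (``spin_reset`` wrap marks).
    """
    if radius <= 0 or length <= 0 or spin_density <= 0:
        raise ValueError("radius, length and spin_density must be positive")
    if vz <= 0:
        raise ValueError("plug-flow velocity must be positive (periodic reinjection)")
    rng = np.random.default_rng(seed)
    n = max(int(round(spin_density * np.pi * radius**2 * length)), 1)
    x, y, z = _cylinder_positions(rng, n, radius, length)
    period = length / vz
    path = _axial_flow_path(z, np.full(n, vz), length, period, n_path_samples)
    motion = Motion(
        action=path, time_curve=time_range(0.0, period, periodic=True)
    )
    return Phantom(
        x=x, y=y, z=z, T1=T1, T2=T2, rho=1.0, motion=motion, name="cylinder-flow"
    )


def make_1d_flow_segment(
    n_spins: int,
    velocities,
    z_min: float = -0.02,
    z_max: float = 0.02,
    duration: float = 0.01,
    T1: float = 1.0,
    T2: float = 0.1,
) -> list:
    """One phantom per velocity: evenly spaced spins on a z segment, constant axial velocity.

    Motion is a plain :class:`~blochflow.motion.Path` (no reinjection) whose
    linear two-sample trajectory, traversed by an identity time curve over
    ``duration``, reproduces constant-velocity motion exactly.  ``v = 0``
    yields a static trajectory.
    """
    if n_spins < 1:
        raise ValueError("need at least one spin")
    z = np.linspace(z_min, z_max, n_spins)
    phantoms = []
    for v in np.atleast_1d(np.asarray(velocities, dtype=float)):
        zeros = np.zeros((n_spins, 2))
        dz = np.column_stack([np.zeros(n_spins), np.full(n_spins, v * duration)])
        motion = Motion(action=Path(zeros, zeros.copy(), dz), time_curve=time_range(0.0, duration))
        phantoms.append(
            Phantom(
                x=np.zeros(n_spins), y=np.zeros(n_spins), z=z,
                T1=T1, T2=T2, rho=1.0, motion=motion,
                name=f"segment-v{v:g}",
            )
        )
    return phantoms


def make_two_tube_phantom(
    radius: float = 0.008,
    length: float = 0.03,
    vmax: float = 0.25,
    static_shell: bool = True,
    seed: int = 0,
    tube_separation: float = 0.024,
    n_spins_per_tube: int = 4000,
    n_shell_spins: int = 3000,
    duration: float = 1.0,
    n_path_samples: int = 400,
    profile: str = "poiseuille",
    T1: float = 1.2,
    T2: float = 0.1,
) -> Phantom:
    """Two parallel tubes along z with opposite flow; one optionally in static tissue.

    Tube centers sit at ``x = +/- tube_separation / 2``.  ``profile`` selects
    the axial velocity profile: ``"poiseuille"`` gives
    ``v(r) = vmax * (1 - r^2 / R^2)`` (laminar pipe flow, mean speed
    ``vmax / 2`` over the cross-section) and ``"plug"`` a uniform ``vmax``.
    The +x tube flows in +z, the -x tube in -z.  The static shell is an
    annulus around the +x tube.  Flow uses FlowPath wrap-around reinjection
    over a non-periodic time curve spanning ``duration`` seconds.
    """
    if tube_separation < 2.0 * radius:
        raise ValueError("tubes overlap: tube_separation must be at least 2 * radius")
    if profile not in ("poiseuille", "plug"):
        raise ValueError("profile must be 'poiseuille' or 'plug'")
    rng = np.random.default_rng(seed)
    xs, ys, zs, vs = [], [], [], []
    for sign, xc in ((+1.0, +0.5 * tube_separation), (-1.0, -0.5 * tube_separation)):
        x, y, z = _cylinder_positions(rng, n_spins_per_tube, radius, length)
        r = np.hypot(x, y)
        if profile == "poiseuille":
            v = sign * vmax * (1.0 - (r / radius) ** 2)
        else:
            v = np.full(n_spins_per_tube, sign * vmax)
        xs.append(x + xc)
        ys.append(y)
        zs.append(z)
        vs.append(v)
    n_flow = 2 * n_spins_per_tube
    if static_shell:
        shell_outer = 1.8 * radius
        rr = np.sqrt(rng.uniform(radius**2, shell_outer**2, size=n_shell_spins))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_shell_spins)
        xs.append(rr * np.cos(phi) + 0.5 * tube_separation)
        ys.append(rr * np.sin(phi))
        zs.append(rng.uniform(-0.5 * length, 0.5 * length, size=n_shell_spins))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    z = np.concatenate(zs)
    path = _axial_flow_path(
        np.concatenate(zs[:2]), np.concatenate(vs), length, duration, n_path_samples
    )
    motion = Motion(
        action=path,
        time_curve=time_range(0.0, duration),
        span=SpinRange(np.arange(n_flow)),
    )
    return Phantom(x=x, y=y, z=z, T1=T1, T2=T2, rho=1.0, motion=motion, name="two-tube")


def make_heartbeat_annulus(
    r_in: float = 0.02,
    r_out: float = 0.035,
    strains=( -0.2, 0.3, 0.0),
    period: float = 1.0,
    n_spins: int = 2000,
    seed: int = 0,
    systole_fraction: float = 0.3,
    T1: float = 1.0,
    T2: float = 0.05,
) -> Phantom:
    """Annular (myocardium-like) phantom contracting with a HeartBeat action.

    ``strains`` is ``(circumferential, radial, longitudinal)``.  The periodic
    time curve rises to full contraction in ``systole_fraction * period``
    (systole) and relaxes back over the rest of the cycle (diastole), an
    asymmetric cardiac-like profile.
    """
    if not (0.0 < r_in < r_out):
        raise ValueError("need 0 < r_in < r_out")
    if not (0.0 < systole_fraction < 1.0):
        raise ValueError("systole_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n_spins))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_spins)
    curve = TimeCurve(
        np.array([0.0, systole_fraction * period, period]),
        np.array([0.0, 1.0, 0.0]),
        periodic=True,
    )
    cs, rs, ls = strains
    motion = Motion(
        action=HeartBeat(
            circumferential_strain=cs, radial_strain=rs, longitudinal_strain=ls
        ),
        time_curve=curve,
    )
    return Phantom(
        x=r * np.cos(phi), y=r * np.sin(phi), z=np.zeros(n_spins),
        T1=T1, T2=T2, rho=1.0, motion=motion, name="heartbeat-annulus",
    )
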