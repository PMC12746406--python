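"""Reader/writer for the ``.phantom`` HDF5 phantom file format.

The format stores everything needed to reconstruct a dynamic digital phantom:
spin positions, contrast parameters, off-resonance and the full motion
specification, so that phantoms can be shared across simulators.

Layout (all arrays float64, SI units, except the binary ``spin_reset``)::

    /                 attrs: Version, Name, Ns, Dims
    /position         datasets: x, y, z                     [m]
    /contrast         datasets: T1, T2, T2s, rho, Dw        [s, s, s, a.u., rad/s]
    /motion           absent for a static phantom; else one subgroup per entry
      /motion_<i>     attr: type in {Translate, Rotate, HeartBeat, Path, FlowPath}
                      parameter datasets (see the action classes)
        /time         datasets: t, t_unit, periodic, periods
        /spins        attr: type in {AllSpins, SpinRange};
                      dataset indices (1-based, sorted) for SpinRange

The reader is permissive where it can be: unknown extra groups are ignored
with a logged warning, scalar ``periods`` are promoted to vectors, and a
``{first, last}`` interval shorthand is accepted for spin spans.  Structural
problems (missing mandatory datasets, shape mismatches, violated invariants)
raise :class:`PhantomFormatError` naming the offending HDF5 path.
"""

from __future__ import annotations

import logging

import h5py
import numpy as np

from .motion import (
    AllSpins,
    FlowPath,
    HeartBeat,
    Motion,
    MotionError,
    NoMotion,
    Path,
    Rotate,
    SpinRange,
    Translate,
    as_motion_list,
)
from .phantom import Phantom
from .timecurve import TimeCurve, TimeCurveError

__all__ = ["write_phantom", "read_phantom", "PhantomFormatError", "FORMAT_VERSION"]

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"

_KNOWN_ROOT = {"position", "contrast", "motion"}
_ACTION_NAMES = {
    Translate: "Translate",
    Rotate: "Rotate",
    HeartBeat: "HeartBeat",
    FlowPath: "FlowPath",  # checked before Path (subclass)
    Path: "Path",
}
# chunking for large trajectory matrices
_CHUNK_ROWS = 4096
_CHUNK_COLS = 64


class PhantomFormatError(ValueError):
    """Raised when a ``.phantom`` file is missing data or violates invariants."""


# ----------------------------------------------------------------------
# Writing
# ----------------------------------------------------------------------
def _write_matrix(grp, name, mat, dtype="f8"):
    mat = np.asarray(mat)
    chunks = (min(mat.shape[0], _CHUNK_ROWS), min(mat.shape[1], _CHUNK_COLS))
    grp.create_dataset(name, data=mat, dtype=dtype, chunks=chunks, compression="gzip")


def _action_name(action) -> str:
    for cls, name in _ACTION_NAMES.items():
        if isinstance(action, cls):
            return name
    raise MotionError(f"unknown action type {type(action).__name__}")


def _write_motion_entry(grp, motion: Motion) -> None:
    a = motion.action
    grp.attrs["type"] = _action_name(a)
    if isinstance(a, Translate):
        for k in ("dx", "dy", "dz"):
            grp.create_dataset(k, data=float(getattr(a, k)), dtype="f8")
    elif isinstance(a, Rotate):
        for k in ("pitch", "roll", "yaw"):
            grp.create_dataset(k, data=float(getattr(a, k)), dtype="f8")
        if a.center is not None:
            grp.create_dataset("center", data=np.asarray(a.center, dtype=float), dtype="f8")
    elif isinstance(a, HeartBeat):
        for k in ("circumferential_strain", "radial_strain", "longitudinal_strain"):
            grp.create_dataset(k, data=float(getattr(a, k)), dtype="f8")
    else:  # Path / FlowPath
        _write_matrix(grp, "dx", a.dx)
        _write_matrix(grp, "dy", a.dy)
        _write_matrix(grp, "dz", a.dz)
        if isinstance(a, FlowPath):
            _write_matrix(grp, "spin_reset", a.spin_reset, dtype="u1")

    tgrp = grp.create_group("time")
    tc = motion.time_curve
    tgrp.create_dataset("t", data=tc.t_nodes, dtype="f8")
    tgrp.create_dataset("t_unit", data=tc.u_nodes, dtype="f8")
    tgrp.create_dataset("periodic", data=np.uint8(tc.periodic), dtype="u1")
    tgrp.create_dataset("periods", data=tc.periods, dtype="f8")

    sgrp = grp.create_group("spins")
    if isinstance(motion.span, AllSpins):
        sgrp.attrs["type"] = "AllSpins"
    else:
        sgrp.attrs["type"] = "SpinRange"
        # 1-based on disk, matching the originating ecosystem's convention
        sgrp.create_dataset("indices", data=motion.span.indices + 1, dtype="i8")


def write_phantom(phantom: Phantom, path) -> None:
    """Write ``phantom`` to ``path`` in the ``.phantom`` HDF5 layout."""
    motions = as_motion_list(phantom.motion)
    with h5py.File(path, "w") as f:
        f.attrs["Version"] = FORMAT_VERSION
        f.attrs["Name"] = phantom.name
        f.attrs["Ns"] = phantom.n_spins
        f.attrs["Dims"] = 3
        pos = f.create_group("position")
        for k in ("x", "y", "z"):
            pos.create_dataset(k, data=getattr(phantom, k), dtype="f8")
        con = f.create_group("contrast")
        for k, attr in (("T1", "T1"), ("T2", "T2"), ("T2s", "T2s"), ("rho", "rho"), ("Dw", "dw")):
            con.create_dataset(k, data=getattr(phantom, attr), dtype="f8")
        if motions:
            mg = f.create_group("motion")
            for i, m in enumerate(motions, start=1):
                _write_motion_entry(mg.create_group(f"motion_{i}"), m)


# ----------------------------------------------------------------------
# Reading
# ----------------------------------------------------------------------
def _require(node, key, kind="dataset"):
    if key not in node:
        raise PhantomFormatError(f"missing mandatory {kind} '{node.name}/{key}'")
    return node[key]


def _read_vec(node, key, n):
    data = np.asarray(_require(node, key)[()], dtype=float).ravel()
    if data.size != n:
        raise PhantomFormatError(
            f"dataset '{node.name}/{key}' has length {data.size}, expected Ns = {n}"
        )
    return data


def _read_scalar(node, key) -> float:
    return float(np.asarray(_require(node, key)[()]).ravel()[0])


def _read_time_curve(grp) -> TimeCurve:
    tgrp = _require(grp, "time", kind="group")
    t = np.asarray(_require(tgrp, "t")[()], dtype=float).ravel()
    u = np.asarray(_require(tgrp, "t_unit")[()], dtype=float).ravel()
    periodic = bool(np.asarray(_require(tgrp, "periodic")[()]).ravel()[0])
    periods = np.asarray(_require(tgrp, "periods")[()], dtype=float).ravel()
    if periods.size == 0:
        periods = np.array([1.0])
    try:
        return TimeCurve(t, u, periodic=periodic, periods=periods)
    except TimeCurveError as exc:
        raise PhantomFormatError(f"invalid time curve at '{tgrp.name}': {exc}") from exc


def _read_span(grp):
    sgrp = _require(grp, "spins", kind="group")
    kind = sgrp.attrs.get("type", "AllSpins")
    if isinstance(kind, bytes):
        kind = kind.decode()
    if kind == "AllSpins":
        return AllSpins()
    if kind != "SpinRange":
        raise PhantomFormatError(f"unknown spin-span type '{kind}' at '{sgrp.name}'")
    if "indices" in sgrp:
        idx = np.asarray(sgrp["indices"][()], dtype=np.int64).ravel()
    elif "first" in sgrp and "last" in sgrp:  # interval shorthand
        first = int(np.asarray(sgrp["first"][()]).ravel()[0])
        last = int(np.asarray(sgrp["last"][()]).ravel()[0])
        idx = np.arange(first, last + 1, dtype=np.int64)
    else:
        raise PhantomFormatError(f"missing mandatory dataset '{sgrp.name}/indices'")
    if idx.size == 0 or np.any(idx < 1):
        raise PhantomFormatError(f"invalid 1-based spin indices at '{sgrp.name}/indices'")
    try:
        return SpinRange(idx - 1)
    except MotionError as exc:
        raise PhantomFormatError(f"invalid spin span at '{sgrp.name}': {exc}") from exc


def _read_motion_entry(grp, n_spins: int) -> Motion:
    kind = grp.attrs.get("type")
    if isinstance(kind, bytes):
        kind = kind.decode()
    span = _read_span(grp)
    curve = _read_time_curve(grp)
    try:
        if kind == "Translate":
            action = Translate(
                _read_scalar(grp, "dx"), _read_scalar(grp, "dy"), _read_scalar(grp, "dz")
            )
        elif kind == "Rotate":
            center = None
            if "center" in grp:
                center = tuple(np.asarray(grp["center"][()], dtype=float).ravel())
            action = Rotate(
                _read_scalar(grp, "pitch"),
                _read_scalar(grp, "roll"),
                _read_scalar(grp, "yaw"),
                center=center,
            )
        elif kind == "HeartBeat":
            action = HeartBeat(
                _read_scalar(grp, "circumferential_strain"),
                _read_scalar(grp, "radial_strain"),
                _read_scalar(grp, "longitudinal_strain"),
            )
        elif kind in ("Path", "FlowPath"):
            dx = np.atleast_2d(np.asarray(_require(grp, "dx")[()], dtype=float))
            dy = np.atleast_2d(np.asarray(_require(grp, "dy")[()], dtype=float))
            dz = np.atleast_2d(np.asarray(_require(grp, "dz")[()], dtype=float))
            if kind == "FlowPath":
                sr = np.atleast_2d(np.asarray(_require(grp, "spin_reset")[()]))
                action = FlowPath(dx, dy, dz, sr)
            else:
                action = Path(dx, dy, dz)
        else:
            raise PhantomFormatError(f"unknown action type '{kind}' at '{grp.name}'")
        motion = Motion(action=action, time_curve=curve, span=span)
    except MotionError as exc:
        raise PhantomFormatError(f"invalid motion entry at '{grp.name}': {exc}") from exc
    # shape-vs-span consistency (Phantom revalidates, but fail with the path here)
    idx = motion.span.resolve(n_spins) if not isinstance(span, AllSpins) else np.arange(n_spins)
    if isinstance(motion.action, Path) and motion.action.n_spins != idx.size:
        raise PhantomFormatError(
            f"displacement matrices at '{grp.name}' have {motion.action.n_spins} rows "
            f"but the span selects {idx.size} spins"
        )
    return motion


def read_phantom(path) -> Phantom:
    """Read a ``.phantom`` file and reconstruct the :class:`Phantom`."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise PhantomFormatError(f"cannot open '{path}' as an HDF5 file: {exc}") from exc
    with f:
        version = f.attrs.get("Version")
        if isinstance(version, bytes):
            version = version.decode()
        if version is None:
            raise PhantomFormatError("missing mandatory root attribute 'Version'")
        if str(version).split(".")[0] != FORMAT_VERSION.split(".")[0]:
            raise PhantomFormatError(f"unsupported phantom format version '{version}'")
        name = f.attrs.get("Name", "phantom")
        if isinstance(name, bytes):
            name = name.decode()
        ns = int(f.attrs.get("Ns", 0))
        pos = _require(f, "position", kind="group")
        if ns == 0:
            ns = int(np.asarray(pos["x"][()]).size) if "x" in pos else 0
        x = _read_vec(pos, "x", ns)
        y = _read_vec(pos, "y", ns)
        z = _read_vec(pos, "z", ns)
        con = _require(f, "contrast", kind="group")
        t1 = _read_vec(con, "T1", ns)
        t2 = _read_vec(con, "T2", ns)
        t2s = _read_vec(con, "T2s", ns) if "T2s" in con else None
        rho = _read_vec(con, "rho", ns) if "rho" in con else None
        dwv = _read_vec(con, "Dw", ns) if "Dw" in con else None

        for key in f.keys():
            if key not in _KNOWN_ROOT:
                logger.warning("ignoring unknown group '/%s' in %s", key, path)

        motion = NoMotion()
        if "motion" in f:
            mg = f["motion"]
            names = sorted(mg.keys(), key=lambda s: int(s.rsplit("_", 1)[-1]))
            entries = [_read_motion_entry(mg[n], ns) for n in names]
            motion = entries[0] if len(entries) == 1 else entries

        try:
            return Phantom(
                x=x, y=y, z=z, T1=t1, T2=t2, T2s=t2s, rho=rho, dw=dwv,
                motion=motion, name=str(name),
            )
        except (ValueError, MotionError) as exc:
            raise PhantomFormatError(f"inconsistent phantom data in '{path}': {exc}") from exc
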