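"""Cartesian reconstruction and phase-contrast velocity mapping.

The raw signal of a Cartesian acquisition is reshaped into a k-space matrix
(one row per phase-encode line) and inverse-Fourier transformed.  With the
builder conventions (``k = gamma * int G dt`` rad/m, signal
``S = sum rho exp(-i k . r)``), image pixel ``(i, j)`` of an ``n x n`` frame
maps to the spatial position ``y_i = (i - n/2) * FOV / n``,
``x_j = (j - n/2) * FOV / n``.

Phase-contrast velocimetry: a pair of acquisitions with toggled bipolar
gradients whose first moments differ by ``M1 = pi / (gamma * venc)`` encodes
velocity into the phase difference ``dphi = angle(I+ conj(I-))``, so
``v = venc * dphi / pi`` -- a spin at ``v = venc`` shows ``dphi = pi``, and
faster flow aliases (wraps) across ``+/- venc``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import GAMMA
from .engine import RawSignal

__all__ = ["VelocityEncoding", "ImagePair", "recon_cartesian", "velocity_map"]


@dataclass(frozen=True)
class VelocityEncoding:
    """Velocity-encoding settings: VENC (m/s) and encoding direction."""

    venc: float
    direction: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if d.shape != (3,) or norm == 0 or not np.all(np.isfinite(d)):
            raise ValueError("direction must be a finite, nonzero 3-vector")
        object.__setattr__(self, "direction", tuple(d / norm))

    @property
    def m1(self) -> float:
        """First-moment difference between the toggled acquisitions (T s^2 / m)."""
        return np.pi / (GAMMA * self.venc)


@dataclass
class ImagePair:
    """Complex images from the two toggled-bipolar acquisitions."""

    plus: np.ndarray
    minus: np.ndarray
    pixel_size: Optional[float] = None
    plane: str = "xy"

    def __post_init__(self):
        self.plus = np.asarray(self.plus)
        self.minus = np.asarray(self.minus)
        if self.plus.shape != self.minus.shape:
            raise ValueError("the two images of a pair must share one shape")


def recon_cartesian(raw: RawSignal, n_matrix: int, line_signs: bool = False) -> np.ndarray:
    """Reconstruct a square Cartesian frame from a raw signal.

    ``raw`` must hold exactly ``n_matrix**2`` samples, ordered line by line
    from ``ky = -k_max``.  With ``line_signs=True`` every other line is
    negated before the transform (bSSFP 0/180 RF phase alternation).
    Returns the complex image, centered (DC pixel at index ``n/2``).
    """
    n = int(n_matrix)
    if raw.n != n * n:
        raise ValueError(f"raw signal holds {raw.n} samples, expected {n * n}")
    k = np.asarray(raw.samples, dtype=complex).reshape(n, n).copy()
    if line_signs:
        k[1::2] *= -1.0
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k)))


def pixel_coords(n_matrix: int, fov: float):
    """Pixel-center coordinates ``(y_grid, x_grid)`` of a reconstructed frame (m)."""
    c = (np.arange(n_matrix) - n_matrix / 2.0) * fov / n_matrix
    return np.meshgrid(c, c, indexing="ij")


def velocity_map(pair: ImagePair, enc: VelocityEncoding, mask_threshold: float = 0.1):
    """Velocity image (m/s) and magnitude image from a phase-contrast pair.

    ``dphi = angle(I+ conj(I-))``; ``v = venc * dphi / pi``.  Pixels whose
    magnitude falls below ``mask_threshold`` times the 99th-percentile
    magnitude are treated as background and set to zero velocity.
    """
    mag = 0.5 * (np.abs(pair.plus) + np.abs(pair.minus))
    dphi = np.angle(pair.plus * np.conj(pair.minus))
    vel = enc.venc * dphi / np.pi
    level = mask_threshold * np.percentile(mag, 99.0)
    vel = np.where(mag < level, 0.0, vel)
    return vel, mag
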