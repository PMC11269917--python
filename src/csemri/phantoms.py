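"""Analytic 2-D disk phantoms, static and dynamic (cardiac + respiratory).

Disk phantoms have a closed-form Fourier transform (a jinc), so radial
k-space data can be synthesized at arbitrary sample positions without a
discretization/inverse-crime shortcut: the reconstruction grid never enters
the data simulation.

The dynamic phantom emulates a beating, breathing heart-like object: a
"ventricle" disk whose radius pulses at the cardiac frequency, inside a
"body" disk translating with respiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import j1

__all__ = ["Disk", "DiskPhantom", "DynamicPhantom"]


@dataclass(frozen=True)
class Disk:
    """Uniform disk: centre (pixels, image-centred), radius (pixels), amplitude."""

    cx: float
    cy: float
    radius: float
    amplitude: float = 1.0


def _disk_kspace(disk: Disk, kx, ky, n):
    """FT of a disk on the grid-unit k convention of :mod:`csemri.nufft`."""
    # Spatial frequency in cycles/pixel is k/n.
    fr = np.hypot(kx, ky) / n
    r = disk.radius
    arg = 2 * np.pi * fr * r
    with np.errstate(invalid="ignore", divide="ignore"):
        shape = np.where(arg > 1e-12, 2.0 * j1(np.where(arg > 0, arg, 1.0)) / np.where(arg > 0, arg, 1.0), 1.0)
    area = np.pi * r * r
    phase = np.exp(-2j * np.pi * (kx * disk.cx + ky * disk.cy) / n)
    return disk.amplitude * area * shape * phase


@dataclass
class DiskPhantom:
    """Static collection of disks on an n x n image grid."""

    n: int
    disks: Sequence[Disk]

    def kspace(self, kpoints: np.ndarray) -> np.ndarray:
        """Analytic k-space at (n_samples, 2) grid-unit positions."""
        kpoints = np.atleast_2d(np.asarray(kpoints, float))
        kx, ky = kpoints[:, 0], kpoints[:, 1]
        out = np.zeros(kpoints.shape[0], complex)
        for d in self.disks:
            out += _disk_kspace(d, kx, ky, self.n)
        return out

    def image(self, supersample: int = 4) -> np.ndarray:
        """Area-averaged rasterization (for reference comparisons)."""
        s = supersample
        ax = (np.arange(self.n * s) + 0.5) / s - self.n / 2
        xg, yg = np.meshgrid(ax, ax, indexing="ij")
        img = np.zeros_like(xg)
        for d in self.disks:
            img += d.amplitude * (
                (xg - d.cx) ** 2 + (yg - d.cy) ** 2 <= d.radius**2
            )
        return img.reshape(self.n, s, self.n, s).mean(axis=(1, 3))


@dataclass
class DynamicPhantom:
    """Heart-like 2-D phantom with cardiac pulsation and respiratory drift.

    At time t the body disk is displaced by ``resp_amp * sin(2 pi f_r t)``
    pixels along y and the ventricle radius is
    ``r0 * (1 + card_amp * sin(2 pi f_c t))``.
    """

    n: int = 48
    resp_freq_hz: float = 0.25
    resp_amp_px: float = 3.0
    card_freq_hz: float = 1.2
    card_amp: float = 0.3
    body_radius: float = 16.0
    ventricle_radius: float = 6.0

    def disks_at(self, t: float) -> list[Disk]:
        dy = self.resp_amp_px * np.sin(2 * np.pi * self.resp_freq_hz * t)
        rv = self.ventricle_radius * (
            1.0 + self.card_amp * np.sin(2 * np.pi * self.card_freq_hz * t)
        )
        return [
            Disk(0.0, dy, self.body_radius, 1.0),
            Disk(2.0, dy - 2.0, rv, -0.6),
        ]

    def phantom_at(self, t: float) -> DiskPhantom:
        return DiskPhantom(self.n, self.disks_at(t))

    def kspace_spoke(self, kpoints: np.ndarray, t: float) -> np.ndarray:
        """Analytic k-space of the phantom frozen at spoke time ``t``."""
        return self.phantom_at(t).kspace(kpoints)

    def projection(self, t: float, axis: int = 1, n_os: int = 2) -> np.ndarray:
        """1-D projection along ``axis`` (a superior-inferior readout).

        Computed from the analytic central k-space line so it matches what
        an SI spoke's first echo would measure.
        """
        n = self.n
        kline = np.zeros((n * n_os, 2))
        kk = (np.arange(n * n_os) - n * n_os / 2) / n_os
        kline[:, axis] = kk
        spec = self.kspace_spoke(kline, t)
        prof = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(spec)))
        return np.abs(prof)
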