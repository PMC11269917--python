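"""Segmented 3D radial spiral-phyllotaxis sampling and multi-echo readouts.

Spokes are arranged on a spiral phyllotaxis over the hemisphere: the n-th
point sits at polar angle theta_n = (pi/2) * sqrt(n/N) with the azimuth
advancing by the golden angle (~137.51 deg) per point, which distributes
directions quasi-uniformly.  The point set is split into segments traversed
one per heartbeat's worth of TRs; each segment is prepended with a
superior-inferior (SI) spoke along +z whose readout provides the
self-gating signal.

The readout designer builds the multi-echo gradient waveform of one TR for
a unit readout direction: alternating-polarity trapezoids for the bipolar
scheme, same-polarity lobes with flyback rewinders for the monopolar one,
with echo centers (k-space origin crossings) placed on the scheme's echo
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .girf import DEFAULT_RASTER_S, GIRFModel, GradientWaveform, KTrajectory, apply_girf, integrate_trajectory
from .spectrum import EchoScheme, SystemConfig

__all__ = [
    "PhyllotaxisPlan",
    "ReadoutDesign",
    "phyllotaxis_directions",
    "build_readout",
    "spoke_kspace",
]

GOLDEN_ANGLE_RAD = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class PhyllotaxisPlan:
    """Spoke directions with segment bookkeeping.

    ``directions`` is (N, 3) unit vectors in acquisition order;
    ``segment_index``/``in_segment_pos`` locate each spoke; ``si_flag``
    marks the superior-inferior spokes (first of each segment).
    """

    directions: np.ndarray
    segment_index: np.ndarray
    in_segment_pos: np.ndarray
    si_flag: np.ndarray
    n_segments: int
    trs_per_segment: int

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]


def phyllotaxis_directions(
    n_segments: int = 3078,
    trs_per_segment: int = 13,
    hemisphere: bool = True,
    alternate_polarity: bool = False,
) -> PhyllotaxisPlan:
    """Segmented spiral-phyllotaxis direction set with SI spokes.

    ``n_segments * (trs_per_segment - 1)`` spiral points are generated and
    dealt out round-robin so each segment's non-SI spokes sample the whole
    polar range; an SI spoke (0,0,1) is prepended to every segment.  With
    ``alternate_polarity`` every second spoke is negated (full-sphere
    coverage from hemisphere points).
    """
    if n_segments < 1 or trs_per_segment < 1:
        raise ValueError("segment counts must be >= 1")
    n_ph = n_segments * (trs_per_segment - 1)
    # Spiral points, pole to equator (or full sphere).
    n = np.arange(1, n_ph + 1)
    if n_ph > 0:
        theta_max = np.pi / 2.0 if hemisphere else np.pi
        theta = theta_max * np.sqrt(n / n_ph) if hemisphere else np.arccos(1 - 2 * n / n_ph)
        phi = n * GOLDEN_ANGLE_RAD
        pts = np.stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
            axis=1,
        )
    else:
        pts = np.empty((0, 3))

    total = n_segments * trs_per_segment
    directions = np.zeros((total, 3))
    seg_idx = np.zeros(total, dtype=int)
    pos_idx = np.zeros(total, dtype=int)
    si = np.zeros(total, dtype=bool)
    for s in range(n_segments):
        base = s * trs_per_segment
        directions[base] = (0.0, 0.0, 1.0)
        si[base] = True
        seg_idx[base : base + trs_per_segment] = s
        pos_idx[base : base + trs_per_segment] = np.arange(trs_per_segment)
        # Round-robin deal: segment s takes spiral points s, s+S, s+2S, ...
        take = np.arange(trs_per_segment - 1) * n_segments + s
        directions[base + 1 : base + trs_per_segment] = pts[take]
    if alternate_polarity:
        directions[1::2] *= -1.0
    return PhyllotaxisPlan(directions, seg_idx, pos_idx, si, n_segments, trs_per_segment)


@dataclass(frozen=True)
class ReadoutDesign:
    """Hardware/protocol parameters of the radial readout.

    Defaults follow a 3T cardiac protocol: (220 mm)^3 FOV, 147 matrix
    (1.5 mm isotropic), 1510 Hz/px receiver bandwidth, 60 mT/m gradients
    at 200 T/m/s slew.
    """

    fov_mm: float = 220.0
    matrix: int = 147
    bw_per_pixel_hz: float = 1510.0
    g_max_mt_m: float = 60.0
    slew_max_t_m_s: float = 200.0
    raster_s: float = DEFAULT_RASTER_S

    def __post_init__(self):
        if min(self.fov_mm, self.matrix, self.bw_per_pixel_hz) <= 0:
            raise ValueError("fov, matrix and bandwidth must be positive")

    @property
    def dwell_s(self) -> float:
        return 1.0 / (self.bw_per_pixel_hz * self.matrix)

    @property
    def sampling_time_s(self) -> float:
        return 1.0 / self.bw_per_pixel_hz

    @property
    def kmax_grid(self) -> float:
        return self.matrix / 2.0


def _trapezoid(amp_mt_m, ramp_n, flat_n):
    up = np.linspace(0.0, amp_mt_m, ramp_n, endpoint=False)
    down = np.linspace(amp_mt_m, 0.0, ramp_n, endpoint=False)
    return np.concatenate([up, np.full(flat_n, amp_mt_m), down])


def _blip_for_area(area_t_s_m, duration_n, dt, slew, g_max, what):
    """Triangle/trapezoid of given net area within a fixed duration.

    Solves G*(d - G/slew) = |area| for the plateau amplitude G (ramps
    included), raising a descriptive error when the duration or hardware
    limits make the area unreachable.
    """
    d = duration_n * dt
    a = abs(area_t_s_m)
    if a == 0:
        return np.zeros(duration_n)
    disc = d * d - 4.0 * a / slew
    if disc < 0:
        raise ValueError(
            f"{what}: required area {a:.3e} T*s/m infeasible in {d*1e3:.3f} ms at slew {slew} T/m/s"
        )
    g = (d - np.sqrt(disc)) * slew / 2.0
    if g * 1e3 > g_max:
        raise ValueError(f"{what}: required amplitude {g*1e3:.1f} mT/m exceeds limit {g_max} mT/m")
    ramp_n = max(int(np.ceil(g / slew / dt)), 1)
    flat_n = duration_n - 2 * ramp_n
    if flat_n < 0:
        ramp_n = duration_n // 2
        flat_n = duration_n - 2 * ramp_n
    # Rescale amplitude for the quantized shape to hit the area exactly.
    eff = (ramp_n + flat_n) * dt
    g = a / eff
    if g * 1e3 > g_max or g / (ramp_n * dt) > slew * 1.01:
        raise ValueError(f"{what}: quantized blip violates hardware limits")
    w = _trapezoid(g * 1e3, ramp_n, flat_n)
    out = np.zeros(duration_n)
    out[: w.size] = w
    return np.sign(area_t_s_m) * out


def build_readout(
    design: ReadoutDesign,
    scheme: EchoScheme,
    system: SystemConfig | None = None,
) -> GradientWaveform:
    """Multi-echo readout gradient of one TR for a unit direction.

    Returns a single-axis waveform (axis label "r") whose integrated
    trajectory crosses k = 0 at the scheme's echo times (within one raster
    step) and spans +-matrix/2 grid points per echo.  ``echo_slices`` and
    sampling windows are attached as attributes for trajectory extraction.
    """
    sc = system or SystemConfig()
    gamma = sc.gamma_hz_per_t
    dt = design.raster_s
    fov_m = design.fov_mm * 1e-3
    dte_n = int(round(scheme.dte * 1e-3 / dt))
    te1_n = int(round(scheme.te1 * 1e-3 / dt))
    if abs(dte_n * dt - scheme.dte * 1e-3) > dt or abs(te1_n * dt - scheme.te1 * 1e-3) > dt:
        raise ValueError("echo timing is not representable on the gradient raster")

    # Readout plateau: traverse matrix/fov (1/m) during the sampling window.
    t_samp = design.sampling_time_s
    samp_n = int(np.ceil(t_samp / dt))
    g_read = (design.matrix / fov_m) / (gamma * t_samp)  # T/m
    if g_read * 1e3 > design.g_max_mt_m:
        raise ValueError(f"readout amplitude {g_read*1e3:.1f} mT/m exceeds limit")
    ramp_n = max(int(np.ceil(g_read / design.slew_max_t_m_s / dt)), 1)

    if scheme.mode == "bipolar":
        lobe_n = dte_n                     # back-to-back lobes: spacing = lobe
        flat_n = lobe_n - 2 * ramp_n
        if flat_n < samp_n:
            raise ValueError(
                f"bipolar echo spacing {scheme.dte} ms too short: flat top "
                f"{flat_n*dt*1e3:.3f} ms < sampling window {t_samp*1e3:.3f} ms"
            )
    else:
        lobe_n = 2 * ramp_n + samp_n + 4   # small margin beyond sampling
        fly_n = dte_n - lobe_n
        if fly_n < 4:
            raise ValueError(
                f"monopolar echo spacing {scheme.dte} ms too short for readout plus flyback"
            )
        flat_n = lobe_n - 2 * ramp_n

    lobe = _trapezoid(g_read * 1e3, ramp_n, flat_n)
    lobe_area = g_read * (flat_n + ramp_n) * dt  # T*s/m

    half_n = lobe_n // 2
    pre_n = te1_n - half_n
    if pre_n < 4:
        raise ValueError(f"TE1 {scheme.te1} ms leaves no room for the prephaser")
    pre = _blip_for_area(-lobe_area / 2.0, pre_n, dt, design.slew_max_t_m_s,
                         design.g_max_mt_m, "prephaser")

    parts = [pre]
    echo_slices = []
    cursor = pre_n
    for e in range(scheme.n_echoes):
        sign = 1.0 if (scheme.mode == "monopolar" or e % 2 == 0) else -1.0
        parts.append(sign * lobe)
        start = cursor + (lobe_n - samp_n) // 2
        echo_slices.append(slice(start, start + samp_n))
        cursor += lobe.size
        if scheme.mode == "monopolar" and e < scheme.n_echoes - 1:
            fly = _blip_for_area(-lobe_area, fly_n, dt, design.slew_max_t_m_s,
                                 design.g_max_mt_m, "flyback")
            parts.append(fly)
            cursor += fly_n

    wave = np.concatenate(parts)
    g = GradientWaveform(dt, wave, ("r",))
    g.echo_slices = echo_slices
    g.samples_per_echo = samp_n
    g.design = design
    return g


def spoke_kspace(
    plan: PhyllotaxisPlan,
    readout: GradientWaveform,
    girf: GIRFModel | None = None,
    system: SystemConfig | None = None,
    spoke_indices: Sequence[int] | None = None,
) -> list[KTrajectory]:
    """Per-spoke 3D k-space trajectories, nominal or GIRF-distorted.

    The unit-direction readout is scaled by each spoke's direction vector
    into per-axis (x, y, z) waveforms; with a GIRF supplied the per-axis
    waveforms are passed through it before temporal integration.
    """
    sc = system or SystemConfig()
    fov_m = readout.design.fov_mm * 1e-3 if hasattr(readout, "design") else 0.22
    echo_slices = getattr(readout, "echo_slices", [])
    idx = range(plan.n_spokes) if spoke_indices is None else spoke_indices
    out = []
    for i in idx:
        d = plan.directions[i]
        g3 = GradientWaveform(readout.dt, d[:, None] * readout.samples[0][None, :],
                              ("x", "y", "z"))
        if girf is not None:
            g3 = apply_girf(g3, girf)
        out.append(integrate_trajectory(g3, sc, fov_m, echo_slices=list(echo_slices)))
    return out
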