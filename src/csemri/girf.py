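"""Gradient-chain modelling via the gradient impulse response function (GIRF).

A gradient system is treated as a per-axis linear time-invariant (LTI)
system: the gradient actually played out is the nominal waveform convolved
with the axis' impulse response, equivalently multiplied by its frequency
response H(f) (the GFRF).  Real systems show a near-pure delay (a linear
phase slope), mechanical resonances of the gradient coils (narrow notches,
typically a few kHz), and a low-pass roll-off that impedes fast switching.

This module can synthesize such a system, simulate its measurement with the
two off-centered thin-slice method, estimate the GIRF from probe/response
pairs by regularized frequency-domain deconvolution, predict distorted
waveforms, and integrate gradients into k-space trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate as _integrate
from scipy.fft import fft, fftfreq, ifft, next_fast_len

from .spectrum import SystemConfig

__all__ = [
    "GradientWaveform",
    "GIRFModel",
    "KTrajectory",
    "synth_gradient_system",
    "thin_slice_measurement",
    "estimate_girf",
    "apply_girf",
    "integrate_trajectory",
    "echo_center_times",
    "echo_parity_shift",
    "apply_timing_calibration",
    "triangle_probes",
    "estimate_delay",
]

DEFAULT_RASTER_S = 10e-6


@dataclass
class GradientWaveform:
    """Uniformly rastered gradient waveform(s), amplitude in mT/m.

    ``samples`` is (n_axes, n) or (n,) for a single axis; ``axes`` labels
    the rows.
    """

    dt: float
    samples: np.ndarray
    axes: tuple[str, ...] = ("x",)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.dt <= 0:
            raise ValueError("raster time must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if len(self.axes) != self.samples.shape[0]:
            raise ValueError("axis labels must match number of waveform rows")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_samples)


@dataclass
class GIRFModel:
    """Per-axis frequency response on a symmetric frequency grid.

    ``H`` is (n_axes, n_freqs) complex, dimensionless; ``delays_s`` holds
    the equivalent group delay estimate of each axis.
    """

    freqs: np.ndarray
    H: np.ndarray
    axes: tuple[str, ...] = ("x", "y", "z")
    delays_s: np.ndarray | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.H = np.atleast_2d(np.asarray(self.H, complex))
        if self.freqs[0] > 0 or self.freqs[-1] < 0:
            raise ValueError("frequency grid must be symmetric around 0")
        if self.H.shape[1] != self.freqs.size:
            raise ValueError("H and frequency grid size mismatch")
        if self.delays_s is None:
            self.delays_s = np.array([estimate_delay(self.freqs, h) for h in self.H])

    def axis_index(self, axis: str) -> int:
        try:
            return self.axes.index(axis)
        except ValueError:
            raise KeyError(f"axis {axis!r} not in {self.axes}") from None

    @classmethod
    def identity(cls, axes=("x", "y", "z"), fmax=50e3, n=2049) -> "GIRFModel":
        freqs = np.linspace(-fmax, fmax, n)
        return cls(freqs, np.ones((len(axes), n), complex), tuple(axes))


def estimate_delay(freqs: np.ndarray, H: np.ndarray, band_hz: float = 10e3) -> float:
    """Equivalent delay from the in-band phase slope, tau = -dphi/df / 2pi."""
    sel = (np.abs(freqs) <= band_hz) & (np.abs(H) > 1e-3)
    if sel.sum() < 3:
        return 0.0
    phase = np.unwrap(np.angle(H[sel]))
    slope = np.polyfit(freqs[sel], phase, 1, w=np.abs(H[sel]))[0]
    return -slope / (2 * np.pi)


def synth_gradient_system(
    delays_s: Sequence[float] = (1.0e-6, 1.5e-6, 2.5e-6),
    resonances: Sequence[Sequence[tuple[float, float, float]]] | None = None,
    lowpass_cutoff_hz: float = 25e3,
    axes: tuple[str, ...] = ("x", "y", "z"),
    fmax: float = 50e3,
    n_freqs: int = 4097,
) -> GIRFModel:
    """Synthesize a plausible gradient chain as H = delay * lowpass * notches.

    ``resonances`` gives per-axis lists of (frequency_hz, depth, width_hz)
    Lorentzian notches; defaults place mechanical resonances in the
    3.3-4 kHz band, deeper on x/y than z, with the z axis dominated by a
    2.5 us delay — the qualitative signature of a real 3T gradient chain.
    ``lowpass_cutoff_hz`` may be ``np.inf`` for a flat response.
    """
    if lowpass_cutoff_hz <= 0:
        raise ValueError("lowpass cutoff must be positive")
    if resonances is None:
        resonances = (
            [(3.4e3, 0.12, 500.0), (3.9e3, 0.08, 400.0)],   # x
            [(3.3e3, 0.10, 500.0), (4.0e3, 0.10, 400.0)],   # y
            [(3.6e3, 0.04, 500.0)],                          # z
        )[: len(axes)]
    freqs = np.linspace(-fmax, fmax, n_freqs)
    H = np.empty((len(axes), n_freqs), complex)
    for a, (tau, res_list) in enumerate(zip(delays_s, resonances)):
        h = np.exp(-2j * np.pi * freqs * tau)
        if np.isfinite(lowpass_cutoff_hz):
            # 4th-order Butterworth magnitude roll-off (zero-phase).
            h = h / np.sqrt(1.0 + (freqs / lowpass_cutoff_hz) ** 8)
        for f_r, depth, width in res_list:
            lor = 1.0 / (1.0 + ((np.abs(freqs) - f_r) / (width / 2.0)) ** 2)
            h = h * (1.0 - depth * lor)
        H[a] = h
    return GIRFModel(freqs, H, tuple(axes))


def _fft_grid(n: int, dt: float):
    nfft = next_fast_len(2 * n)
    return nfft, fftfreq(nfft, dt)


def apply_girf(nominal: GradientWaveform, girf: GIRFModel, axes=None) -> GradientWaveform:
    """Predict the actually played waveform: frequency-domain multiplication.

    Waveforms are zero-padded to at least twice their length before the FFT
    to avoid circular wrap-around; H is linearly interpolated onto the FFT
    grid (edge-held outside the stored band).  Output length equals input
    length.
    """
    axes = axes or nominal.axes
    nfft, f = _fft_grid(nominal.n_samples, nominal.dt)
    out = np.empty_like(nominal.samples)
    for row, axis in enumerate(axes):
        h_row = girf.H[girf.axis_index(axis)]
        hr = np.interp(f, girf.freqs, h_row.real)
        hi = np.interp(f, girf.freqs, h_row.imag)
        spec = fft(nominal.samples[row], nfft) * (hr + 1j * hi)
        out[row] = np.real(ifft(spec))[: nominal.n_samples]
    return GradientWaveform(nominal.dt, out, nominal.axes)


def thin_slice_measurement(
    system: GIRFModel,
    probe: GradientWaveform,
    axis: str = "x",
    slice_offset_m: float = 0.005,
    noise_sd: float = 0.0,
    seed: int = 0,
    system_config: SystemConfig | None = None,
) -> GradientWaveform:
    """Simulate the two off-centered thin-slice gradient measurement.

    Two slices at +-``slice_offset_m`` accrue phase +-2*pi*gamma*x*int(G dt)
    under the system's *actual* gradient; the unwrapped phase difference of
    the two slice signals, differentiated in time, recovers the gradient
    waveform (plus measurement noise on the complex slice signals).

    The default offset keeps the per-sample phase advance below pi for
    gradients up to the 60 mT/m hardware limit so unwrapping stays valid.
    The known cos^2(pi f dt) response of differentiating the trapezoid-
    integrated phase is compensated as part of the measurement processing.
    """
    if slice_offset_m == 0:
        raise ValueError("slice offset must be nonzero (zero separation)")
    sc = system_config or SystemConfig()
    gamma = sc.gamma_hz_per_t
    actual = apply_girf(probe, system, axes=(axis,) * probe.samples.shape[0])
    g_t_per_m = actual.samples[0] * 1e-3
    k = _integrate.cumulative_trapezoid(g_t_per_m, dx=probe.dt, initial=0.0)
    phase = 2 * np.pi * gamma * slice_offset_m * k
    s_plus = np.exp(1j * phase)
    s_minus = np.exp(-1j * phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s_plus = s_plus + noise_sd * (
            rng.normal(size=phase.size) + 1j * rng.normal(size=phase.size)
        )
        s_minus = s_minus + noise_sd * (
            rng.normal(size=phase.size) + 1j * rng.normal(size=phase.size)
        )
    dphi = np.unwrap(np.angle(s_plus * np.conj(s_minus)))
    k_meas = dphi / (2 * np.pi * gamma * 2 * slice_offset_m)

    # The phase samples are the exact trapezoid integral of the gradient,
    # so the interval means m[i] = (G[i] + G[i+1])/2 invert exactly by the
    # recursion G[i+1] = 2 m[i] - G[i] with G[0] = 0 (the sequence starts
    # at rest).  This keeps the measurement bias-free; noise on the slice
    # signals propagates (strongest near Nyquist), which averaging over
    # repetitions suppresses.
    from scipy.signal import lfilter

    m = np.diff(k_meas) / probe.dt
    g_meas = np.concatenate([[0.0], lfilter([2.0], [1.0, 1.0], m)])
    return GradientWaveform(probe.dt, g_meas * 1e3, (axis,))


def triangle_probes(
    dt: float = DEFAULT_RASTER_S,
    ramp_samples: Sequence[int] = (3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 31, 38),
    slew_t_m_s: float = 200.0,
    g_max_mt_m: float = 40.0,
    n_samples: int = 512,
    axis: str = "x",
) -> list[GradientWaveform]:
    """Slew-limited triangular blips of distinct slopes/durations.

    Short blips carry the high-frequency probe energy, long ones the low
    frequencies; amplitudes ride at 80 % of the slew limit so every probe
    is hardware-legal.
    """
    probes = []
    for ramp in ramp_samples:
        amp = min(0.8 * slew_t_m_s * ramp * dt * 1e3, g_max_mt_m)
        tri = np.concatenate(
            [np.linspace(0, amp, ramp, endpoint=False),
             np.linspace(amp, 0, ramp + 1)]
        )
        w = np.zeros(n_samples)
        start = n_samples // 4
        w[start : start + tri.size] = tri
        probes.append(GradientWaveform(dt, w, (axis,)))
    return probes


def estimate_girf(
    probes: Sequence[GradientWaveform],
    measured: Sequence[GradientWaveform],
    reg: float = 1e-6,
    fmax: float = 50e3,
    n_freqs: int = 4097,
) -> GIRFModel:
    """Estimate a single-axis GIRF by input-output deconvolution.

    H(f) = sum conj(P_i) M_i / (sum |P_i|^2 + reg * max sum|P|^2), the
    Tikhonov-regularized least-squares solution over all probes.  Frequency
    bands where the probes carry (numerically) no energy are masked to 0
    and reported via the ``flagged`` attribute on the returned model; the
    equivalent delay is fitted with probe-energy weighting so poorly probed
    bands cannot corrupt it.
    """
    if len(probes) == 0 or len(probes) != len(measured):
        raise ValueError("need matching, nonempty probe and measurement lists")
    dt = probes[0].dt
    n = max(max(p.n_samples for p in probes), max(m.n_samples for m in measured))
    nfft, f = _fft_grid(n, dt)
    num = np.zeros(nfft, complex)
    den = np.zeros(nfft, float)
    for p, m in zip(probes, measured):
        P = fft(p.samples[0], nfft)
        M = fft(m.samples[0], nfft)
        num += np.conj(P) * M
        den += np.abs(P) ** 2
    scale = den.max()
    H_fft = num / (den + reg * scale)
    dead = den < 1e-12 * scale
    H_fft[dead] = 0.0

    freqs = np.linspace(-fmax, fmax, n_freqs)
    order = np.argsort(f)
    Hr = np.interp(freqs, f[order], H_fft.real[order])
    Hi = np.interp(freqs, f[order], H_fft.imag[order])
    weight = np.interp(freqs, f[order], den[order]) / scale

    # Probe-energy weighted phase-slope fit for the equivalent delay.
    H_grid = Hr + 1j * Hi
    sel = weight > 1e-3
    phase = np.unwrap(np.angle(H_grid[sel]))
    slope = np.polyfit(freqs[sel], phase, 1, w=weight[sel])[0]
    model = GIRFModel(
        freqs, H_grid[None, :], (probes[0].axes[0],),
        delays_s=np.array([-slope / (2 * np.pi)]),
    )
    model.probe_energy = weight
    model.flagged = bool(dead.any() and not dead.all())
    return model


@dataclass
class KTrajectory:
    """k-space sample positions in grid-point units (cycles across the FOV).

    ``k`` is (n_axes, n_samples); ``echo_slices`` delimits per-echo sample
    ranges and ``parity`` labels each echo "odd"/"even" (1-based echo
    counting, so echo 1 is odd).
    """

    k: np.ndarray
    times: np.ndarray
    echo_slices: list[slice] = field(default_factory=list)
    parity: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.k = np.atleast_2d(np.asarray(self.k, float))
        self.times = np.asarray(self.times, float)


def integrate_trajectory(
    grad: GradientWaveform,
    system: SystemConfig | None = None,
    fov_m: float = 0.22,
    echo_slices: list[slice] | None = None,
) -> KTrajectory:
    """k(t) = gamma * cumulative integral of G, in grid-point units.

    Trapezoidal integration; gradients in mT/m.  One grid point equals a
    k-space increment of 1/FOV.
    """
    sc = system or SystemConfig()
    k_inv_m = sc.gamma_hz_per_t * _integrate.cumulative_trapezoid(
        grad.samples * 1e-3, dx=grad.dt, axis=1, initial=0.0
    )
    k_grid = k_inv_m * fov_m
    slices = echo_slices or []
    parity = ["odd" if i % 2 == 0 else "even" for i in range(len(slices))]
    return KTrajectory(k_grid, grad.times(), slices, parity)


def apply_timing_calibration(
    actual: KTrajectory, nominal: KTrajectory
) -> KTrajectory:
    """Constant-delay compensation zeroing the first-echo k error.

    Emulates a sequence's built-in per-readout calibration: the sampling
    window is shifted by the constant delay that nulls the mean first-echo
    displacement, which also nulls every other echo of a pure-delay system
    but leaves residual (parity-split) errors for any richer distortion.
    """
    if not nominal.echo_slices:
        raise ValueError("nominal trajectory carries no echo segmentation")
    dt = float(np.mean(np.diff(actual.times)))

    def first_echo_shift(tau):
        shifted = np.stack(
            [np.interp(actual.times + tau, actual.times, row) for row in actual.k]
        )
        sl = nominal.echo_slices[0]
        diff = shifted[:, sl] - nominal.k[:, sl]
        return diff, shifted

    d0, _ = first_echo_shift(0.0)
    d1, _ = first_echo_shift(dt)
    m0 = float(d0.mean())
    m1 = float(d1.mean())
    tau = 0.0 if m1 == m0 else -m0 * dt / (m1 - m0)
    _, shifted = first_echo_shift(tau)
    out = KTrajectory(shifted, actual.times, list(nominal.echo_slices), list(nominal.parity))
    out.calibration_delay_s = tau
    return out


def echo_center_times(traj: KTrajectory, axis: int = 0) -> np.ndarray:
    """k-space-origin crossing time of each echo, linearly interpolated.

    The crossing closest to the echo window centre is used; if the window
    contains no sign change the time of the smallest |k| sample is returned.
    """
    if not traj.echo_slices:
        raise ValueError("trajectory carries no echo segmentation")
    out = []
    for sl in traj.echo_slices:
        k = traj.k[axis, sl]
        t = traj.times[sl]
        sign_change = np.nonzero(np.diff(np.signbit(k)))[0]
        if sign_change.size == 0:
            out.append(t[np.argmin(np.abs(k))])
            continue
        mid = (k.size - 1) / 2.0
        i = sign_change[np.argmin(np.abs(sign_change - mid))]
        frac = k[i] / (k[i] - k[i + 1])
        out.append(t[i] + frac * (t[i + 1] - t[i]))
    return np.asarray(out)


def echo_parity_shift(nominal: KTrajectory, actual: KTrajectory) -> tuple[float, float]:
    """Mean k shift of actual vs nominal along the spoke axis, by echo parity.

    Returns (mean_shift_even, mean_shift_odd) in grid points.  The per-
    sample displacement is projected on the *first echo's* readout
    direction for every echo, so on a bipolar readout a residual timing
    error produces shifts of opposite sign for even (2nd, 4th, ...) and
    odd (1st, 3rd, ...) echoes.
    """
    if nominal.k.shape != actual.k.shape:
        raise ValueError("trajectories are not congruent")
    if not nominal.echo_slices:
        raise ValueError("nominal trajectory carries no echo segmentation")
    diff = actual.k - nominal.k
    first = nominal.k[:, nominal.echo_slices[0]]
    d = first[:, -1] - first[:, 0]
    nrm = np.linalg.norm(d)
    d = d / nrm if nrm > 0 else np.array([1.0] + [0.0] * (nominal.k.shape[0] - 1))
    shifts = {"even": [], "odd": []}
    for sl, par in zip(nominal.echo_slices, nominal.parity):
        shifts[par].append(d @ diff[:, sl])
    mean_even = float(np.mean(np.concatenate(shifts["even"]))) if shifts["even"] else 0.0
    mean_odd = float(np.mean(np.concatenate(shifts["odd"]))) if shifts["odd"] else 0.0
    return mean_even, mean_odd
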