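"""Fat-water signal model, fat spectrum handling and echo-scheme analytics.

The chemical-shift-encoded (CSE) signal of a voxel containing water and fat
acquired at echo times ``t`` is modelled as

    y(t) = (W + F * sum_m alpha_m * exp(i * omega_m * t))
           * exp(i * phi0) * exp((i * 2*pi*f0 - R2*) * t)

with ``W``/``F`` the water/fat magnitudes, ``alpha_m``/``omega_m`` the
relative amplitude and angular frequency offset of the m-th fat resonance,
``phi0`` a common initial phase (valid for low flip angles), ``f0`` the B0
off-resonance in Hz and ``R2*`` the effective transverse decay in 1/s.

Units: everything internal is SI — seconds, Hz, Tesla, radians.  Echo-scheme
fields are in milliseconds (the unit users and protocols speak); conversion
happens exactly once, in :meth:`EchoScheme.echo_times_s`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GAMMA_HZ_PER_T",
    "FatSpectrum",
    "SystemConfig",
    "EchoScheme",
    "TissueVoxel",
    "default_fat_spectrum",
    "peak_frequencies",
    "simulate_signal",
    "inphase_outphase_delay",
    "scheme_presets",
]

#: Proton gyromagnetic ratio in Hz/T.
GAMMA_HZ_PER_T = 42.577478518e6


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat resonance model.

    Parameters
    ----------
    shifts_ppm
        Chemical shift of each peak relative to water, in ppm.  Negative
        means lower resonance frequency than water (the dominant methylene
        peak sits near -3.40 ppm).
    rel_amplitudes
        Relative amplitude of each peak; must be non-negative and sum to 1.
    """

    shifts_ppm: np.ndarray
    rel_amplitudes: np.ndarray

    def __init__(self, shifts_ppm: Sequence[float], rel_amplitudes: Sequence[float]):
        shifts = np.asarray(shifts_ppm, dtype=float)
        amps = np.asarray(rel_amplitudes, dtype=float)
        if shifts.ndim != 1 or amps.ndim != 1 or shifts.size != amps.size:
            raise ValueError("shifts_ppm and rel_amplitudes must be 1-D of equal length")
        if shifts.size == 0:
            raise ValueError("spectrum needs at least one peak")
        if np.any(amps < 0):
            raise ValueError("relative amplitudes must be non-negative")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError(f"relative amplitudes must sum to 1 (got {amps.sum()!r})")
        object.__setattr__(self, "shifts_ppm", shifts)
        object.__setattr__(self, "rel_amplitudes", amps)

    @property
    def n_peaks(self) -> int:
        return self.shifts_ppm.size

    @classmethod
    def single_peak(cls, shift_ppm: float = -3.40) -> "FatSpectrum":
        """Single effective fat resonance (methylene by default)."""
        return cls([shift_ppm], [1.0])

    @classmethod
    def from_json(cls, path) -> "FatSpectrum":
        """Load a spectrum from a JSON file.

        Two layouts are accepted: ``{"shifts_ppm": [...], "rel_amplitudes":
        [...]}`` with pre-normalized amplitudes, or the packaged layout with
        a ``peaks`` list of ``{"ppm", "protons"}`` entries plus a
        ``water_ppm`` reference, in which case shifts are computed relative
        to water and proton counts normalized.
        """
        with open(path) as fh:
            doc = json.load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "FatSpectrum":
        if "peaks" in doc:
            water = float(doc.get("water_ppm", 4.70))
            ppm = np.array([p["ppm"] for p in doc["peaks"]], dtype=float)
            protons = np.array([p["protons"] for p in doc["peaks"]], dtype=float)
            return cls(ppm - water, protons / protons.sum())
        return cls(doc["shifts_ppm"], doc["rel_amplitudes"])


def default_fat_spectrum() -> FatSpectrum:
    """The packaged 10-peak subcutaneous triglyceride spectrum."""
    ref = resources.files("csemri.data").joinpath("fat_spectrum_10peak.json")
    return FatSpectrum._from_doc(json.loads(ref.read_text()))


@dataclass(frozen=True)
class SystemConfig:
    """Static-field and gyromagnetic-ratio configuration.

    The default field is 2.89 T, the exact field strength of a nominal-3T
    system.  Fat shifts are expressed relative to the water resonance;
    methylene fat resonates ~3.4 ppm *below* water, hence negative shift
    and negative frequency offset.
    """

    b0_tesla: float = 2.89
    gamma_hz_per_t: float = GAMMA_HZ_PER_T

    def __post_init__(self):
        if self.b0_tesla <= 0:
            raise ValueError("b0_tesla must be positive")
        if self.gamma_hz_per_t <= 0:
            raise ValueError("gamma_hz_per_t must be positive")


@dataclass(frozen=True)
class EchoScheme:
    """Multi-echo readout scheme.

    ``mode`` is "monopolar" (same-polarity lobes with flyback rewinders) or
    "bipolar" (alternating polarity, halving the achievable echo spacing).
    Times are in milliseconds.
    """

    mode: Literal["monopolar", "bipolar"]
    n_echoes: int
    te1: float
    dte: float
    tr: float = 15.0

    def __post_init__(self):
        if self.mode not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if self.te1 <= 0 or self.dte <= 0:
            raise ValueError("te1 and dte must be positive")
        if self.echo_times()[-1] >= self.tr:
            raise ValueError(
                f"last echo ({self.echo_times()[-1]:.2f} ms) must precede TR ({self.tr} ms)"
            )

    def echo_times(self) -> np.ndarray:
        """Echo times in milliseconds, te1 + k*dte."""
        return self.te1 + self.dte * np.arange(self.n_echoes)

    def echo_times_s(self) -> np.ndarray:
        """Echo times in seconds (the internal unit)."""
        return self.echo_times() * 1e-3


_PRESETS = {
    # 15-ms TR multi-echo protocols at nominal 3T.
    "monopolar3T": EchoScheme("monopolar", 8, 1.16, 1.96, 15.0),
    "bipolar3T": EchoScheme("bipolar", 13, 1.12, 1.07, 15.0),
}


def scheme_presets(name: str | None = None):
    """Named echo-scheme presets.

    With no argument returns the full preset dict; with a name returns that
    scheme or raises ``KeyError`` listing valid names.
    """
    if name is None:
        return dict(_PRESETS)
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown scheme {name!r}; available: {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class TissueVoxel:
    """Ground-truth voxel composition for signal synthesis.

    ``phi0`` is in degrees (converted internally), ``f0`` in Hz, ``r2star``
    in 1/s.  The proton-density fat fraction is F/(W+F).
    """

    water: float
    fat: float
    phi0: float = 0.0
    f0: float = 0.0
    r2star: float = 0.0

    def __post_init__(self):
        if self.water < 0 or self.fat < 0:
            raise ValueError("water and fat magnitudes must be non-negative")
        if self.r2star < 0:
            raise ValueError("r2star must be non-negative")

    def pdff(self) -> float:
        """Fat fraction in [0, 1]; 0 for an empty voxel."""
        tot = self.water + self.fat
        return self.fat / tot if tot > 0 else 0.0


def peak_frequencies(
    spectrum: FatSpectrum, system: SystemConfig | None = None
) -> np.ndarray:
    """Frequency offset of each fat peak relative to water, in Hz.

    f_m = shift_ppm * 1e-6 * gamma * B0.  Negative for peaks below the water
    frequency (methylene at -3.40 ppm gives about -418 Hz at 2.89 T).
    """
    system = system or SystemConfig()
    return spectrum.shifts_ppm * 1e-6 * system.gamma_hz_per_t * system.b0_tesla


def fat_phasor(spectrum: FatSpectrum, echo_times_s: np.ndarray,
               system: SystemConfig | None = None) -> np.ndarray:
    """Complex fat modulation c(t) = sum_m alpha_m exp(i 2 pi f_m t)."""
    t = np.asarray(echo_times_s, dtype=float)
    freqs = peak_frequencies(spectrum, system)
    return np.exp(2j * np.pi * np.outer(t, freqs)) @ spectrum.rel_amplitudes


def simulate_signal(
    voxel: TissueVoxel,
    spectrum: FatSpectrum,
    echo_times_s: Sequence[float],
    system: SystemConfig | None = None,
) -> np.ndarray:
    """Noiseless CSE signal of one voxel at the given echo times (seconds).

    Returns one complex sample per echo time.  Noise is added separately
    (see :func:`csemri.silico.add_complex_noise`).
    """
    t = np.asarray(echo_times_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("echo times must be non-negative")
    c = fat_phasor(spectrum, t, system)
    phi0 = np.deg2rad(voxel.phi0)
    return (
        (voxel.water + voxel.fat * c)
        * np.exp(1j * phi0)
        * np.exp((2j * np.pi * voxel.f0 - voxel.r2star) * t)
    )


def effective_fat_frequency(
    spectrum: FatSpectrum,
    system: SystemConfig | None = None,
    peaks: Literal["resolved", "all", "dominant"] = "resolved",
    min_separation_ppm: float = 1.0,
) -> float:
    """Amplitude-weighted effective fat-water frequency offset in Hz.

    ``peaks`` selects which resonances enter the weighted mean:

    - ``"resolved"`` (default): peaks at least ``min_separation_ppm`` from
      water.  The olefinic and glycerol resonances within ~0.6 ppm of water
      are spectrally indistinguishable from it at clinical field strengths
      and do not contribute to the observable fat-water beat, so they are
      excluded from the effective frequency.
    - ``"all"``: every peak.
    - ``"dominant"``: the single largest-amplitude peak.
    """
    freqs = peak_frequencies(spectrum, system)
    amps = spectrum.rel_amplitudes
    if peaks == "dominant":
        i = int(np.argmax(amps))
        return float(freqs[i])
    if peaks == "resolved":
        mask = np.abs(spectrum.shifts_ppm) >= min_separation_ppm
        if not mask.any():
            raise ValueError("no fat peak resolved from water at this separation")
        freqs, amps = freqs[mask], amps[mask]
    elif peaks != "all":
        raise ValueError(f"unknown peaks selector {peaks!r}")
    return float(np.sum(amps * freqs) / np.sum(amps))


def inphase_outphase_delay(
    spectrum: FatSpectrum,
    system: SystemConfig | None = None,
    peaks: Literal["resolved", "all", "dominant"] = "resolved",
) -> float:
    """In-phase/out-of-phase delay in milliseconds.

    Half the period of the effective fat-water beat, 1/(2*|f_eff|), with
    f_eff from :func:`effective_fat_frequency`.  About 1.24 ms for the
    default 10-peak spectrum at 2.89 T.
    """
    f_eff = effective_fat_frequency(spectrum, system, peaks=peaks)
    if f_eff == 0:
        raise ValueError("no fat-water frequency separation (f_eff == 0)")
    return 1e3 / (2.0 * abs(f_eff))
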