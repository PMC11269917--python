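"""Multipeak fat-water separation with joint B0 and R2* estimation.

The estimator is an IDEAL-type variable-projection (VARPRO) fit of the
two-species CSE model.  For a candidate pair (f0, R2*) the complex water and
fat amplitudes enter the model linearly through the basis

    a1(t) = exp((i 2 pi f0 - R2*) t)
    a2(t) = c(t) * a1(t),      c(t) = sum_m alpha_m exp(i 2 pi f_m t)

so they are projected out by linear least squares and only the 2-D nonlinear
landscape over (f0, R2*) is searched: a coarse global grid (the landscape is
periodic-ish in f0 with many local minima) followed by per-voxel parabolic
coordinate refinement.  A spatial field-map consistency constraint then
iteratively re-fits voxels whose B0 estimate deviates from the local median,
suppressing isolated fat-water swaps while leaving coherently swapped
regions (the genuinely ambiguous ones) intact.

All arrays are vectorized over voxels; a single voxel is just the N=1 case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .spectrum import FatSpectrum, SystemConfig, default_fat_spectrum, fat_phasor

__all__ = ["FitConfig", "FatWaterResult", "varpro_fit_voxel", "fit_volume", "compute_pdff"]


@dataclass(frozen=True)
class FitConfig:
    """Search and constraint settings for the VARPRO fit.

    The coarse grid only needs to land in the correct basin of the (f0, R2*)
    residual landscape — basin width in f0 is ~1/(NTE*dTE), hundreds of Hz
    wide in practice — after which parabolic refinement reaches continuum
    precision, so the default steps are deliberately coarse.
    """

    f0_range_hz: tuple[float, float] = (-600.0, 600.0)
    f0_step_hz: float = 8.0
    r2s_range: tuple[float, float] = (0.0, 300.0)
    r2s_step: float = 50.0
    n_refine: int = 10
    n_local_iters: int = 3
    fieldmap_size: int = 3
    fieldmap_threshold_hz: float = 150.0
    constraint_slack: float = 2.0
    coarse_neighborhood: int = 3
    smooth_fieldmap: bool = False
    debias_amplitudes: bool = True
    f0_penalty_per_hz: float = 4e-6
    chunk: int = 4096

    def __post_init__(self):
        if self.f0_range_hz[1] <= self.f0_range_hz[0]:
            raise ValueError("empty f0 range")
        if self.f0_step_hz <= 0 or self.r2s_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.r2s_range[0] < 0 or self.r2s_range[1] <= self.r2s_range[0]:
            raise ValueError("invalid r2s range")

    def f0_grid(self) -> np.ndarray:
        lo, hi = self.f0_range_hz
        n = int(np.floor((hi - lo) / self.f0_step_hz)) + 1
        return lo + self.f0_step_hz * np.arange(n)

    def r2s_grid(self) -> np.ndarray:
        lo, hi = self.r2s_range
        n = int(np.floor((hi - lo) / self.r2s_step)) + 1
        return lo + self.r2s_step * np.arange(n)


@dataclass
class FatWaterResult:
    """Per-voxel fat-water decomposition maps.

    ``water``/``fat`` are complex amplitudes, ``f0_map`` in Hz,
    ``r2star_map`` in 1/s, ``pdff_map`` in % (kept in [0, 100] by magnitude
    discrimination), ``residual_map`` the minimized residual norm, and
    ``degenerate`` flags voxels with no usable signal (all-zero or
    non-finite input).

    ``pdff_signed_map`` is the companion unclipped estimate: the water and
    fat amplitudes are projected onto the common-phase axis and their signed
    ratio taken, so noise at the 0 %/100 % boundaries stays symmetric
    instead of rectifying.  Accuracy statistics use it; display maps use the
    clipped ``pdff_map``.
    """

    water: np.ndarray
    fat: np.ndarray
    f0_map: np.ndarray
    r2star_map: np.ndarray
    pdff_map: np.ndarray
    residual_map: np.ndarray
    degenerate: np.ndarray
    pdff_signed_map: np.ndarray | None = None


def compute_pdff(W, F):
    """Proton-density fat fraction in %, by magnitude discrimination.

    Uses |F|/(|W|+|F|) when fat is the minority species and the complementary
    1-|W|/(|W|+|F|) otherwise, which keeps the map in [0, 100] regardless of
    phase errors.  Empty voxels (W = F = 0) map to 0.
    """
    aw = np.abs(np.asarray(W))
    af = np.abs(np.asarray(F))
    tot = aw + af
    with np.errstate(invalid="ignore", divide="ignore"):
        minority = np.where(tot > 0, 100.0 * af / np.where(tot > 0, tot, 1.0), 0.0)
        majority = np.where(tot > 0, 100.0 * (1.0 - aw / np.where(tot > 0, tot, 1.0)), 0.0)
    out = np.where(af <= aw, minority, majority)
    return out if out.ndim else float(out)


def _project(S, t, c, f0, r2s):
    """Least-squares water/fat amplitudes and squared residual per voxel.

    S: (N, NE) signals; f0, r2s: (N,).  The Gram matrix of the basis only
    depends on R2* (|a1|^2 cancels the f0 phase), which keeps this cheap.
    """
    f0 = np.atleast_1d(np.asarray(f0, float))
    r2s = np.atleast_1d(np.asarray(r2s, float))
    decay = np.exp(-r2s[:, None] * t[None, :])              # (N, NE) real
    e = decay * np.exp(2j * np.pi * f0[:, None] * t[None, :])
    d2 = decay * decay
    g11 = d2.sum(axis=1)
    g22 = (np.abs(c) ** 2 * d2).sum(axis=1)
    g12 = (c[None, :] * d2).sum(axis=1)                     # complex
    ce = np.conj(e)
    b1 = (ce * S).sum(axis=1)
    b2 = (np.conj(c)[None, :] * ce * S).sum(axis=1)
    det = g11 * g22 - np.abs(g12) ** 2
    det = np.where(det > 0, det, np.finfo(float).tiny)
    W = (g22 * b1 - g12 * b2) / det
    F = (g11 * b2 - np.conj(g12) * b1) / det
    s2 = (np.abs(S) ** 2).sum(axis=1)
    res2 = s2 - np.real(np.conj(b1) * W + np.conj(b2) * F)
    return W, F, np.maximum(res2, 0.0)


def _coarse_search(S, t, c, cfg: FitConfig, shape=None):
    """Global grid search over (f0, R2*); returns per-voxel best pair.

    Uses orthonormalized candidate bases stacked into one matrix so the
    residual reduction for every voxel x candidate is a single GEMM.

    When ``shape`` is given and ``cfg.coarse_neighborhood > 1`` the
    per-candidate residual reduction is averaged over a spatial box before
    the argmax.  Summing the variable-projection likelihood over neighbors
    is the joint estimate of a locally shared field map with free per-voxel
    amplitudes; it resolves the f0 ambiguities (period aliases, fat-water
    exchange) toward the branch consistent with the neighborhood.
    """
    f0s = cfg.f0_grid()
    r2ss = cfg.r2s_grid()
    ff, rr = np.meshgrid(f0s, r2ss, indexing="ij")
    cand_f0 = ff.ravel()
    cand_r2s = rr.ravel()
    ncand = cand_f0.size

    decay = np.exp(-cand_r2s[:, None] * t[None, :])
    e = decay * np.exp(2j * np.pi * cand_f0[:, None] * t[None, :])
    A = np.stack([e, c[None, :] * e], axis=-1)              # (ncand, NE, 2)
    Q, _ = np.linalg.qr(A)
    M = np.conj(Q.transpose(1, 0, 2).reshape(t.size, ncand * 2))  # (NE, 2*ncand)

    # For species-pure voxels and uniform echo spacing the landscape is
    # exactly periodic in f0 with period 1/dTE, so noise alone can tip the
    # argmax into an alias.  A small relative penalty growing with |f0|
    # breaks those ties toward the smallest off-resonance while leaving
    # genuinely discriminated minima (fat-anchored, or noise-driven swaps)
    # untouched.
    tiebreak = (1.0 - cfg.f0_penalty_per_hz * np.abs(cand_f0)).astype(np.float32)

    n = S.shape[0]
    spatial = shape is not None and cfg.coarse_neighborhood > 1
    best_val = np.full(n, -np.inf, dtype=np.float32)
    best = np.zeros(n, dtype=np.int64)
    # Chunk over candidates: each candidate's reduction is needed for all
    # voxels at once when spatial aggregation is on.
    cchunk = max(1, min(ncand, int(2**25 // max(n, 1)) or 1)) if spatial else ncand
    for clo in range(0, ncand, cchunk):
        chi = min(clo + cchunk, ncand)
        Mc = M[:, 2 * clo : 2 * chi]
        red = np.empty((n, chi - clo), dtype=np.float32)
        for lo in range(0, n, cfg.chunk):
            hi = min(lo + cfg.chunk, n)
            P = S[lo:hi] @ Mc
            red[lo:hi] = (np.abs(P[:, 0::2]) ** 2 + np.abs(P[:, 1::2]) ** 2).astype(
                np.float32
            )
        if spatial:
            k = cfg.coarse_neighborhood
            red = red.reshape(shape + (chi - clo,))
            red = ndimage.uniform_filter(red, size=(k, k, k, 1), mode="nearest")
            red = red.reshape(n, chi - clo)
        red *= tiebreak[None, clo:chi]
        cand_best = np.argmax(red, axis=1)
        cand_val = np.take_along_axis(red, cand_best[:, None], axis=1)[:, 0]
        better = cand_val > best_val
        best[better] = cand_best[better] + clo
        best_val[better] = cand_val[better]
    return cand_f0[best], cand_r2s[best]


def _refine(S, t, c, f0, r2s, cfg: FitConfig, vary_f0=True, vary_r2s=True):
    """Per-voxel parabolic coordinate refinement of (f0, R2*)."""
    f0 = f0.astype(float).copy()
    r2s = r2s.astype(float).copy()
    r2s_lo, r2s_hi = cfg.r2s_range
    step_f = np.full_like(f0, cfg.f0_step_hz * 0.5)
    step_r = np.full_like(r2s, cfg.r2s_step * 0.5)
    coords = [w for w, on in (("f0", vary_f0), ("r2s", vary_r2s)) if on]

    def res2_at(f, r):
        return _project(S, t, c, f, np.clip(r, r2s_lo, r2s_hi))[2]

    for _ in range(cfg.n_refine):
        for which in coords:
            if which == "f0":
                step, x = step_f, f0
                rm = res2_at(x - step, r2s)
                r0 = res2_at(x, r2s)
                rp = res2_at(x + step, r2s)
            else:
                step, x = step_r, r2s
                rm = res2_at(f0, x - step)
                r0 = res2_at(f0, x)
                rp = res2_at(f0, x + step)
            denom = rp - 2.0 * r0 + rm
            with np.errstate(invalid="ignore", divide="ignore"):
                shift = np.where(denom > 0, 0.5 * (rm - rp) / np.where(denom != 0, denom, 1.0), 0.0)
            shift = np.clip(shift, -1.0, 1.0) * step
            # Fall back to the best of the three probes where the parabola
            # is degenerate or the landscape locally concave.
            three = np.stack([rm, r0, rp])
            pick = np.argmin(three, axis=0)
            fallback = (pick.astype(float) - 1.0) * step
            shift = np.where(denom > 0, shift, fallback)
            if which == "f0":
                f0 = x + shift
            else:
                r2s = np.clip(x + shift, r2s_lo, r2s_hi)
        step_f *= 0.5
        step_r *= 0.5
    return f0, r2s


def _r2s_sweep(S, t, c, f0, r2s, cfg: FitConfig):
    """Escape wrong decay basins: per-voxel scan of the R2* grid at the
    refined f0, re-refining voxels that prefer a different basin."""
    grid = cfg.r2s_grid()
    res = np.stack([_project(S, t, c, f0, np.full(f0.shape, r))[2] for r in grid])
    best = grid[np.argmin(res, axis=0)]
    cur = _project(S, t, c, f0, r2s)[2]
    swept = np.minimum(res.min(axis=0), np.inf)
    move = (np.abs(best - r2s) > cfg.r2s_step / 2) & (swept < cur)
    if move.any():
        nf0, nr2s = _refine(S[move], t, c, f0[move], best[move], cfg)
        f0 = f0.copy()
        r2s = r2s.copy()
        f0[move], r2s[move] = nf0, nr2s
    return f0, r2s


def _fit_flat(S, t, c, cfg: FitConfig):
    """Coarse + refine on flat (N, NE) signals; returns W, F, f0, r2s, res2."""
    f0, r2s = _coarse_search(S, t, c, cfg)
    f0, r2s = _refine(S, t, c, f0, r2s, cfg)
    f0, r2s = _r2s_sweep(S, t, c, f0, r2s, cfg)
    W, F, res2 = _project(S, t, c, f0, r2s)
    return W, F, f0, r2s, res2


def varpro_fit_voxel(
    signal: Sequence[complex],
    echo_times_s: Sequence[float],
    spectrum: FatSpectrum | None = None,
    config: FitConfig | None = None,
    system: SystemConfig | None = None,
):
    """Fit one voxel; returns (W, F, f0, r2star, residual).

    Requires at least 4 echoes (4 unknowns).  An all-zero signal returns
    zero amplitudes, zero residual and the search-range defaults for
    (f0, R2*); callers can detect it by the zero amplitudes.
    """
    cfg = config or FitConfig()
    spectrum = spectrum or default_fat_spectrum()
    S = np.asarray(signal, dtype=complex).reshape(1, -1)
    t = np.asarray(echo_times_s, dtype=float)
    if S.shape[1] != t.size:
        raise ValueError("signal and echo_times length mismatch")
    if t.size < 4:
        raise ValueError("need at least 4 echoes to fit W, F, f0 and R2*")
    if not np.all(np.isfinite(S.view(float))):
        raise ValueError("signal contains non-finite values")
    if np.all(S == 0):
        return 0j, 0j, 0.0, cfg.r2s_range[0], 0.0
    c = fat_phasor(spectrum, t, system)
    W, F, f0, r2s, res2 = _fit_flat(S, t, c, cfg)
    return complex(W[0]), complex(F[0]), float(f0[0]), float(r2s[0]), float(np.sqrt(res2[0]))


def fit_volume(
    vol,
    spectrum: FatSpectrum | None = None,
    config: FitConfig | None = None,
    system: SystemConfig | None = None,
) -> FatWaterResult:
    """Fit every voxel of a multi-echo volume, then apply the field-map
    consistency constraint.

    ``vol`` is a :class:`csemri.silico.MultiEchoVolume` (or any object with
    ``data`` shaped (x, y, z, echo) and ``echo_times_s``).  Non-finite or
    all-zero voxels are masked as degenerate, never aborting the volume.
    The result is deterministic and invariant to voxel ordering: the
    constraint depends only on the 3-D neighborhood structure.
    """
    cfg = config or FitConfig()
    spectrum = spectrum or default_fat_spectrum()
    data = np.asarray(vol.data)
    t = np.asarray(vol.echo_times_s, float)
    if t.size < 4:
        raise ValueError("need at least 4 echoes to fit W, F, f0 and R2*")
    shape = data.shape[:-1]
    S = data.reshape(-1, t.size).astype(complex)

    finite = np.all(np.isfinite(S.view(float).reshape(S.shape[0], -1)), axis=1)
    nonzero = np.any(S != 0, axis=1)
    ok = finite & nonzero
    c = fat_phasor(spectrum, t, system)

    W = np.zeros(S.shape[0], complex)
    F = np.zeros(S.shape[0], complex)
    f0 = np.zeros(S.shape[0])
    r2s = np.full(S.shape[0], cfg.r2s_range[0])
    res2 = np.zeros(S.shape[0])
    if ok.any():
        # Coarse search runs on the full spatial layout (masked voxels are
        # zeroed and contribute nothing) so neighborhood aggregation sees
        # the true geometry; refinement then touches only valid voxels.
        S_masked = np.where(ok[:, None], S, 0.0)
        cshape = shape if cfg.coarse_neighborhood > 1 else None
        f0c, r2c = _coarse_search(S_masked, t, c, cfg, shape=cshape)
        f0r, r2r = _refine(S[ok], t, c, f0c[ok], r2c[ok], cfg)
        f0[ok], r2s[ok] = _r2s_sweep(S[ok], t, c, f0r, r2r, cfg)
        W[ok], F[ok], res2[ok] = _project(S[ok], t, c, f0[ok], r2s[ok])

    # Field-map consistency constraint: voxels whose B0 deviates from the
    # local median are re-fitted starting from that median; the smooth
    # solution is kept when its residual is competitive.
    for _ in range(cfg.n_local_iters):
        f0_map = f0.reshape(shape)
        f0_med = ndimage.median_filter(f0_map, size=cfg.fieldmap_size, mode="nearest")
        dev = np.abs(f0_map - f0_med).reshape(-1)
        flagged = ok & (dev > cfg.fieldmap_threshold_hz)
        if not flagged.any():
            break
        idx = np.flatnonzero(flagged)
        f0_init = f0_med.reshape(-1)[idx]
        nf0, nr2s = _refine(S[idx], t, c, f0_init, r2s[idx], cfg)
        nW, nF, nres2 = _project(S[idx], t, c, nf0, nr2s)
        accept = nres2 <= cfg.constraint_slack * res2[idx]
        upd = idx[accept]
        W[upd], F[upd] = nW[accept], nF[accept]
        f0[upd], r2s[upd], res2[upd] = nf0[accept], nr2s[accept], nres2[accept]

    # Final smoothing pass: the field map is a smooth nuisance parameter, so
    # adopt its local median everywhere and re-estimate R2* and the linear
    # amplitudes with f0 fixed.  This is what makes the estimate "constrained":
    # B0 noise no longer propagates voxel-wise into PDFF.
    if cfg.smooth_fieldmap and ok.any():
        f0_sm = ndimage.median_filter(
            f0.reshape(shape), size=cfg.fieldmap_size, mode="nearest"
        ).reshape(-1)
        idx = np.flatnonzero(ok)
        f0[idx] = f0_sm[idx]
        _, r2s[idx] = _refine(
            S[idx], t, c, f0[idx], r2s[idx], cfg, vary_f0=False, vary_r2s=True
        )
        W[idx], F[idx], res2[idx] = _project(S[idx], t, c, f0[idx], r2s[idx])

    # Magnitude debiasing: |W|^2 and |F|^2 are noncentral quantities whose
    # expectation exceeds the true squared amplitude by twice the per-
    # component estimator variance (CRLB diagonal of the linear subproblem).
    # Subtracting that, with the noise level read off the fit residual,
    # symmetrizes the PDFF bias near the 0% and 100% edges where plain
    # magnitudes rectify noise upward.
    aW, aF = np.abs(W), np.abs(F)
    if cfg.debias_amplitudes and ok.any():
        dof = max(2 * t.size - 6, 2)
        # Robust volume-wide noise level: the median residual is immune to
        # the inflated residuals of swapped or otherwise misfit voxels.
        sigma2 = np.median(res2[ok]) / dof
        decay2 = np.exp(-2.0 * np.outer(r2s, t))
        g11 = decay2.sum(axis=1)
        g22 = decay2 @ (np.abs(c) ** 2)
        g12 = decay2 @ c
        det = np.maximum(g11 * g22 - np.abs(g12) ** 2, np.finfo(float).tiny)
        var_w = 2.0 * sigma2 * g22 / det
        var_f = 2.0 * sigma2 * g11 / det
        # sqrt(max(|X|^2 - 2s^2, 0)) is unbiased in the squared domain but
        # carries a -s^2/(2A) Jensen deficit; the second term refills it
        # (bounded near A = 0 where the clamp takes over).
        mW = np.maximum(aW**2 - var_w, 0.0)
        mF = np.maximum(aF**2 - var_f, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            aW = np.sqrt(mW) + np.where(var_w > 0, 0.5 * var_w / np.sqrt(mW + np.where(var_w > 0, var_w, 1.0)), 0.0)
            aF = np.sqrt(mF) + np.where(var_f > 0, 0.5 * var_f / np.sqrt(mF + np.where(var_f > 0, var_f, 1.0)), 0.0)

    pdff = compute_pdff(aW, aF)

    # Signed fraction: demodulate the common phase, take real parts.  The
    # denominator Re((W+F) e^{-i phi}) equals |W+F|, so it is non-negative
    # and the estimate is symmetric (and hence unbiased) under noise even
    # where the true fraction sits on the 0 or 100 % boundary.
    tot = W + F
    denom = np.abs(tot)
    phase = np.where(denom > 0, tot / np.where(denom > 0, denom, 1.0), 1.0)
    f_r = np.real(F * np.conj(phase))
    pdff_signed = np.where(denom > 0, 100.0 * f_r / np.where(denom > 0, denom, 1.0), 0.0)

    return FatWaterResult(
        water=W.reshape(shape),
        fat=F.reshape(shape),
        f0_map=f0.reshape(shape),
        r2star_map=r2s.reshape(shape),
        pdff_map=np.asarray(pdff).reshape(shape),
        residual_map=np.sqrt(res2).reshape(shape),
        degenerate=(~ok).reshape(shape),
        pdff_signed_map=pdff_signed.reshape(shape),
    )
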