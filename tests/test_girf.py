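import numpy as np
import pytest

from csemri.girf import (
    GIRFModel,
    GradientWaveform,
    apply_girf,
    apply_timing_calibration,
    echo_center_times,
    echo_parity_shift,
    estimate_girf,
    integrate_trajectory,
    synth_gradient_system,
    thin_slice_measurement,
    triangle_probes,
)
from csemri.phyllotaxis import ReadoutDesign, build_readout
from csemri.spectrum import SystemConfig, scheme_presets


def pure_delay_model(tau, axes=("x",), fmax=50e3, n=4097):
    f = np.linspace(-fmax, fmax, n)
    H = np.tile(np.exp(-2j * np.pi * f * tau), (len(axes), 1))
    return GIRFModel(f, H, axes)


@pytest.fixture(scope="module")
def chain():
    return synth_gradient_system()


@pytest.fixture(scope="module")
def bipolar_readout():
    return build_readout(ReadoutDesign(), scheme_presets("bipolar3T"))


class TestSynthSystem:
    def test_identity_limit(self):
        g = synth_gradient_system(delays_s=(0.0,), resonances=[[]], lowpass_cutoff_hz=np.inf,
                                  axes=("x",))
        np.testing.assert_allclose(g.H[0], 1.0, atol=1e-12)

    def test_pure_delay_phase_slope(self):
        tau = 3e-6
        g = synth_gradient_system(delays_s=(tau,), resonances=[[]],
                                  lowpass_cutoff_hz=np.inf, axes=("x",))
        phase = np.unwrap(np.angle(g.H[0]))
        slope = np.polyfit(g.freqs, phase, 1)[0]
        assert slope == pytest.approx(-2 * np.pi * tau, rel=1e-9)

    def test_default_chain_shape(self, chain):
        i0 = np.argmin(np.abs(chain.freqs))
        assert np.all(np.abs(np.abs(chain.H[:, i0]) - 1.0) < 1e-2)
        # notches sit in the 3.3-4 kHz band
        band = (np.abs(chain.freqs) > 3.2e3) & (np.abs(chain.freqs) < 4.1e3)
        assert np.abs(chain.H[0][band]).min() < 0.95
        assert chain.delays_s[2] == pytest.approx(2.5e-6, abs=1e-7)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            synth_gradient_system(lowpass_cutoff_hz=0.0)


class TestThinSlice:
    def test_identity_system_recovers_probe(self):
        ident = GIRFModel.identity(axes=("x",))
        p = triangle_probes()[4]
        m = thin_slice_measurement(ident, p, axis="x")
        assert np.abs(m.samples - p.samples).max() < 1e-6

    def test_pure_delay_shifts_probe(self):
        tau = 3e-5  # 3 raster steps
        m = thin_slice_measurement(pure_delay_model(tau), triangle_probes()[4], axis="x")
        p = triangle_probes()[4].samples[0]
        xc = [np.dot(np.roll(p, s), m.samples[0]) for s in range(8)]
        assert int(np.argmax(xc)) == 3

    def test_slice_offset_cancels(self, chain):
        p = triangle_probes(axis="z")[2]
        m1 = thin_slice_measurement(chain, p, axis="z", slice_offset_m=0.002)
        m2 = thin_slice_measurement(chain, p, axis="z", slice_offset_m=0.004)
        np.testing.assert_allclose(m1.samples, m2.samples, atol=1e-6)

    def test_zero_offset_rejected(self, chain):
        with pytest.raises(ValueError):
            thin_slice_measurement(chain, triangle_probes()[0], slice_offset_m=0.0)


class TestEstimateGirf:
    def test_self_deconvolution_is_identity(self):
        probes = triangle_probes()
        est = estimate_girf(probes, probes)
        band = est.probe_energy > 1e-2
        assert np.abs(est.H[0][band] - 1.0).max() < 1e-3

    def test_recovers_synthetic_system_in_band(self, chain):
        probes = triangle_probes(axis="z")
        measured = [thin_slice_measurement(chain, p, axis="z") for p in probes]
        est = estimate_girf(probes, measured)
        band = est.probe_energy > 1e-2
        true = np.interp(est.freqs, chain.freqs, chain.H[2].real) + 1j * np.interp(
            est.freqs, chain.freqs, chain.H[2].imag
        )
        rel = np.abs(est.H[0][band] - true[band]) / np.abs(true[band])
        assert rel.max() < 0.01

    def test_z_delay_recovered(self, chain):
        probes = triangle_probes(axis="z")
        measured = [thin_slice_measurement(chain, p, axis="z") for p in probes]
        est = estimate_girf(probes, measured)
        assert est.delays_s[0] == pytest.approx(2.5e-6, abs=5e-6 / 2)

    def test_noise_averaging_improves_recovery(self, chain):
        """Averaging repeated noisy measurements shrinks the H error."""
        probes = triangle_probes(axis="z")
        errs = []
        for n_avg in (1, 4, 16):
            measured = []
            for i, p in enumerate(probes):
                reps = [
                    thin_slice_measurement(chain, p, axis="z", noise_sd=0.05,
                                           seed=1000 * n_avg + 10 * i + r)
                    for r in range(n_avg)
                ]
                avg = np.mean([m.samples[0] for m in reps], axis=0)
                measured.append(GradientWaveform(p.dt, avg, ("z",)))
            est = estimate_girf(probes, measured)
            band = est.probe_energy > 1e-2
            true = np.interp(est.freqs, chain.freqs, chain.H[2].real) + 1j * np.interp(
                est.freqs, chain.freqs, chain.H[2].imag
            )
            errs.append(np.sqrt(np.mean(np.abs(est.H[0][band] - true[band]) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            estimate_girf([], [])


class TestApplyGirf:
    def test_identity_map(self, bipolar_readout):
        ident = GIRFModel.identity()
        out = apply_girf(bipolar_readout, ident, axes=("x",))
        assert np.abs(out.samples - bipolar_readout.samples).max() < 1e-9

    def test_one_raster_delay_shifts_samples(self):
        p = triangle_probes()[5]
        out = apply_girf(p, pure_delay_model(p.dt), axes=("x",))
        np.testing.assert_allclose(out.samples[0][1:], p.samples[0][:-1], atol=1e-6)

    def test_linearity(self, chain):
        p1, p2 = triangle_probes()[2], triangle_probes()[6]
        a, b = 1.7, -0.6
        combo = GradientWaveform(p1.dt, a * p1.samples + b * p2.samples, ("x",))
        lhs = apply_girf(combo, chain).samples
        rhs = a * apply_girf(p1, chain).samples + b * apply_girf(p2, chain).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestTrajectoryIntegration:
    def test_constant_gradient_linear_ramp(self):
        sc = SystemConfig()
        g = GradientWaveform(1e-5, np.full(200, 10.0), ("x",))
        kt = integrate_trajectory(g, sc, fov_m=0.22)
        expected = sc.gamma_hz_per_t * 10e-3 * 199e-5 * 0.22
        assert kt.k[0, -1] == pytest.approx(expected, rel=1e-12)

    def test_balanced_bipolar_pair_returns_to_zero(self):
        lobe = np.concatenate([np.linspace(0, 20, 10), np.full(30, 20.0),
                               np.linspace(20, 0, 10)])
        wave = np.concatenate([lobe, -lobe])
        kt = integrate_trajectory(GradientWaveform(1e-5, wave, ("x",)), fov_m=0.22)
        assert abs(kt.k[0, -1]) < 1e-9

    def test_delay_shifts_plateau_k(self):
        sc = SystemConfig()
        tau = 2e-5
        wave = np.concatenate([np.linspace(0, 15, 20), np.full(380, 15.0)])
        g = GradientWaveform(1e-5, wave, ("x",))
        gd = apply_girf(g, pure_delay_model(tau), axes=("x",))
        k1 = integrate_trajectory(g, sc, fov_m=0.22)
        k2 = integrate_trajectory(gd, sc, fov_m=0.22)
        expected = sc.gamma_hz_per_t * 15e-3 * tau * 0.22
        mid = slice(100, 300)
        assert np.mean(k1.k[0, mid] - k2.k[0, mid]) == pytest.approx(expected, rel=1e-4)


class TestEchoParity:
    def test_identity_zero_shift(self, bipolar_readout):
        kt = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                  echo_slices=bipolar_readout.echo_slices)
        assert echo_parity_shift(kt, kt) == (0.0, 0.0)

    def test_uniform_even_only_shift(self, bipolar_readout):
        kt = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                  echo_slices=bipolar_readout.echo_slices)
        shifted = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                       echo_slices=bipolar_readout.echo_slices)
        for sl, par in zip(shifted.echo_slices, shifted.parity):
            if par == "even":
                shifted.k[:, sl] += 1.0
        ev, od = echo_parity_shift(kt, shifted)
        assert ev == pytest.approx(1.0) and od == pytest.approx(0.0)

    def test_delay_system_parity_split(self, chain, bipolar_readout):
        """Distorted bipolar readout: opposite-sign even/odd shifts, and a
        first-echo calibration leaves even echoes more affected."""
        kt = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                  echo_slices=bipolar_readout.echo_slices)
        rox = GradientWaveform(bipolar_readout.dt, bipolar_readout.samples, ("x",))
        dist = apply_girf(rox, chain)
        ktd = integrate_trajectory(dist, fov_m=0.22, echo_slices=bipolar_readout.echo_slices)
        ev, od = echo_parity_shift(kt, ktd)
        assert ev * od < 0  # opposite signs
        cal = apply_timing_calibration(ktd, kt)
        ev2, od2 = echo_parity_shift(kt, cal)
        assert abs(od2) < 0.01
        assert abs(ev2) > abs(od2)

    def test_pure_delay_fully_calibrated(self, bipolar_readout):
        kt = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                  echo_slices=bipolar_readout.echo_slices)
        rox = GradientWaveform(bipolar_readout.dt, bipolar_readout.samples, ("x",))
        dist = apply_girf(rox, pure_delay_model(2.5e-6))
        ktd = integrate_trajectory(dist, fov_m=0.22, echo_slices=bipolar_readout.echo_slices)
        ev, od = echo_parity_shift(kt, ktd)
        assert ev * od < 0 and abs(abs(ev) - abs(od)) < 0.05
        cal = apply_timing_calibration(ktd, kt)
        ev2, od2 = echo_parity_shift(kt, cal)
        assert abs(ev2) < 0.02 and abs(od2) < 0.02

    def test_congruence_required(self, bipolar_readout):
        kt = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                  echo_slices=bipolar_readout.echo_slices)
        from csemri.girf import KTrajectory

        other = KTrajectory(kt.k[:, :-10], kt.times[:-10], kt.echo_slices, kt.parity)
        with pytest.raises(ValueError):
            echo_parity_shift(kt, other)


class TestRoundTrip:
    def test_estimated_girf_predicts_held_out_waveform(self, chain, bipolar_readout):
        """Measure on triangles, predict the multi-echo readout: <1% RMS."""
        probes = triangle_probes(axis="z")
        measured = [thin_slice_measurement(chain, p, axis="z") for p in probes]
        est = estimate_girf(probes, measured)
        ro = GradientWaveform(bipolar_readout.dt, bipolar_readout.samples, ("z",))
        truth = apply_girf(ro, chain, axes=("z",)).samples
        pred = apply_girf(ro, est, axes=("z",)).samples
        rms = np.sqrt(np.mean((truth - pred) ** 2)) / np.sqrt(np.mean(truth**2))
        assert rms < 0.01

    def test_echo_centers_on_schedule(self, bipolar_readout):
        kt = integrate_trajectory(bipolar_readout, fov_m=0.22,
                                  echo_slices=bipolar_readout.echo_slices)
        centers_ms = echo_center_times(kt) * 1e3
        sch = scheme_presets("bipolar3T")
        assert np.abs(centers_ms - sch.echo_times()).max() <= 0.01 + 1e-9
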