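import numpy as np
import pytest

from csemri.phantoms import Disk, DiskPhantom, DynamicPhantom
from csemri.recon import (
    ReconConfig,
    admm_tv_recon,
    assign_bins,
    bipolar_artifact_experiment,
    extract_selfgating,
    golden_radial_2d,
    nufft_gridding_recon,
    svd_coil_compress,
    uniform_radial_2d,
)

SEG_DT = 0.195  # 13 TRs of 15 ms: the self-gating sampling interval (~5 Hz)


@pytest.fixture(scope="module")
def gating_series():
    dp = DynamicPhantom()
    t = np.arange(240) * SEG_DT
    prof = np.stack([dp.projection(tk) for tk in t])
    return dp, t, extract_selfgating(prof, t)


class TestSelfGating:
    def test_respiratory_signal_recovered(self, gating_series):
        dp, t, sg = gating_series
        truth = np.sin(2 * np.pi * dp.resp_freq_hz * t)
        r = np.corrcoef(sg.respiratory, truth)[0, 1]
        assert abs(r) > 0.95

    def test_cardiac_frequency_recovered(self, gating_series):
        from scipy.signal import periodogram

        dp, t, sg = gating_series
        f, p = periodogram(sg.cardiac, fs=sg.sampling_rate_hz)
        assert f[np.argmax(p)] == pytest.approx(dp.card_freq_hz, abs=0.1)

    def test_static_phantom_yields_quiet_signals(self, gating_series):
        _, t, sg_moving = gating_series
        static = DynamicPhantom(resp_amp_px=0.0, card_amp=0.0)
        prof = np.stack([static.projection(tk) for tk in t])
        sg = extract_selfgating(prof, t)
        assert np.var(sg.respiratory) < 0.01 * np.var(sg_moving.respiratory)
        assert np.var(sg.cardiac) < 0.01 * np.var(sg_moving.cardiac)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            extract_selfgating(np.ones((5, 16)), np.arange(5) * SEG_DT)


class TestBinning:
    def test_metronome_heart_gives_rr_over_width_bins(self):
        """RR of exactly 1000 ms with 100 ms windows -> 10 cardiac bins."""
        from csemri.recon import SelfGatingSeries

        t = np.arange(0, 60, SEG_DT)
        card = np.cos(2 * np.pi * 1.0 * t)  # 1 Hz heart
        resp = np.sin(2 * np.pi * 0.25 * t)
        sg = SelfGatingSeries(t, resp, card, 1.0 / SEG_DT)
        spokes = np.arange(0.0, 59.0, 0.015)
        plan = assign_bins(sg, spokes, n_resp_bins=4, cardiac_bin_width_ms=100.0)
        assert plan.n_cardiac_bins in (9, 10, 11)  # RR from peak detection at ~5 Hz
        counts = np.bincount(plan.resp_bin, minlength=4)
        assert counts.max() - counts.min() <= counts.mean() * 0.1
        assert plan.resp_bin.size == spokes.size
        assert np.all(plan.cardiac_bin >= 0) and np.all(plan.cardiac_bin < plan.n_cardiac_bins)

    def test_spoke_conservation_across_bins(self, gating_series):
        _, t, sg = gating_series
        spokes = np.arange(0.0, t[-1], 0.015)
        plan = assign_bins(sg, spokes)
        total = 0
        for r in range(plan.n_resp_bins):
            for c in range(plan.n_cardiac_bins):
                total += int(np.sum((plan.resp_bin == r) & (plan.cardiac_bin == c)))
        assert total == spokes.size

    def test_flat_cardiac_signal_rejected(self):
        from csemri.recon import SelfGatingSeries

        t = np.arange(0, 30, SEG_DT)
        sg = SelfGatingSeries(t, np.sin(t), np.zeros_like(t) - 1.0, 1.0 / SEG_DT)
        with pytest.raises(ValueError):
            assign_bins(sg, np.arange(0.0, 29.0, 0.015))


class TestCoilCompression:
    def test_rank_one_compresses_to_single_coil(self):
        rng = np.random.default_rng(0)
        sens = np.exp(1j * np.linspace(0, 2, 8))
        data = sens[:, None] * (rng.normal(size=500) + 1j * rng.normal(size=500))
        comp, rep = svd_coil_compress(data, 0.02)
        assert rep["n_coils_out"] == 1
        assert rep["energy_retained"] == pytest.approx(1.0)

    def test_zero_threshold_preserves_everything(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(6, 300)) + 1j * rng.normal(size=(6, 300))
        comp, rep = svd_coil_compress(data, 0.0)
        assert rep["n_coils_out"] == 6
        # unitary compression: total energy preserved exactly
        assert np.sum(np.abs(comp) ** 2) == pytest.approx(np.sum(np.abs(data) ** 2))

    def test_smooth_sensitivities_compress_losslessly(self):
        """24 coils with smooth sensitivities: 2% threshold keeps the
        signal subspace, so the compressed recon matches the full one."""
        n = 32
        ph = DiskPhantom(n, [Disk(0, 0, 10, 1.0)])
        k = uniform_radial_2d(48, n, 2 * n).reshape(-1, 2)
        y0 = ph.kspace(k)
        # 5 spatial modes = phantom shifted by smooth sensitivity lobes;
        # 24 coils are smooth mixtures of them, so the data have rank 5.
        shifts = np.linspace(-3, 3, 5)
        modes = np.stack([y0 * np.exp(-2j * np.pi * k[:, 0] * s / n) for s in shifts])
        x = np.linspace(-1, 1, 24)
        A = np.exp(-2.0 * (x[:, None] - np.linspace(-1, 1, 5)[None, :]) ** 2)
        coil_y = A @ modes
        comp, rep = svd_coil_compress(coil_y, 0.02)
        full = np.sqrt(sum(np.abs(nufft_gridding_recon(c, k, (n, n))) ** 2 for c in coil_y))
        red = np.sqrt(sum(np.abs(nufft_gridding_recon(c, k, (n, n))) ** 2 for c in comp))
        assert rep["n_coils_out"] <= 5
        assert np.linalg.norm(full - red) / np.linalg.norm(full) < 0.01

    def test_empty_coil_axis_rejected(self):
        with pytest.raises(ValueError):
            svd_coil_compress(np.zeros(10))


class TestGridding:
    def test_fully_sampled_disk_benchmark(self):
        """Uniform-angle radial sampling reconstructs the bandlimited disk
        phantom within 5% NRMSE."""
        n = 48
        ph = DiskPhantom(n, [Disk(0, 0, 14, 1.0), Disk(5, -4, 4, -0.5)])
        kx = np.arange(n) - n / 2
        KX, KY = np.meshgrid(kx, kx, indexing="ij")
        spec = ph.kspace(np.stack([KX.ravel(), KY.ravel()], 1)).reshape(n, n)
        mask = np.hypot(KX, KY) <= n / 2
        ref = np.abs(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec * mask))))
        k = uniform_radial_2d(int(np.ceil(np.pi / 2 * n)), n, 2 * n).reshape(-1, 2)
        img = np.abs(nufft_gridding_recon(ph.kspace(k), k, (n, n)))
        assert np.linalg.norm(img - ref) / np.linalg.norm(ref) < 0.05

    def test_zero_data_zero_image(self):
        k = golden_radial_2d(10, 16).reshape(-1, 2)
        img = nufft_gridding_recon(np.zeros(k.shape[0]), k, (16, 16))
        assert np.all(img == 0)

    def test_empty_bin_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            img = nufft_gridding_recon(np.zeros(0), np.zeros((0, 2)), (8, 8))
        assert np.all(img == 0)


def _binned_phantom_acquisition(spokes_per_bin, R=2, C=6, n=32):
    dp = DynamicPhantom(n=n)
    ks_all = golden_radial_2d(R * C * spokes_per_bin, n)
    binned_y, binned_k, refs = [], [], []
    i = 0
    for r in range(R):
        row_y, row_k = [], []
        for c in range(C):
            ph = dp.phantom_at((c + 0.5) / C / dp.card_freq_hz + 17.0 * r)
            k = ks_all[i : i + spokes_per_bin].reshape(-1, 2)
            i += spokes_per_bin
            row_y.append(ph.kspace(k))
            row_k.append(k)
            refs.append(np.abs(ph.image()))
        binned_y.append(row_y)
        binned_k.append(row_k)
    return binned_y, binned_k, refs


def _bin_nrmse(images, refs):
    errs = []
    j = 0
    for r in range(len(images)):
        for c in range(images.shape[1]):
            ref = refs[j]
            j += 1
            img = np.abs(images[r, c])
            sc = np.sum(img * ref) / max(np.sum(img * img), 1e-30)
            errs.append(np.linalg.norm(sc * img - ref) / np.linalg.norm(ref))
    return float(np.mean(errs))


class TestAdmm:
    def test_objective_monotone_with_default_parameters(self):
        binned_y, binned_k, _ = _binned_phantom_acquisition(4)
        x, info = admm_tv_recon(binned_y, binned_k, (32, 32))
        obj = np.array(info["objective"])
        assert obj.size == ReconConfig().n_iter + 1
        assert np.all(np.diff(obj[2:]) <= 1e-6 * obj[2])

    def test_cs_beats_gridding_at_high_undersampling(self):
        binned_y, binned_k, refs = _binned_phantom_acquisition(3)
        x, info = admm_tv_recon(binned_y, binned_k, (32, 32))
        e_admm = _bin_nrmse(x, refs)
        e_grid = _bin_nrmse(info["gridding"], refs)
        assert e_admm < 0.7 * e_grid  # >= 30% NRMSE improvement

    def test_zero_lambda_full_sampling_matches_gridding(self):
        n = 32
        ph = DiskPhantom(n, [Disk(0, 0, 10, 1.0)])
        k = uniform_radial_2d(int(np.pi / 2 * n) + 1, n, 2 * n)
        y = ph.kspace(k.reshape(-1, 2))
        cfg = ReconConfig(lambda_s=0.0, lambda_c=0.0, lambda_r=0.0, rho=0.06, n_iter=6, n_cg=12)
        x, info = admm_tv_recon([[y]], [[k.reshape(-1, 2)]], (n, n), cfg)
        # with no regularization the solution is plain least squares:
        # data-consistent to <1% and close to the gridding image
        from csemri.nufft import NufftOperator

        op = NufftOperator((n, n), k.reshape(-1, 2))
        resid = np.linalg.norm(op.forward(x[0, 0]) - y / info["scale"])
        assert resid / np.linalg.norm(y / info["scale"]) < 0.01
        g = info["gridding"][0, 0]
        assert np.linalg.norm(np.abs(x[0, 0]) - np.abs(g)) / np.linalg.norm(g) < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(lambda_s=-1.0)
        with pytest.raises(ValueError):
            ReconConfig(n_iter=0)


class TestTrajectoryCorrection:
    def test_corrected_echoes_more_consistent(self):
        """GIRF-corrected gridding removes the even/odd-echo inconsistency
        caused by distorted bipolar readout trajectories."""
        res = bipolar_artifact_experiment()
        assert res["corrected"] < res["nominal"]
        assert res["nominal"] / res["corrected"] > 2.0

    def test_identity_chain_has_no_inconsistency(self):
        from csemri.girf import GIRFModel

        res = bipolar_artifact_experiment(
            girf_model=GIRFModel.identity(fmax=260e3, n=8193)
        )
        assert res["nominal"] == pytest.approx(res["corrected"], abs=1e-12)
        assert res["nominal"] < 1e-9
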