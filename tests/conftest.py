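import numpy as np
import pytest

from csemri.ideal import fit_volume
from csemri.silico import (
    SilicoGrid,
    accuracy_report,
    add_complex_noise,
    generate_silico_volume,
    normalize_volume,
)
from csemri.spectrum import SystemConfig, default_fat_spectrum, scheme_presets


@pytest.fixture(scope="session")
def spectrum():
    return default_fat_spectrum()


@pytest.fixture(scope="session")
def system():
    return SystemConfig()


@pytest.fixture(scope="session")
def bipolar():
    return scheme_presets("bipolar3T")


@pytest.fixture(scope="session")
def monopolar():
    return scheme_presets("monopolar3T")


def run_silico_study(scheme, snr, seeds, spectrum, n_reps=2, fit_config=None):
    """Generate-fit-score one scheme/SNR condition, averaged over seeds."""
    reports = []
    for seed in seeds:
        grid = SilicoGrid(n_reps=n_reps, snr=snr, seed=seed)
        vol = add_complex_noise(
            normalize_volume(generate_silico_volume(grid, scheme, spectrum)), snr, seed
        )
        reports.append(accuracy_report(grid, fit_volume(vol, spectrum, fit_config)))
    return reports


@pytest.fixture(scope="session")
def silico_metrics(spectrum, bipolar, monopolar):
    """Scaled in-silico study: both schemes, both SNRs, 3 seeds.

    Session-scoped because the four fits dominate suite runtime; every
    accuracy-related test reads from this cache.
    """
    seeds = (1, 2, 3)
    out = {}
    for name, scheme in (("bipolar", bipolar), ("monopolar", monopolar)):
        for snr in (10, 50):
            reps = run_silico_study(scheme, snr, seeds, spectrum)
            out[(name, snr)] = {
                "bias": float(np.mean([r.mean_bias_pdff for r in reps])),
                "abs_err": float(np.mean([r.mean_abs_err_pdff for r in reps])),
                "r2s_bias": float(np.mean([r.mean_bias_r2s for r in reps])),
                "max_r2s_err": float(np.mean([r.max_abs_err_r2s_over_pdff for r in reps])),
                "reports": reps,
            }
    return out
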