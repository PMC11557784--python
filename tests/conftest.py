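import numpy as np
import pytest

from piva import synthetic_data as syn

FS = 1000.0
WINDOW = 8192


def exact_bin_rate(k: int, n: int = WINDOW, fs: float = FS) -> float:
    """Compression rate (per minute) whose frequency sits exactly on bin k."""
    return 60.0 * k * fs / n


@pytest.fixture(scope="session")
def default_recording():
    """Noiseless default recording + ground truth (session-cached)."""
    cfg = syn.SimConfig()
    return syn.generate_recording(cfg)


@pytest.fixture(scope="session")
def noisy_recording():
    cfg = syn.SimConfig(noise_sd=0.15, rng_seed=7)
    return syn.generate_recording(cfg)


@pytest.fixture(scope="session")
def calibration_recording():
    """Constant-envelope, exact-bin tones: the spectral calibration scenario.

    Compression frequency on bin 27 and ventilation frequency on bin 8 of an
    8192-sample window at 1 kHz, constant envelope, no noise, CPR from t=0,
    so every fully-in-CPR window contains pure integer-cycle tones.
    """
    amp = 4.0
    sites = {
        site: syn.SiteEnvelope(12.0, amp, 27.0, 8.0, 8.0, shape="constant")
        for site in ("tail", "femoral", "central")
    }
    cfg = syn.SimConfig(
        pre_cpr_duration=0.0,
        cpr_duration=55.0,
        post_rosc_duration=5.0,
        compression_rate=exact_bin_rate(27),
        ventilation_rate=exact_bin_rate(8),
        sites=sites,
        noise_sd=0.0,
    )
    rec, truth = syn.generate_recording(cfg)
    return cfg, rec, truth, amp
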