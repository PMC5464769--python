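import numpy as np
import pytest

import chronolume as cl


@pytest.fixture(scope="session")
def ld_dd_schedule():
    """10 entrained days followed by 18 days of constant darkness."""
    return cl.concatenate_schedules([
        cl.build_light_schedule("LD12:12", 240.0),
        cl.build_light_schedule("DD", 432.0),
    ])


@pytest.fixture(scope="session")
def eeg_day():
    """One simulated LD12:12 day of EEG: ground-truth hypnogram, epoch
    signals and spectra (seed 0).  Shared across spectral tests."""
    config = cl.EEGSimConfig(seed=0)
    schedule = cl.build_light_schedule("LD12:12", 24.0)
    hyp = cl.simulate_hypnogram(config, schedule, 24.0)
    signals = cl.simulate_eeg_epochs(hyp, config, schedule)
    spectra = cl.compute_epoch_spectra(signals, config.sampling_hz)
    return {"config": config, "schedule": schedule, "hypnogram": hyp,
            "signals": signals, "spectra": spectra}


def make_spectra(power_rows, fmax=50.0):
    """EpochSpectra from a list of per-epoch power rows on a 0.25 Hz grid."""
    freqs = np.arange(0.0, fmax + 1e-9, 0.25)
    power = np.asarray(power_rows, dtype=float)
    assert power.shape[1] == freqs.size
    return cl.EpochSpectra(freqs_hz=freqs, power=power)


def flat_row(value=1.0, fmax=50.0):
    return np.full(int(round(fmax / 0.25)) + 1, float(value))


def theta_row(peak_hz=8.0, spike=149.0, base=1.0, fmax=50.0):
    """Flat base plus a single-bin spike; ratio = (spike + 9b) / (spike + 167b)
    on the default grid (9 bins within +-1 Hz, 167 bins in 3.5-45 Hz)."""
    row = flat_row(base, fmax)
    idx = int(round(peak_hz / 0.25))
    row[idx] += spike
    return row
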