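import numpy as np
import pytest

from zfseizure import profiles, sigio, synth


@pytest.fixture(scope="session")
def tl_profile():
    return profiles.get_profile("TL")


@pytest.fixture(scope="session")
def short_config():
    """Desk-scale recording: 2 min baseline + 5 min treatment at 500 Hz."""
    return profiles.SimulationConfig(
        sampling_rate=500.0, baseline_duration=120.0, treatment_duration=300.0,
        noise_sd=0.05, seed=11,
    )


def make_trace_with_events(
    events,
    noise_sd=0.05,
    fs=1000.0,
    baseline_s=120.0,
    treatment_s=300.0,
    seed=5,
    amp_seed=6,
):
    """Noise trace with waveforms injected at known places.

    ``events`` is a list of (start_s, duration_s, kind, amp_factor); kind
    selects the generator's SLE or IED waveform.  Returns (recording, events).
    """
    rng = np.random.default_rng(seed)
    wave_rng = np.random.default_rng(amp_seed)
    n = int((baseline_s + treatment_s) * fs)
    trace = rng.normal(0.0, noise_sd, n)
    for start, dur, kind, factor in events:
        wave = (
            synth._sle_waveform(dur, fs, wave_rng)
            if kind == "SLE"
            else synth._ied_waveform(dur, fs, wave_rng)
        )
        i0 = int(round(start * fs))
        trace[i0:i0 + len(wave)] += factor * noise_sd * wave
    rec = sigio.LFPRecording(
        samples=trace, sampling_rate=fs,
        baseline_end=baseline_s, treatment_end=baseline_s + treatment_s,
        subject={"id": "crafted", "genotype": "synthetic", "drugs": "PTZ"},
    )
    return rec
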