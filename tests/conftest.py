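import numpy as np
import pytest

from muscan import analysis, synth


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic generator conditions: no noise, every stimulus fires,
    no latency jitter, no probe drift."""
    return synth.GeneratorConfig(
        seed=3,
        noise_sd_uV=0.0,
        firing_probability=1.0,
        latency_jitter_sd_ms=0.0,
        drift_step_sd_px=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_scan(noise_free_config):
    return synth.generate_scan(noise_free_config)


@pytest.fixture(scope="session")
def default_scan():
    return synth.generate_scan(synth.GeneratorConfig(seed=7))


@pytest.fixture()
def detection_config():
    return analysis.DetectionConfig()


def make_position_sweeps(
    n_sweeps: int,
    n_samples: int,
    stim_onset_index: int,
    amp_uV: float,
    latency_ms: float,
    duration_ms: float,
    sampling_rate_hz: float = 10_000.0,
    fired: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hand-constructed sweeps for one needle position."""
    rng = rng or np.random.default_rng(0)
    sweeps = (
        rng.normal(0.0, noise_sd, (n_sweeps, n_samples))
        if noise_sd > 0
        else np.zeros((n_sweeps, n_samples))
    )
    wave = synth.mup_template(amp_uV, duration_ms, sampling_rate_hz)
    onset = stim_onset_index + int(round(latency_ms * sampling_rate_hz / 1000.0))
    if fired is None:
        fired = np.ones(n_sweeps, dtype=bool)
    for s in np.flatnonzero(fired):
        sweeps[s, onset : onset + len(wave)] += wave
    return sweeps
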