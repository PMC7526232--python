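import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stethosim import (
    AcousticEvent, CohortConfig, DeviceProfile, EventModelConfig, Waveform,
    render_recording, synth_breath_noise,
)
from stethosim.detect import detect_events
from stethosim.pipeline import PipelineConfig, run_pipeline
from stethosim.preprocess import preprocess
from stethosim.simulate import _draw_events

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def tiny_config(seed: int = 0, **overrides) -> PipelineConfig:
    """A small, fast cohort: 5 participants, 2 quadrants, 5 s recordings."""
    cohort = CohortConfig(
        group_sizes={"normal": 2, "wheeze_only": 1,
                     "crackles_pm_wheeze": 1, "cf_clear": 1},
        quadrants=("LUQ", "RUQ"),
        devices=(DeviceProfile("hifi", 8000, 32),
                 DeviceProfile("lofi", 4000, 16)),
        exclusions_per_device=1,
        duration_s=5.0,
        master_rate_hz=8000,
        **overrides,
    )
    return PipelineConfig(seed=seed, cohort=cohort, write_plots=False)


@pytest.fixture(scope="session")
def tiny_pipeline_config() -> PipelineConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def default_report() -> dict:
    """Full default-cohort pipeline run (the study-shaped configuration)."""
    return run_pipeline(PipelineConfig(seed=0, write_plots=False))


@pytest.fixture(scope="session")
def recovery_batch():
    """Seeded 20 dB SNR batch with known injected events plus detections.

    Returns a list of (truth_events, accepted_crackles, wheeze_segments).
    """
    cfg = CohortConfig(events=EventModelConfig(
        snr_db=20.0, wheeze_in_crackle_group_prob=1.0))
    rng = np.random.default_rng(20_001)
    out = []
    for i in range(8):
        events = _draw_events(cfg, "crackles_pm_wheeze", rng)
        noise = synth_breath_noise(cfg.duration_s, cfg.events.breath_cycle_s,
                                   cfg.master_rate_hz, seed=1000 + i)
        mix, truth = render_recording(events, noise, snr_db=20.0)
        crackles, wheezes = detect_events(preprocess(mix))
        out.append((truth, crackles, wheezes))
    return out
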