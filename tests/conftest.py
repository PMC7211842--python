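"""Shared fixtures: small synthetic datasets generated at test time."""

import pytest

from fimpull.segmentation import AnalyzerConfig
from fimpull.synthetic import SMDSpec, SyntheticSpec, generate_afm_trace, generate_smd_trace


@pytest.fixture(scope="session")
def default_config() -> AnalyzerConfig:
    return AnalyzerConfig()


@pytest.fixture(scope="session")
def clean_afm():
    """One noise-free AFM trace with ground truth (accepted by the analyzer)."""
    return generate_afm_trace(SyntheticSpec(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_afm():
    """One AFM trace at the default instrument noise, with ground truth."""
    return generate_afm_trace(SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def clean_smd():
    """One noise-free SMD trace (no work spread) with ground truth."""
    return generate_smd_trace(
        SMDSpec(seed=5, force_noise_sd=0.0, extension_jitter_sd=0.0, rip_work_rel_sd=0.0)
    )
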