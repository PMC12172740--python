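"""Shared fixtures: montages, clean/noisy subjects, and the standard cohort.

Expensive simulations are session-scoped so that recovery, determinism and
comparison tests share one cohort and one reference run.
"""

from __future__ import annotations

import numpy as np
import pytest

import erpbench as eb
from erpbench.simulate import ArtifactConfig


NO_ARTIFACTS = ArtifactConfig(
    blink_rate_per_min=0.0,
    blink_amplitude_uv=0.0,
    n_flat_channels=0,
    flat_duration_s=0.0,
    transient_rate_per_min=0.0,
    transient_amplitude_uv=0.0,
    line_noise_amplitude_uv=0.0,
)


@pytest.fixture(scope="session")
def montage():
    return eb.standard_montage_32()


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, jitter-free, artifact-free subject: the zero-noise limit."""
    rec, manifest = eb.generate_subject(
        seed=1, noise_rms_uv=0.0, amplitude_jitter=0.0, artifact_config=NO_ARTIFACTS
    )
    return rec, manifest


@pytest.fixture(scope="session")
def clean_reference_result(clean_subject):
    rec, _ = clean_subject
    from erpbench.pipeline import run_second_pass

    return run_second_pass(rec, [], eb.get_variant("reference"))


@pytest.fixture(scope="session")
def small_cohort():
    """Six short noisy subjects for cross-variant comparison tests."""
    cohort, manifest = eb.generate_cohort(
        6, master_seed=11, n_blocks=2, trials_per_block=20
    )
    return cohort, manifest


@pytest.fixture(scope="session")
def cohort20():
    """The default study-scale cohort: n=20 subjects, default template,
    default artifacts, fixed master seed."""
    cohort, manifest = eb.generate_cohort(20, master_seed=7)
    return cohort, manifest


@pytest.fixture(scope="session")
def reference_run20(cohort20):
    cohort, _ = cohort20
    return eb.run_variant(cohort, eb.get_variant("reference"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
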