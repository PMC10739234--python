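"""Shared fixtures: phantoms and pipeline products reused across test modules.

Expensive artifacts (the 25-phantom study, the evaluated seed-0 phantom) are
session-scoped so the full suite generates them once.
"""

from __future__ import annotations

import dataclasses

import pytest

from neurofuse.evaluation import evaluate_phantom, run_study, segment_phantom
from neurofuse.fusion import RigidTransform
from neurofuse.phantom import PhantomSpec, generate_phantom
from neurofuse.volumes import PipelineConfig


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


def clean_phantom_config(cfg: PipelineConfig):
    """Noise-free, artifact-free phantom settings."""
    return dataclasses.replace(cfg.phantom, noise_sd=0.0, flow_severity=0.0,
                               pulsation_amplitude=0.0)


@pytest.fixture(scope="session")
def session_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_bundle(session_config):
    """Noise-free, artifact-free, aligned (identity-transform) phantom."""
    spec = PhantomSpec(clean_phantom_config(session_config), seed=0,
                       true_transform=RigidTransform.identity())
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_segmentation(clean_bundle, session_config):
    """CSF / brainstem / nerve / TOF-vessel masks of the clean phantom."""
    return segment_phantom(clean_bundle, session_config)


@pytest.fixture(scope="session")
def default_bundle(session_config):
    """Seed-0 phantom under the default study conditions (noise, artifacts,
    misalignment)."""
    return generate_phantom(PhantomSpec(session_config.phantom, seed=0))


@pytest.fixture(scope="session")
def pipeline0(session_config):
    """Fully processed seed-0 phantom: segmentation, registration, fusion and
    all four evaluated variants."""
    return evaluate_phantom(0, session_config)


@pytest.fixture(scope="session")
def study_report(session_config):
    """The full 25-phantom four-variant study under default conditions."""
    return run_study(25, session_config)
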