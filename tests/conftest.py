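"""Shared synthetic fixtures.

Heavy pipeline artifacts (sessions, embeddings) are session-scoped so the
generator -> LEM -> decoding chain is built once and reused across test
modules. Two subjects share one archetype model (the conserved-code
condition); durations are kept at 10 minutes so every session still clears
the 5000-time-point floor of the full pipeline.
"""

import warnings

import numpy as np
import pytest

import pawcode as pc
from pawcode.behavior import LabelTrack
from pawcode.synthetic import default_metadata_plan

ARCH_SEED = 0
DUR_S = 600.0


@pytest.fixture(scope="session")
def shared_arch():
    return pc.ArchetypeModel.create(seed=ARCH_SEED)


@pytest.fixture(scope="session")
def session_a(shared_arch):
    return pc.generate_session(
        shared_arch, pc.SessionConfig(duration_s=DUR_S, seed=11, subject="A")
    )


@pytest.fixture(scope="session")
def session_b(shared_arch):
    return pc.generate_session(
        shared_arch, pc.SessionConfig(duration_s=DUR_S, seed=22, subject="B")
    )


@pytest.fixture(scope="session")
def emb_a(session_a):
    return pc.lem_pipeline(pc.preprocess_population(session_a))


@pytest.fixture(scope="session")
def emb_b(session_b):
    return pc.lem_pipeline(pc.preprocess_population(session_b))


@pytest.fixture(scope="session")
def track_a(session_a):
    return LabelTrack(session_a.labels)


@pytest.fixture(scope="session")
def track_b(session_b):
    return LabelTrack(session_b.labels)


@pytest.fixture(scope="session")
def tiny_session(shared_arch):
    """2-minute, 12-unit session for IO and structural tests."""
    return pc.generate_session(
        shared_arch,
        pc.SessionConfig(
            n_units=12,
            units_metadata_plan=default_metadata_plan(1),
            duration_s=120.0,
            seed=7,
            subject="tiny",
        ),
    )


@pytest.fixture(scope="session")
def small_session(shared_arch):
    """5-minute full-width session for mid-weight embedding tests."""
    return pc.generate_session(
        shared_arch, pc.SessionConfig(duration_s=300.0, seed=5, subject="S")
    )


@pytest.fixture(autouse=True)
def _quiet_component_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*components; restricting.*"
        )
        yield


def make_fake_embedding(rng, n_snippets, n_dims=10, class_sep=3.0):
    """Gaussian class-cluster embedding + label track (fast decoding tests)."""
    labels = rng.choice(pc.CLASSES, size=n_snippets)
    centers = {c: rng.normal(0, class_sep, n_dims) for c in pc.CLASSES}
    n_bins = n_snippets * 5
    per_bin = np.repeat(labels, 5)
    coords = np.stack([centers[c] for c in per_bin])
    coords += rng.normal(0, 1.0, coords.shape)
    emb = pc.Embedding(
        coords=coords,
        eigenvalues=np.linspace(0.1, 1.0, n_dims),
        kept_time_index=np.arange(n_bins),
        method="LEM",
        params={},
    )
    return emb, LabelTrack(labels)
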