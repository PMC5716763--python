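"""Shared fixtures: small deterministic sequences and one full study run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ymarker.pipeline import StudyResult, default_study_config, run_study
from ymarker.sim import SimConfig

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down simulation for fast pipeline tests."""
    return SimConfig(
        seed=11,
        autosome_len=40_000,
        x_len=30_000,
        y_divergent_region=(14_000, 2_000),
        n_pool_females=4,
    )


@pytest.fixture(scope="session")
def default_run() -> StudyResult:
    """One full pipeline run at the default desk-scale study conditions.

    Session-scoped: the end-to-end stages are deterministic for the fixed
    seed, and several acceptance-level checks share this single run.
    """
    return run_study(default_study_config(seed=0))
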