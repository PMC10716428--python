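"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ckdprog import (
    AssemblyConfig,
    GeneratorConfig,
    MatchSpec,
    assemble_dataset,
    build_matched_dataset,
    generate_cohort,
)
from ckdprog.synthetic import reduced_catalog


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient default-config cohort (full variable catalog)."""
    return generate_cohort(GeneratorConfig(n_patients=400, seed=2))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    ds, _ = assemble_dataset(
        small_cohort.observations, small_cohort.static, AssemblyConfig()
    )
    return ds


@pytest.fixture(scope="session")
def small_matched(small_dataset):
    return build_matched_dataset(small_dataset, MatchSpec(seed=0)).dataset


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort with a reduced catalog for CLI and model tests."""
    cfg = GeneratorConfig(
        n_patients=250, seed=7, variable_catalog=reduced_catalog(2)
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_matched(tiny_cohort):
    ds, _ = assemble_dataset(
        tiny_cohort.observations,
        tiny_cohort.static,
        AssemblyConfig(catalog=reduced_catalog(2)),
    )
    return build_matched_dataset(ds, MatchSpec(seed=0)).dataset
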