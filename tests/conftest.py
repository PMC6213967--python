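"""Shared fixtures: synthetic cohorts and a curated reference panel.

The "study" fixtures use the generator's default probe counts and effect
sizes (1000 chrX / 400 chrY / 2000 autosomal probes); the "small" fixtures
shrink probe counts for fast unit tests.  Session scope keeps the expensive
builds to one per run.
"""

import pandas as pd
import pytest

from methylsex import (
    BinScheme,
    SimulationConfig,
    build_profiles,
    build_reference,
    simulate_cohort,
)

REF_SEED = 11
TEST_SEED = 22
EST_SEED = 7


def small_config(**kwargs) -> SimulationConfig:
    defaults = dict(
        n_probes_chrx=300, n_probes_chry=150, n_probes_autosome=100, seed=5
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def study_ref_cohort():
    """100 XX + 100 XY at default generator parameters."""
    return simulate_cohort(SimulationConfig(n_xx=100, n_xy=100, seed=REF_SEED))


@pytest.fixture(scope="session")
def study_ref_build(study_ref_cohort):
    profiles = build_profiles(
        study_ref_cohort.matrix, study_ref_cohort.annot, BinScheme.fine()
    )
    labels = study_ref_cohort.truth["sex_label"].str.lower()
    return build_reference(profiles, labels, seed=REF_SEED)


@pytest.fixture(scope="session")
def panel(study_ref_build):
    return study_ref_build.panel


@pytest.fixture(scope="session")
def study_test_cohort():
    """40 XX + 40 XY + 10 XXY + 10 X0, disjoint seed from the reference."""
    return simulate_cohort(
        SimulationConfig(n_xx=40, n_xy=40, n_xxy=10, n_x0=10, seed=TEST_SEED)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Quick mixed cohort for unit tests (reduced probe counts)."""
    return simulate_cohort(small_config(n_xx=25, n_xy=25, seed=5))


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    profiles = build_profiles(small_cohort.matrix, small_cohort.annot, BinScheme.fine())
    labels = small_cohort.truth["sex_label"].str.lower()
    return build_reference(profiles, labels, seed=5).panel


def as_labels(truth: pd.DataFrame) -> pd.Series:
    return truth["sex_label"]
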