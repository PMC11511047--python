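"""Shared fixtures: the canonical synthetic fixture and small collections."""

from __future__ import annotations

from datetime import date

import pytest

from pvsignal.simulate import (
    GroupSpec,
    PTSpec,
    SimConfig,
    emit_fixture,
    fixture_config,
    simulate,
)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Canonical small fixture written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    emit_fixture(outdir)
    return outdir


@pytest.fixture(scope="session")
def fixture_sim():
    """The canonical fixture as in-memory objects."""
    return simulate(fixture_config())


def small_config(seed: int = 42, n_a: int = 30, n_b: int = 20) -> SimConfig:
    """Tiny two-group configuration for fast unit tests."""
    groups = (
        GroupSpec(name="a", suspect_drug="druga", launch_date=date(2021, 1, 1),
                  n_reports=n_a, n_semesters=3),
        GroupSpec(name="b", suspect_drug="drugb", launch_date=date(2020, 1, 1),
                  n_reports=n_b, n_semesters=3),
    )
    catalog = (
        PTSpec(pt="Myalgia", soc="Musculoskeletal and connective tissue disorders",
               prob_per_group={"a": 0.3, "b": 0.1}),
        PTSpec(pt="Nausea", soc="Gastrointestinal disorders",
               prob_per_group={"a": 0.2, "b": 0.2}),
    )
    return SimConfig(seed=seed, groups=groups, pt_catalog=catalog,
                     extra_reactions_mean=1.0)


@pytest.fixture()
def fifty_reports():
    """A 50-report collection exercising both groups of the generator."""
    collection, meddra, truth = simulate(small_config())
    assert len(collection) == 50
    return collection, meddra, truth
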