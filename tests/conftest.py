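"""Shared fixtures: synthetic libraries and trained models.

Everything is generated programmatically from fixed seeds; session scope
keeps the expensive model fits shared across test modules.
"""

from __future__ import annotations

import warnings

import pytest

from isoprofiler import curation, fixtures, modeling

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


def balanced_subset(compounds, n):
    """First n//2 compounds of each class, preserving order."""
    actives = [c for c in compounds if c.label.value == "ACTIVE"]
    inactives = [c for c in compounds if c.label.value == "INACTIVE"]
    return actives[: n // 2] + inactives[: n - n // 2]


@pytest.fixture(scope="session")
def separable_split():
    """Balanced 400-compound library with activity = planted sulfonamide,
    split 80/20 per class."""
    library = fixtures.generate_separable_library(
        fixtures.FixtureConfig(n_compounds=400, seed=11)
    )
    return curation.stratified_split(library, seed=11)


@pytest.fixture(scope="session")
def svm_circular_model(separable_split):
    train, _test = separable_split
    spec = modeling.ModelSpec.make(
        "SVM",
        "CIRCULAR_2048",
        modeling.default_hyperparams("SVM", "CIRCULAR_2048"),
        seed=11,
    )
    return modeling.train_final(spec, train, threshold_pki=6.30, isoform="hCA_I")


@pytest.fixture(scope="session")
def activity_table_500():
    cfg = fixtures.FixtureConfig(n_compounds=500, seed=7)
    records, manifest = fixtures.generate_activity_table(cfg)
    return cfg, records, manifest
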