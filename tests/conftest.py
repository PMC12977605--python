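"""Shared fixtures: the shipped synthetic scenario run end to end once per
session, plus small hand-built tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

from vagitype.pipeline import run_full
from vagitype.synthetic import (
    SpeciesSpec,
    SyntheticSpec,
    TemplateSpec,
    default_scenario,
    generate_samples,
)

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def dataset():
    return generate_samples(default_scenario(), seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def result(dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_full(
            dataset.counts, dataset.annotation, dataset.catalog, seed=FIXTURE_SEED
        )


@pytest.fixture(scope="session")
def small_scenario():
    """Two templates x 15 samples, three species with 2 subspecies each;
    sized for fast CLI round-trips."""
    species = [
        SpeciesSpec("SpA", k_subspecies=2, n_core_vogs=40, n_accessory_vogs=30),
        SpeciesSpec("SpB", k_subspecies=2, n_core_vogs=40, n_accessory_vogs=30),
        SpeciesSpec("SpC", k_subspecies=2, n_core_vogs=40, n_accessory_vogs=30),
    ]
    names = [s.name for s in species]
    templates = [
        TemplateSpec("t1", dict(zip(names, [0.6, 0.2, 0.2])), dict(zip(names, [1, 1, 2]))),
        TemplateSpec("t2", dict(zip(names, [0.1, 0.5, 0.4])), dict(zip(names, [2, 2, 1]))),
    ]
    return SyntheticSpec(
        species=species,
        templates=templates,
        n_samples_per_template=15,
        reads_per_sample=200_000,
    )


def make_annotation(rows):
    """rows: list of (gene_id, length_bp, species, vog_id-or-None)."""
    frame = pd.DataFrame(
        rows, columns=["gene_id", "length_bp", "species", "vog_id"]
    ).set_index("gene_id")
    frame.index.name = None
    return frame


@pytest.fixture
def toy_annotation():
    return make_annotation(
        [
            ("g1", 300, "A", "V1"),
            ("g2", 150, "A", "V1"),
            ("g3", 600, "A", "V2"),
            ("g4", 300, "B", "V3"),
            ("g5", 450, "B", None),
        ]
    )


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        {
            "s1": [2, 0, 4, 1, 3],
            "s2": [0, 1, 0, 0, 0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
        dtype=np.int64,
    )
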