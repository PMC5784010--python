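"""Shared fixtures: every input is generated, with recorded ground truth."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import ncpgeom as ng

REFERENCE_DIR = Path(__file__).parent / "data" / "reference"


@pytest.fixture(scope="session")
def toy():
    """Default toy NCP (reference-sequence octamer), fully prepared."""
    model, truth = ng.make_toy_ncp(ng.SyntheticSpec(seed=7))
    ng.assign_domains(model)
    ng.pair_bases(model)
    return model, truth


@pytest.fixture(scope="session")
def toy_axis(toy):
    model, _ = toy
    return ng.compute_axis(model)


@pytest.fixture(scope="session")
def toy_fit(toy_axis):
    return ng.fit_superhelix(toy_axis)


@pytest.fixture(scope="session")
def toy_frame(toy, toy_fit):
    model, _ = toy
    return ng.build_frame(model, sh=toy_fit)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def reference_structure(entry: str) -> Path:
    """Path of a cached reference crystal structure, failing loudly if absent.

    The cache is populated by ``scripts/fetch_structures.py`` (needs
    network access to the PDB).  The test asserting against published
    per-structure values cannot pass without it.
    """
    path = REFERENCE_DIR / f"{entry.lower()}.cif"
    if not path.exists():
        pytest.fail(
            f"reference structure {entry} not cached at {path}; run "
            "'python scripts/fetch_structures.py' (requires network access "
            "to files.rcsb.org) to enable checks against published values")
    return path
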