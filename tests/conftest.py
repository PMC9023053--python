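"""Shared fixtures: models, repertoire builders, and a session-wide
simulation cache (VJ-pair simulations are reusable across tests that share
the human-like model and simulation settings)."""

from __future__ import annotations

import numpy as np
import pytest

from tcrconv.generative_model import (
    SimulationCache,
    human_like_model,
    toy_insertion_model,
    toy_model,
)
from tcrconv.repertoire_io import Clonotype, Repertoire

#: simulation settings used by every human-like-model test
N_SIM = 10_000
N_BATCHES = 20


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture(scope="session")
def toy_ins():
    return toy_insertion_model()


@pytest.fixture(scope="session")
def human_model():
    return human_like_model()


@pytest.fixture(scope="session")
def sim_cache(human_model):
    return SimulationCache(human_model, N_SIM, N_BATCHES, seed=99)


def make_repertoire(rows, sample_id="s"):
    """rows: iterable of (cdr3_aa, v, j, count)."""
    total = sum(r[3] for r in rows)
    clonotypes = [
        Clonotype(cdr3_aa=aa, v_gene=v, j_gene=j, count=n, freq=n / total if total else 0.0)
        for aa, v, j, n in rows
    ]
    return Repertoire(sample_id, clonotypes)


@pytest.fixture
def small_rep():
    return make_repertoire(
        [
            ("CASSF", "TRBV1", "TRBJ1", 5),
            ("CASTF", "TRBV1", "TRBJ1", 3),
            ("CASSG", "TRBV1", "TRBJ1", 2),
        ]
    )
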