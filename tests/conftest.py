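from __future__ import annotations

import numpy as np
import pytest

from taxonet import BipartiteNetwork, TaxonomyTable, TaxonRecord, run_pipeline


def make_net(matrix, weighted=False, level="species", name="net"):
    m = np.asarray(matrix, dtype=float)
    return BipartiteNetwork(
        matrix=m,
        row_labels=tuple(f"plant{i}" for i in range(m.shape[0])),
        col_labels=tuple(f"poll{j}" for j in range(m.shape[1])),
        weighted=weighted,
        level=level,
        name=name,
    )


def random_binary(rng, r, c, p=0.5):
    """Random 0/1 matrix with no empty rows or columns."""
    while True:
        m = (rng.random((r, c)) < p).astype(float)
        if m.any(axis=1).all() and m.any(axis=0).all():
            return m


def random_counts(rng, r, c, p=0.6, high=5):
    while True:
        m = rng.integers(0, high + 1, (r, c)) * (rng.random((r, c)) < p)
        m = m.astype(float)
        if m.any(axis=1).all() and m.any(axis=0).all():
            return m


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_taxonomy():
    """3 plants in 2 genera / 2 families, 3 pollinators in 2 genera / 2 families."""
    plants = {
        "plant0": TaxonRecord("Pg1", "Pf1", True),
        "plant1": TaxonRecord("Pg1", "Pf1", True),
        "plant2": TaxonRecord("Pg2", "Pf2", True),
    }
    polls = {
        "poll0": TaxonRecord("Ag1", "Af1", True),
        "poll1": TaxonRecord("Ag2", "Af2", True),
        "poll2": TaxonRecord("Ag2", "Af2", True),
    }
    return TaxonomyTable(plants=plants, pollinators=polls)


@pytest.fixture(scope="session")
def study_report():
    """Full comparison pipeline on the default 41-network synthetic corpus.

    Null ensembles, robustness sequences and modularity restarts are scaled
    down so the whole study runs in well under a minute; the design (41
    networks, 10 binary, three resolutions) is untouched.
    """
    config = {
        "synthetic": {"n_networks": 41, "seed": 11},
        "n_null": 25,
        "robustness_sequences": 50,
        "modularity_restarts": 5,
        "seed": 11,
    }
    return run_pipeline(config)
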