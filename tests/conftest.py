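"""Shared fixtures: synthetic studies are simulated once per session.

All fixtures derive from the synthetic-data generator; nothing in the
suite reads external data.
"""

from __future__ import annotations

import numpy as np
import pytest

import atlaspipe as ap
from atlaspipe.synthetic import DEFAULT_ROSTER


@pytest.fixture(scope="session")
def default_sim():
    """Full default study (markers + smoking response + lineage + mucin)."""
    counts, annotations, truth = ap.simulate_dataset(ap.default_config(1))
    return counts, annotations, truth


@pytest.fixture(scope="session")
def default_norm(default_sim):
    counts, _, _ = default_sim
    return ap.normalize(counts)


@pytest.fixture(scope="session")
def smoking_de_tables(default_sim, default_norm):
    """Per-roster-population smoker-vs-non-smoker DE on the default study."""
    counts, annotations, _ = default_sim
    pop = annotations.table["population"].to_numpy()
    smoking = annotations.table["smoking"].to_numpy()
    tables = {}
    for p in DEFAULT_ROSTER:
        cells_s = np.flatnonzero((pop == p) & (smoking == "heavy"))
        cells_n = np.flatnonzero((pop == p) & (smoking == "never"))
        tables[p] = ap.de_contrast(
            default_norm, counts.values, counts.gene_ids, cells_s, cells_n
        )
    return tables


@pytest.fixture(scope="session")
def marker_sim():
    """Marker blocks only (no lineage / mucin / smoking structure)."""
    counts, annotations, truth = ap.simulate_dataset(ap.marker_benchmark_config(1))
    return counts, annotations, truth


@pytest.fixture(scope="session")
def marker_table(marker_sim):
    counts, annotations, _ = marker_sim
    norm = ap.normalize(counts)
    pop = annotations.table["population"].to_numpy()
    return ap.pairwise_markers(norm, counts.values, counts.gene_ids, pop, seed=1)


@pytest.fixture(scope="session")
def mucin_sim():
    """Secretory-enriched study carrying the anchor programs."""
    counts, annotations, truth = ap.simulate_dataset(ap.mucin_benchmark_config(3))
    return counts, annotations, truth


@pytest.fixture(scope="session")
def lineage_cells(default_sim, default_norm):
    """PCA coordinates, labels and planted pseudotime of the lineage subset."""
    counts, annotations, truth = default_sim
    pop = annotations.table["population"].to_numpy()
    chain = ["Basal_Prolif", "Basal_Diff", "KRT8_high", "Secretory"]
    mask = np.isin(pop, chain)
    idx = np.flatnonzero(mask)
    coords = ap.pca_reduce(default_norm[:, idx])
    return {
        "coords": coords,
        "labels": pop[mask],
        "true_pseudotime": truth.cells["true_pseudotime"].to_numpy()[mask],
        "chain": chain,
        "cell_idx": idx,
    }
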