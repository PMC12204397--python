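"""Shared fixtures: synthetic communities and trained models.

Expensive artifacts (pair-metric tables, trained classifiers) are built
once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import taxodelim as td
from taxodelim.classifier import SearchConfig, label_pairs, train_rank_classifier
from taxodelim.synthetic_data import small_config


@pytest.fixture(scope="session")
def small_community():
    """~80-genome community used by most module tests."""
    return td.simulate_community(small_config(seed=0))


@pytest.fixture(scope="session")
def small_metrics(small_community):
    c = small_community
    return td.build_pair_metrics(c.records, c.schema, c.aai_table, c.ani_table)


@pytest.fixture(scope="session")
def genus_pairs(small_community, small_metrics):
    return label_pairs(small_community.records, "genus", small_metrics)


@pytest.fixture(scope="session")
def genus_model(genus_pairs):
    """Trained genus delineator on the small community (reduced grid)."""
    config = SearchConfig.reduced(seed=7)
    delineator, report, trace = train_rank_classifier(genus_pairs, config)
    return delineator, report, trace


@pytest.fixture(scope="session")
def default_run():
    """Full-size (~350 genome) end-to-end run shared by acceptance tests."""
    from taxodelim.clustering import crossvalidate_algorithms, enumerate_taxa

    community = td.simulate_community(td.SimulationConfig(seed=11))
    metrics = td.build_pair_metrics(
        community.records, community.schema,
        community.aai_table, community.ani_table)
    pairs = label_pairs(community.records, "genus", metrics)
    config = SearchConfig.reduced(seed=11)
    delineator, report, trace = train_rank_classifier(pairs, config)
    cv_reports, selected = crossvalidate_algorithms(
        community.records, pairs, delineator,
        subset_sizes=(50, 100, 200), rounds_per_size=20, seed=11)
    partition, n_taxa = enumerate_taxa(
        community.records, pairs, delineator, selected)
    true_genera = len({lin["genus"] for lin in community.true_taxonomy.values()})
    return {
        "community": community, "metrics": metrics, "pairs": pairs,
        "delineator": delineator, "report": report,
        "cv_reports": cv_reports, "selected": selected,
        "n_taxa": n_taxa, "true_genera": true_genera,
    }


def block_affinity(sizes, within, between, ids=None):
    """Block-constant affinity matrix helper used across clustering tests."""
    from taxodelim.clustering import AffinityMatrix

    n = sum(sizes)
    a = np.full((n, n), between, dtype=float)
    start = 0
    for s in sizes:
        a[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(a, 1.0)
    if ids is None:
        ids = [f"g{i:03d}" for i in range(n)]
    return AffinityMatrix(ids, a)
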