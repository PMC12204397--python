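"""GG/GGR greedy clustering against hand-traced oracles, affinity-matrix
contracts, and cluster-count cross-validation."""

import numpy as np
import pytest

from taxodelim.clustering import (
    SIGMA_GRID,
    AffinityMatrix,
    AlgorithmSpec,
    build_affinity,
    crossvalidate_algorithms,
    gg_cluster,
    ggr_cluster,
)
from taxodelim.errors import InputError

from conftest import block_affinity


def clusters_of(partition):
    groups = {}
    for g, c in partition.assignment.items():
        groups.setdefault(c, set()).add(g)
    return sorted(sorted(s) for s in groups.values())


class TestAffinityMatrix:
    def test_contract_violations_rejected(self):
        with pytest.raises(InputError):
            AffinityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(InputError):
            AffinityMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))
        with pytest.raises(InputError):
            AffinityMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))

    def test_final_mode_uses_known_statuses(self, small_community,
                                            small_metrics, genus_model,
                                            genus_pairs):
        delineator, _, _ = genus_model
        records = small_community.records
        known = [r.genome_id for r in records if r.resolved_at("genus")][:25]
        aff = build_affinity(known, records, genus_pairs, delineator,
                             mode="final")
        off_diag = aff.values[~np.eye(len(known), dtype=bool)]
        assert np.isin(off_diag, (0.0, 1.0)).all()
        assert np.allclose(aff.values, aff.values.T)
        assert (np.diag(aff.values) == 1.0).all()

    def test_cv_mode_predicts_everything(self, small_community, small_metrics,
                                         genus_model, genus_pairs):
        delineator, _, _ = genus_model
        records = small_community.records
        known = [r.genome_id for r in records if r.resolved_at("genus")][:25]
        aff = build_affinity(known, records, genus_pairs, delineator, mode="cv")
        off_diag = aff.values[~np.eye(len(known), dtype=bool)]
        assert not np.isin(off_diag, (0.0, 1.0)).all()


class TestGG:
    def test_all_ones_single_cluster(self):
        aff = block_affinity([6], within=1.0, between=1.0)
        assert gg_cluster(aff, 0.5).n_clusters == 1

    def test_all_zeros_all_singletons(self):
        aff = block_affinity([6], within=0.0, between=0.0)
        assert gg_cluster(aff, 0.5).n_clusters == 6

    def test_two_block_hand_trace(self):
        """6x6 matrix, two 3-genome blocks (within 0.9, between 0.1),
        sigma 0.5: hand-tracing the greedy rule yields exactly the two
        blocks."""
        ids = ["g1", "g2", "g3", "h1", "h2", "h3"]
        aff = block_affinity([3, 3], within=0.9, between=0.1, ids=ids)
        expected = [["g1", "g2", "g3"], ["h1", "h2", "h3"]]
        assert clusters_of(gg_cluster(aff, 0.5)) == expected
        assert clusters_of(ggr_cluster(aff, 0.5)) == expected

    @pytest.mark.parametrize("sizes", [
        (1,), (2, 3), (50, 7, 1), (10, 10, 10), (5, 1, 25), (50, 50),
    ])
    def test_block_recovery_exact(self, sizes):
        """With within > sigma > between, GG recovers block-constant
        matrices exactly."""
        aff = block_affinity(list(sizes), within=0.9, between=0.2)
        partition = gg_cluster(aff, 0.5)
        start = 0
        expected = []
        for s in sizes:
            expected.append(sorted(aff.genome_ids[start:start + s]))
            start += s
        assert clusters_of(partition) == sorted(expected)

    def test_sigma_out_of_range_rejected(self):
        aff = block_affinity([3], within=0.9, between=0.1)
        with pytest.raises(InputError):
            gg_cluster(aff, 1.5)

    def test_cluster_count_monotone_in_sigma(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 30
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            aff = AffinityMatrix([f"g{i:02d}" for i in range(n)], a)
            for fn in (gg_cluster, ggr_cluster):
                counts = [fn(aff, s).n_clusters for s in SIGMA_GRID]
                assert all(b >= a_ for a_, b in zip(counts, counts[1:])), \
                    (fn.__name__, seed, counts)

    def test_relabeling_invariance(self):
        """Permuting genome ids permutes the partition accordingly."""
        rng = np.random.default_rng(3)
        n = 12
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"g{i:02d}" for i in range(n)]
        base = gg_cluster(AffinityMatrix(ids, a), 0.6)
        perm = rng.permutation(n)
        # permuted matrix, same id->row mapping; ids keep their rows'
        # affinities so the partition must map through the permutation
        a2 = a[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        permuted = gg_cluster(AffinityMatrix(ids2, a2), 0.6)
        groups1 = {frozenset(g for g, c in base.assignment.items() if c == k)
                   for k in set(base.assignment.values())}
        groups2 = {frozenset(g for g, c in permuted.assignment.items() if c == k)
                   for k in set(permuted.assignment.values())}
        assert groups1 == groups2


class TestGGR:
    def _refinement_matrix(self):
        """g1 joins the big block A greedily (mean affinity exactly at
        sigma) before block B exists; refinement should move it to B."""
        ids = [f"a{i}" for i in range(1, 7)] + ["g1", "b1", "b2"]
        n = 9
        a = np.zeros((n, n))
        # block A: a1..a6, within 0.9
        a[:6, :6] = 0.9
        # block B: b1, b2, within 0.9
        a[7:, 7:] = 0.9
        # g1: 0.5 to A members, 0.8 to B members
        a[6, :6] = a[:6, 6] = 0.5
        a[6, 7:] = a[7:, 6] = 0.8
        np.fill_diagonal(a, 1.0)
        return AffinityMatrix(ids, a)

    def test_refinement_counterexample_hand_trace(self):
        aff = self._refinement_matrix()
        gg = clusters_of(gg_cluster(aff, 0.5))
        assert gg == [["a1", "a2", "a3", "a4", "a5", "a6", "g1"],
                      ["b1", "b2"]]
        ggr = clusters_of(ggr_cluster(aff, 0.5))
        assert ggr == [["a1", "a2", "a3", "a4", "a5", "a6"],
                       ["b1", "b2", "g1"]]

    def test_idempotent_on_gg_fixed_point(self):
        aff = block_affinity([4, 3], within=0.9, between=0.1)
        assert clusters_of(ggr_cluster(aff, 0.5)) == \
            clusters_of(gg_cluster(aff, 0.5))

    def test_fixed_point_leaves_no_genome_preferring_another_cluster(self):
        """At the GGR fixed point every genome already sits in the cluster
        the greedy joining rule would pick for it (or in a singleton with
        no cluster reaching sigma)."""
        sigma = 0.6
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 25
            a = rng.random((n, n)) ** 0.5
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            aff = AffinityMatrix([f"g{i:02d}" for i in range(n)], a)
            partition = ggr_cluster(aff, sigma)
            pos = {g: i for i, g in enumerate(aff.genome_ids)}
            clusters = {}
            for g, c in partition.assignment.items():
                clusters.setdefault(c, []).append(pos[g])
            for g, c in partition.assignment.items():
                i = pos[g]
                own = [j for j in clusters[c] if j != i]
                own_mean = float(a[i, own].mean()) if own else -1.0
                for c2, members in clusters.items():
                    if c2 == c:
                        continue
                    other_mean = float(a[i, members].mean())
                    if other_mean >= sigma:
                        assert own_mean >= other_mean - 1e-12, (seed, g)


class TestCrossValidation:
    def test_perfect_affinity_gives_r2_one(self, small_community, genus_pairs,
                                           genus_model):
        """With a near-perfect classifier, GG at sigma 0.5 recovers exact
        counts on every round, so the selected R-squared is ~1."""
        delineator, _, _ = genus_model
        reports, selected = crossvalidate_algorithms(
            small_community.records, genus_pairs, delineator,
            algorithms=[AlgorithmSpec("gg", 0.5), AlgorithmSpec("gg", 0.9)],
            subset_sizes=(25, 50), rounds_per_size=5, seed=0)
        assert max(r.r_squared for r in reports) > 0.9
        assert selected.name == "gg"

    def test_constant_prediction_scores_nonpositive(self):
        """R-squared of a constant predictor is <= 0 by definition."""
        true = np.array([5.0, 7, 9, 4, 6])
        pred = np.full(5, 6.0)
        ss_tot = np.sum((true - true.mean()) ** 2)
        r2 = 1 - np.sum((pred - true) ** 2) / ss_tot
        assert r2 <= 0

    def test_deterministic_reports(self, small_community, genus_pairs,
                                   genus_model):
        delineator, _, _ = genus_model
        kwargs = dict(
            algorithms=[AlgorithmSpec("gg", 0.5)],
            subset_sizes=(20,), rounds_per_size=3, seed=42)
        r1, _ = crossvalidate_algorithms(small_community.records, genus_pairs,
                                         delineator, **kwargs)
        r2, _ = crossvalidate_algorithms(small_community.records, genus_pairs,
                                         delineator, **kwargs)
        assert r1[0].rounds == r2[0].rounds
        assert r1[0].r_squared == r2[0].r_squared


class TestEnumeration:
    def test_enumeration_recovers_label_count(self, small_community,
                                              genus_pairs, genus_model):
        from taxodelim.clustering import enumerate_taxa

        delineator, _, _ = genus_model
        records = small_community.records
        partition, n = enumerate_taxa(records, genus_pairs, delineator,
                                      AlgorithmSpec("gg", 0.5))
        assert sorted(partition.assignment) == sorted(
            r.genome_id for r in records)
        true = len({lin["genus"]
                    for lin in small_community.true_taxonomy.values()})
        assert abs(n - true) / true <= 0.10
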