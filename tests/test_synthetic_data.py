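"""Simulator contracts: branching process, gene-loss model, observation
model, identities, surveys, and label masking."""

import dataclasses

import numpy as np
import pytest

from taxodelim.errors import ConfigurationError
from taxodelim.metrics import RANKS
from taxodelim.synthetic_data import (
    SimulationConfig,
    mask_labels,
    simulate_community,
    simulate_detection_matrix,
    simulate_gene_content,
    simulate_taxonomy,
    small_config,
)


def _degenerate_config(**overrides):
    base = SimulationConfig(
        n_phyla=1,
        mean_children_per_rank={r: 1.0 for r in RANKS[1:]},
        mean_genomes_per_species=1.0,
    )
    return dataclasses.replace(base, **overrides)


class TestSimulateTaxonomy:
    def test_degenerate_tree_has_one_taxon_per_rank(self):
        tree = simulate_taxonomy(_degenerate_config())
        for rank in RANKS:
            assert len(tree.taxa_at(rank)) == 1
        assert len(tree.species) == 1

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_phyla=3, seed=99)
        t1, t2 = simulate_taxonomy(cfg), simulate_taxonomy(cfg)
        assert t1.nodes == t2.nodes and t1.species == t2.species

    def test_every_species_has_full_lineage(self):
        tree = simulate_taxonomy(SimulationConfig(seed=4))
        for s in tree.species:
            lineage = tree.lineage(s)
            assert set(lineage) == set(RANKS)

    def test_branching_process_mean_species_count(self):
        """E[species] = n_phyla * prod(mean children) for the shifted-
        Poisson offspring law; Monte-Carlo mean within 3 SE."""
        cfg = dataclasses.replace(
            SimulationConfig(),
            n_phyla=5,
            mean_children_per_rank={r: 2.0 for r in RANKS[1:]},
        )
        expected = 5 * 2.0 ** 5
        counts = []
        for seed in range(200):
            tree = simulate_taxonomy(dataclasses.replace(cfg, seed=seed))
            counts.append(len(tree.species))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) <= 3 * se

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_phyla"):
            simulate_taxonomy(dataclasses.replace(SimulationConfig(), n_phyla=0))
        bad = dataclasses.replace(
            SimulationConfig(),
            rank_divergence={"species": 0.5, "genus": 0.4, "family": 0.3,
                             "order": 0.2, "class": 0.1, "phylum": 0.05})
        with pytest.raises(ConfigurationError, match="rank_divergence"):
            simulate_taxonomy(bad)


class TestGeneContent:
    def test_zero_loss_rate_keeps_full_pool(self):
        cfg = _degenerate_config(
            gene_pool_sizes={"amino_acid_metabolism": 50},
            gene_loss_rates={"amino_acid_metabolism": 0.0},
        )
        tree = simulate_taxonomy(cfg)
        genes, schema = simulate_gene_content(tree, cfg)
        (species_set,) = genes.values()
        assert species_set == schema.categories["amino_acid_metabolism"]
        assert len(species_set) == 50

    def test_same_species_genomes_share_species_gene_set(self):
        """Two genomes of the same species diverge only along the short
        terminal branches; at zero species-level divergence their true
        sets coincide with the species set."""
        cfg = _degenerate_config(
            rank_divergence={"species": 1e-9, "genus": 0.15, "family": 0.25,
                             "order": 0.35, "class": 0.45, "phylum": 0.6},
            mean_genomes_per_species=3.0,
            completeness_range=(1.0, 1.0), contamination_max=0.0,
            label_mask_fraction={},
        )
        community = simulate_community(cfg)
        sets = {g: s for g, s in community.true_genes.items()}
        first = next(iter(sets.values()))
        assert all(s == first for s in sets.values())

    def test_pairwise_jaccard_matches_two_lineage_loss_oracle(self):
        """Mean Jaccard between two lineages at divergence d matches a
        brute-force simulation of the independent-loss process."""
        lam, d, pool = 1.0, 0.5, 1000
        q = np.exp(-lam * d / 2.0)      # per-lineage survival over d/2

        def one_pair(r):
            a = r.random(pool) < q
            b = r.random(pool) < q
            union = np.sum(a | b)
            return np.sum(a & b) / union if union else 1.0

        # independent oracle: direct simulation of the two-lineage loss
        # process from a shared ancestral pool
        oracle = np.array([one_pair(np.random.default_rng(10_000 + i))
                           for i in range(5_000)])
        expected = oracle.mean()

        # simulator path: sister species whose divergence (genus level)
        # is d; the near-zero species-level depth puts the species nodes
        # effectively at the tips, so species gene sets realize the
        # two-lineage process at divergence d
        cfg = _degenerate_config(
            mean_children_per_rank={"class": 1.0, "order": 1.0, "family": 1.0,
                                    "genus": 1.0, "species": 2.0},
            rank_divergence={"species": 1e-6, "genus": d, "family": 0.51,
                             "order": 0.52, "class": 0.53, "phylum": 0.54},
            root_divergence=0.56,
            gene_pool_sizes={"amino_acid_metabolism": pool},
            gene_loss_rates={"amino_acid_metabolism": lam},
        )
        vals = []
        for seed in range(100):
            tree = simulate_taxonomy(dataclasses.replace(cfg, seed=seed))
            if len(tree.species) != 2:
                continue
            genes, _ = simulate_gene_content(
                tree, dataclasses.replace(cfg, seed=seed))
            s1, s2 = (genes[s] for s in tree.species)
            union = len(s1 | s2)
            vals.append(len(s1 & s2) / union if union else 1.0)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expected) <= 3 * se


class TestObservedGenomes:
    def test_complete_uncontaminated_genome_is_unchanged(self):
        cfg = _degenerate_config(completeness_range=(1.0, 1.0),
                                 contamination_max=0.0,
                                 label_mask_fraction={})
        community = simulate_community(cfg)
        (rec,) = community.records
        assert rec.genes == community.true_genes[rec.genome_id]
        assert rec.completeness == pytest.approx(1.0)

    def test_binomial_thinning_of_gene_count(self):
        cfg = _degenerate_config(
            gene_pool_sizes={"translation": 1000},
            gene_loss_rates={"translation": 0.0},
            completeness_range=(0.8, 0.8), contamination_max=0.0,
            label_mask_fraction={},
        )
        community = simulate_community(cfg)
        (rec,) = community.records
        n_true = len(community.true_genes[rec.genome_id])
        sd = np.sqrt(n_true * 0.8 * 0.2)
        assert abs(len(rec.genes) - 0.8 * n_true) <= 3 * sd

    def test_identical_records_on_rerun(self):
        cfg = small_config(seed=123)
        c1, c2 = simulate_community(cfg), simulate_community(cfg)
        assert [r.genome_id for r in c1.records] == [r.genome_id for r in c2.records]
        for r1, r2 in zip(c1.records, c2.records):
            assert r1 == r2
        assert np.array_equal(c1.detection, c2.detection)
        assert c1.aai_table.equals(c2.aai_table)


class TestIdentities:
    def test_aai_decay_and_ani_missingness(self, small_community):
        c = small_community
        cfg = c.config
        ani_pairs = set(map(tuple, c.ani_table[["genome1", "genome2"]].to_numpy()))
        lineages = c.true_taxonomy
        genus_d = cfg.rank_divergence["genus"]
        from taxodelim.synthetic_data import pair_divergence
        import itertools

        ids = sorted(lineages)
        for a, b in itertools.islice(itertools.combinations(ids, 2), 500):
            d = pair_divergence(c.tree, cfg, lineages[a], lineages[b])
            assert ((a, b) in ani_pairs) == (d <= genus_d)

    def test_noiseless_identity_equals_linear_decay(self):
        cfg = _degenerate_config(
            mean_children_per_rank={"class": 1.0, "order": 1.0, "family": 1.0,
                                    "genus": 1.0, "species": 2.0},
            aai_noise_sd=0.0, ani_noise_sd=0.0,
            label_mask_fraction={},
        )
        for seed in range(30):
            community = simulate_community(dataclasses.replace(cfg, seed=seed))
            if len(community.tree.species) < 2 or len(community.aai_table) == 0:
                continue
            # cross-species pairs in the same genus: d = 0.15 -> AAI 85
            row = community.aai_table.iloc[0]
            same_species = (community.true_taxonomy[row["genome1"]]["species"]
                            == community.true_taxonomy[row["genome2"]]["species"])
            expected = 97.0 if same_species else 85.0
            assert row["AAI"] == pytest.approx(expected)
            return
        pytest.fail("no multi-species community generated")

    def test_monotone_signal_with_divergence(self, small_community):
        """Mean AAI and mean true-gene Jaccard strictly decrease as the
        most recent common taxon moves up the ranks."""
        c = small_community
        from taxodelim.metrics import canonical_pair
        import itertools

        aai_lut = {canonical_pair(r["genome1"], r["genome2"]): r["AAI"]
                   for _, r in c.aai_table.iterrows()}
        by_mrca_aai: dict[str, list] = {r: [] for r in RANKS}
        by_mrca_j: dict[str, list] = {r: [] for r in RANKS}
        ids = sorted(c.true_taxonomy)
        for a, b in itertools.combinations(ids, 2):
            la, lb = c.true_taxonomy[a], c.true_taxonomy[b]
            mrca = None
            for rank in reversed(RANKS):
                if la[rank] == lb[rank]:
                    mrca = rank
                    break
            if mrca is None:
                continue
            if (a, b) in aai_lut:
                by_mrca_aai[mrca].append(aai_lut[(a, b)])
            sa, sb = c.true_genes[a], c.true_genes[b]
            union = len(sa | sb)
            by_mrca_j[mrca].append(len(sa & sb) / union if union else 1.0)
        means_aai = [np.mean(by_mrca_aai[r]) for r in reversed(RANKS)
                     if by_mrca_aai[r]]
        means_j = [np.mean(by_mrca_j[r]) for r in reversed(RANKS) if by_mrca_j[r]]
        assert all(b < a for a, b in zip(means_aai, means_aai[1:]))
        assert all(b < a for a, b in zip(means_j, means_j[1:]))


class TestSurveys:
    def test_forced_full_prevalence_detects_everywhere(self):
        rng = np.random.default_rng(0)
        mat = simulate_detection_matrix(50, 8, mu=10.0, sigma=1e-9, rng=rng)
        assert mat.shape == (50, 8)
        assert mat.all()

    def test_binomial_mean_detections(self):
        rng = np.random.default_rng(1)
        mat = simulate_detection_matrix(1000, 10, mu=np.log(0.5), sigma=1e-12,
                                        rng=rng)
        per_species = mat.sum(axis=1)
        se = np.std(per_species, ddof=1) / np.sqrt(len(per_species))
        assert abs(per_species.mean() - 5.0) <= 3 * se

    def test_genomes_attached_to_detected_surveys(self, small_community):
        c = small_community
        idx = {s: i for i, s in enumerate(c.species_order)}
        for rec in c.records:
            species = c.true_taxonomy[rec.genome_id]["species"]
            survey_no = int(rec.survey_id.removeprefix("survey")) - 1
            assert c.detection[idx[species], survey_no] == 1


class TestMaskLabels:
    def _records(self, n):
        from taxodelim.metrics import GenomeRecord

        return [GenomeRecord(
            genome_id=f"g{i:04d}", survey_id="s", completeness=0.9,
            contamination=0.0,
            taxonomy={r: f"{r}_x" for r in RANKS}) for i in range(n)]

    def test_zero_fraction_changes_nothing(self):
        cfg = dataclasses.replace(SimulationConfig(),
                                  label_mask_fraction={r: 0.0 for r in RANKS})
        recs = self._records(20)
        out = mask_labels(recs, cfg, np.random.default_rng(0))
        assert all(o.taxonomy == r.taxonomy for o, r in zip(out, recs))

    def test_full_phylum_masking_unresolves_everything(self):
        cfg = dataclasses.replace(SimulationConfig(),
                                  label_mask_fraction={"phylum": 1.0})
        out = mask_labels(self._records(10), cfg, np.random.default_rng(0))
        assert all(all(v is None for v in o.taxonomy.values()) for o in out)

    def test_exact_count_masked_without_replacement(self):
        cfg = dataclasses.replace(SimulationConfig(),
                                  label_mask_fraction={"genus": 0.3})
        out = mask_labels(self._records(1000), cfg, np.random.default_rng(5))
        n_unresolved = sum(o.taxonomy["genus"] is None for o in out)
        assert n_unresolved == 300

    def test_masking_is_always_nested(self, small_community):
        for rec in small_community.records:
            seen_none = False
            for rank in RANKS:
                if rec.taxonomy[rank] is None:
                    seen_none = True
                else:
                    assert not seen_none, rec.genome_id
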