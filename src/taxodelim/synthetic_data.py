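"""Synthetic MAG-community generator with known ground-truth taxonomy.

Emulates the statistical structure the delineation pipeline assumes, with
closed-form (or brute-force enumerable) expectations so that every
downstream stage can be validated offline:

* a nested taxonomy (phylum .. species) generated by a branching process;
* gene content evolving on the tree by independent per-gene loss events
  from a common ancestral pool, at a category-specific rate per unit
  divergence, with no regain — so gene-sharing decays predictably with
  taxonomic divergence;
* amino-acid / nucleotide identities decaying linearly with divergence plus
  Gaussian noise, with ANI unreportable beyond genus-level divergence
  (mimicking alignment failure between distant genomes);
* incomplete observed assemblies: each true gene retained independently
  with probability equal to the genome's completeness, plus contamination
  genes drawn from outside the genome;
* heterogeneous species prevalence across surveys (lognormal), driving the
  incidence-frequency structure the richness estimators consume.

Everything is driven by a single integer seed and is byte-for-byte
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .metrics import RANKS, CategorySchema, GenomeRecord

#: Ranks that have their own internal tree nodes, from root side to tips.
_CHILD_RANKS = RANKS[1:]  # class .. species

#: Synthetic gene categories: id -> (tier-B pool size, loss rate per unit
#: divergence).  Tier-A categories are unions of tier-B pools, mirroring a
#: two-level functional hierarchy.  Loss rates span slow housekeeping-like
#: families to fast accessory-like families so FSG carries rank signal.
_BASE_CATEGORIES: dict[str, tuple[int, float]] = {
    "amino_acid_metabolism": (180, 1.2),
    "carbohydrate_metabolism": (200, 1.5),
    "energy_metabolism": (160, 1.0),
    "cofactor_vitamin_metabolism": (140, 0.8),
    "nucleotide_metabolism": (120, 0.9),
    "replication_repair": (110, 0.7),
    "translation": (100, 0.6),
    "membrane_transport": (150, 2.0),
    "signal_transduction": (130, 2.5),
    "environmental_adaptation": (120, 1.1),
}

_LEVEL_A_GROUPS: dict[str, tuple[str, ...]] = {
    "metabolism": (
        "amino_acid_metabolism", "carbohydrate_metabolism", "energy_metabolism",
        "cofactor_vitamin_metabolism", "nucleotide_metabolism",
    ),
    "genetic_information_processing": ("replication_repair", "translation"),
    "environmental_information_processing": ("membrane_transport", "signal_transduction"),
    "cellular_processes": ("environmental_adaptation",),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community.

    ``rank_divergence[r]`` is the divergence depth ``d`` separating two
    genomes whose most recent common taxon is at rank ``r``; it must
    increase strictly from species to phylum.  ``root_divergence`` applies
    to pairs in different phyla.  AAI decays as ``100 * (1 - d)`` plus
    Gaussian noise, so the defaults put same-species pairs near 97%
    identity and cross-phylum pairs near 25%.
    """

    n_phyla: int = 5
    mean_children_per_rank: dict[str, float] = field(default_factory=lambda: {
        "class": 1.8, "order": 1.8, "family": 1.8, "genus": 1.8, "species": 2.0,
    })
    mean_genomes_per_species: float = 3.0
    rank_divergence: dict[str, float] = field(default_factory=lambda: {
        "species": 0.03, "genus": 0.15, "family": 0.25,
        "order": 0.35, "class": 0.45, "phylum": 0.60,
    })
    root_divergence: float = 0.75
    gene_pool_sizes: dict[str, int] = field(default_factory=lambda: {
        c: n for c, (n, _) in _BASE_CATEGORIES.items()
    })
    gene_loss_rates: dict[str, float] = field(default_factory=lambda: {
        c: lam for c, (_, lam) in _BASE_CATEGORIES.items()
    })
    aai_noise_sd: float = 2.0
    ani_noise_sd: float = 1.0
    aai_floor: float = 20.0
    completeness_range: tuple[float, float] = (0.8, 1.0)
    contamination_max: float = 0.05
    reporting_noise_sd: float = 0.0
    n_surveys: int = 12
    prevalence_lognormal: tuple[float, float] = (-1.0, 1.0)
    label_mask_fraction: dict[str, float] = field(default_factory=lambda: {
        "phylum": 0.0, "class": 0.05, "order": 0.05,
        "family": 0.10, "genus": 0.15, "species": 0.20,
    })
    seed: int = 0

    def validate(self) -> None:
        if self.n_phyla < 1:
            raise ConfigurationError(f"n_phyla must be >= 1, got {self.n_phyla}")
        for rank in _CHILD_RANKS:
            mc = self.mean_children_per_rank.get(rank)
            if mc is None or mc < 1:
                raise ConfigurationError(
                    f"mean_children_per_rank[{rank!r}] must be >= 1, got {mc}"
                )
        if self.mean_genomes_per_species < 1:
            raise ConfigurationError(
                "mean_genomes_per_species must be >= 1, got "
                f"{self.mean_genomes_per_species}"
            )
        prev = 0.0
        for rank in reversed(RANKS):  # species .. phylum
            d = self.rank_divergence.get(rank)
            if d is None or not 0.0 < d < 1.0:
                raise ConfigurationError(f"rank_divergence[{rank!r}] must be in (0, 1), got {d}")
            if d <= prev:
                raise ConfigurationError(
                    "rank_divergence must increase strictly from species to phylum; "
                    f"violated at {rank!r} ({d} <= {prev})"
                )
            prev = d
        if self.root_divergence <= self.rank_divergence["phylum"]:
            raise ConfigurationError(
                "root_divergence must exceed rank_divergence['phylum']"
            )
        for cat, n in self.gene_pool_sizes.items():
            if n < 1:
                raise ConfigurationError(f"gene_pool_sizes[{cat!r}] must be >= 1, got {n}")
            if self.gene_loss_rates.get(cat, -1.0) < 0.0:
                raise ConfigurationError(
                    f"gene_loss_rates[{cat!r}] must be >= 0, got {self.gene_loss_rates.get(cat)}"
                )
        lo, hi = self.completeness_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(f"completeness_range must satisfy 0 < lo <= hi <= 1, got {self.completeness_range}")
        if not 0.0 <= self.contamination_max <= 1.0:
            raise ConfigurationError(f"contamination_max must be in [0, 1], got {self.contamination_max}")
        if self.n_surveys < 1:
            raise ConfigurationError(f"n_surveys must be >= 1, got {self.n_surveys}")
        for rank, f in self.label_mask_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"label_mask_fraction[{rank!r}] must be in [0, 1], got {f}"
                )


@dataclass
class TaxonomyTree:
    """Nested taxonomy: every node except the phyla has exactly one parent
    at the next-higher rank, and every species has ancestors at all five
    higher ranks."""

    ranks: tuple[str, ...]
    nodes: dict[str, tuple[str, str | None]]  # taxon id -> (rank, parent id)
    species: list[str]

    def lineage(self, species_id: str) -> dict[str, str]:
        """Map rank -> taxon id for the full ancestry of a species."""
        out: dict[str, str] = {}
        node: str | None = species_id
        while node is not None:
            rank, parent = self.nodes[node]
            out[rank] = node
            node = parent
        return out

    def taxa_at(self, rank: str) -> list[str]:
        return sorted(t for t, (r, _) in self.nodes.items() if r == rank)


def simulate_taxonomy(config: SimulationConfig) -> TaxonomyTree:
    """Generate the taxonomy by a branching process.

    Each phylum independently spawns ``1 + Poisson(mean_children - 1)``
    classes, each class spawns orders the same way, and so on down to
    species; every taxon therefore has at least one child.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    prefixes = {"phylum": "p", "class": "c", "order": "o",
                "family": "f", "genus": "g", "species": "s"}
    counters = {r: 0 for r in RANKS}
    nodes: dict[str, tuple[str, str | None]] = {}

    def new_id(rank: str) -> str:
        counters[rank] += 1
        return f"{prefixes[rank]}{counters[rank]:04d}"

    frontier: list[str] = []
    for _ in range(config.n_phyla):
        pid = new_id("phylum")
        nodes[pid] = ("phylum", None)
        frontier.append(pid)
    for rank in _CHILD_RANKS:
        mean = config.mean_children_per_rank[rank]
        nxt: list[str] = []
        for parent in frontier:
            n_children = 1 + rng.poisson(mean - 1.0)
            for _ in range(n_children):
                cid = new_id(rank)
                nodes[cid] = (rank, parent)
                nxt.append(cid)
        frontier = nxt
    return TaxonomyTree(ranks=RANKS, nodes=nodes, species=frontier)


def _node_heights(config: SimulationConfig) -> dict[str, float]:
    """Height above the genome tips of an internal node at each rank.

    A pair whose most recent common taxon is at rank ``r`` has divergence
    ``rank_divergence[r]``, i.e. the common node sits at height ``d/2``.
    """
    h = {rank: config.rank_divergence[rank] / 2.0 for rank in RANKS}
    h["root"] = config.root_divergence / 2.0
    return h


def pair_divergence(tree: TaxonomyTree, config: SimulationConfig,
                    lineage1: dict[str, str], lineage2: dict[str, str]) -> float:
    """Divergence between two genomes given their species lineages."""
    for rank in reversed(RANKS):  # species first
        if lineage1.get(rank) == lineage2.get(rank):
            return config.rank_divergence[rank]
    return config.root_divergence


def simulate_gene_content(tree: TaxonomyTree, config: SimulationConfig,
                          ) -> tuple[dict[str, frozenset[str]], CategorySchema]:
    """Evolve gene presence/absence down the taxonomy.

    Every gene of category ``c`` starts present in the (implicit) root
    ancestor and is lost independently on each branch with probability
    ``1 - exp(-lambda_c * branch_length)``; there is no regain.  For two
    species at divergence ``d`` this gives an expected true Jaccard close
    to ``exp(-lambda_c * d)`` (exactly ``q / (2 - q)`` with
    ``q = exp(-lambda_c * d / 2)`` for genes surviving to their common
    ancestor; the two agree to first order in ``lambda_c * d``).

    Returns (species id -> true gene set, category schema).  The per-genome
    within-species variation is applied later via the species-node ->
    genome branches in :func:`simulate_observed_genomes`'s caller,
    :func:`simulate_community`; here gene sets are per species.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    heights = _node_heights(config)

    # deterministic gene family ids: K<index> partitioned into base pools
    pools: dict[str, list[str]] = {}
    next_k = 1
    for cat in _BASE_CATEGORIES:
        size = config.gene_pool_sizes.get(cat, 0)
        pools[cat] = [f"K{k:05d}" for k in range(next_k, next_k + size)]
        next_k += size
    # include any user-defined categories beyond the built-in ones
    for cat, size in config.gene_pool_sizes.items():
        if cat not in pools:
            pools[cat] = [f"K{k:05d}" for k in range(next_k, next_k + size)]
            next_k += size

    # children lookup for the traversal
    children: dict[str | None, list[str]] = {}
    for tid, (_, parent) in tree.nodes.items():
        children.setdefault(parent, []).append(tid)
    for lst in children.values():
        lst.sort()

    species_genes: dict[str, set[str]] = {s: set() for s in tree.species}
    for cat in sorted(pools):
        fams = pools[cat]
        lam = config.gene_loss_rates.get(cat, 0.0)
        n = len(fams)

        def descend(node_id: str | None, rank: str, present: np.ndarray) -> None:
            h_here = heights["root"] if node_id is None else heights[rank]
            for child in children.get(node_id, []):
                child_rank = tree.nodes[child][0]
                branch = h_here - heights[child_rank]
                survive = rng.random(n) < np.exp(-lam * branch)
                child_present = present & survive
                if child_rank == "species":
                    species_genes[child].update(
                        fams[i] for i in np.flatnonzero(child_present)
                    )
                else:
                    descend(child, child_rank, child_present)

        descend(None, "root", np.ones(n, dtype=bool))

    categories: dict[str, frozenset[str]] = {c: frozenset(p) for c, p in pools.items()}
    levels = {c: "B" for c in categories}
    for a_cat, members in _LEVEL_A_GROUPS.items():
        fams_a = frozenset().union(*(categories[m] for m in members if m in categories))
        if fams_a:
            categories[a_cat] = fams_a
            levels[a_cat] = "A"
    schema = CategorySchema(categories=categories, levels=levels)
    return {s: frozenset(g) for s, g in species_genes.items()}, schema


@dataclass
class SyntheticCommunity:
    """Bundle of everything the simulator produces for one seed."""

    config: SimulationConfig
    tree: TaxonomyTree
    schema: CategorySchema
    records: list[GenomeRecord]            # observed (incomplete) genomes
    true_genes: dict[str, frozenset[str]]  # genome id -> true gene set
    true_taxonomy: dict[str, dict[str, str]]  # genome id -> rank -> taxon id
    aai_table: "object"                    # pandas DataFrame (genome1, genome2, AAI)
    ani_table: "object"
    detection: np.ndarray                  # species x surveys, 0/1
    species_order: list[str]               # row order of `detection`


def _gene_rate_map(config: SimulationConfig) -> dict[str, float]:
    """Map gene family id -> its category loss rate (by pool construction order)."""
    rates: dict[str, float] = {}
    next_k = 1
    for cat in _BASE_CATEGORIES:
        size = config.gene_pool_sizes.get(cat, 0)
        lam = config.gene_loss_rates.get(cat, 0.0)
        for k in range(next_k, next_k + size):
            rates[f"K{k:05d}"] = lam
        next_k += size
    for cat, size in config.gene_pool_sizes.items():
        if cat in _BASE_CATEGORIES:
            continue
        lam = config.gene_loss_rates.get(cat, 0.0)
        for k in range(next_k, next_k + size):
            rates[f"K{k:05d}"] = lam
        next_k += size
    return rates


def _genome_true_genes(species_set: frozenset[str], config: SimulationConfig,
                             rng: np.random.Generator) -> frozenset[str]:
    branch = config.rank_divergence["species"] / 2.0
    rates = _gene_rate_map(config)
    fams = sorted(species_set)
    surv = np.array([np.exp(-rates.get(f, 0.0) * branch) for f in fams])
    keep = rng.random(len(fams)) < surv
    return frozenset(f for f, k in zip(fams, keep) if k)


def simulate_observed_genomes(
    true_genes: dict[str, frozenset[str]],
    config: SimulationConfig,
    rng: np.random.Generator,
    full_pool: frozenset[str],
) -> dict[str, tuple[frozenset[str], float, float]]:
    """Thin each true gene set down to an observed assembly.

    True completeness ``C`` is drawn uniformly from ``completeness_range``;
    each true gene is retained independently with probability ``C``.
    Contamination genes are sampled from the remainder of the global pool
    at a fraction drawn uniformly from ``[0, contamination_max]`` of the
    true gene count.  Reported completeness equals true ``C`` unless
    ``reporting_noise_sd`` > 0.

    Returns genome id -> (observed gene set, reported completeness,
    reported contamination).
    """
    lo, hi = config.completeness_range
    pool_list = sorted(full_pool)
    out: dict[str, tuple[frozenset[str], float, float]] = {}
    for gid in sorted(true_genes):
        genes = sorted(true_genes[gid])
        c_true = rng.uniform(lo, hi)
        keep = rng.random(len(genes)) < c_true
        observed = {g for g, k in zip(genes, keep) if k}
        contam_frac = rng.uniform(0.0, config.contamination_max)
        n_contam = int(round(contam_frac * len(genes)))
        if n_contam > 0:
            foreign = [g for g in pool_list if g not in true_genes[gid]]
            if foreign:
                picks = rng.choice(len(foreign), size=min(n_contam, len(foreign)),
                                   replace=False)
                observed.update(foreign[i] for i in picks)
        c_reported = c_true
        if config.reporting_noise_sd > 0:
            c_reported = float(np.clip(
                c_true + rng.normal(0.0, config.reporting_noise_sd), 1e-6, 1.0))
        out[gid] = (frozenset(observed), float(c_reported), float(contam_frac))
    return out


def simulate_identities(genome_lineages: dict[str, dict[str, str]],
                        tree: TaxonomyTree, config: SimulationConfig,
                        rng: np.random.Generator):
    """Pairwise AAI and ANI tables with divergence-driven missingness.

    AAI = 100*(1-d) + N(0, aai_noise_sd), clipped to [0, 100]; values below
    ``aai_floor`` are dropped (reported missing).  ANI is analogous but is
    reported missing for any pair more divergent than the genus level,
    emulating the failure of nucleotide alignment between distant genomes.
    """
    import itertools

    import pandas as pd

    ids = sorted(genome_lineages)
    genus_d = config.rank_divergence["genus"]
    aai_rows: list[tuple[str, str, float]] = []
    ani_rows: list[tuple[str, str, float]] = []
    for a, b in itertools.combinations(ids, 2):
        d = pair_divergence(tree, config, genome_lineages[a], genome_lineages[b])
        aai = float(np.clip(100.0 * (1.0 - d) + rng.normal(0.0, config.aai_noise_sd),
                            0.0, 100.0))
        if aai >= config.aai_floor:
            aai_rows.append((a, b, aai))
        if d <= genus_d:
            ani = float(np.clip(100.0 * (1.0 - d) + rng.normal(0.0, config.ani_noise_sd),
                                0.0, 100.0))
            ani_rows.append((a, b, ani))
    aai_table = pd.DataFrame(aai_rows, columns=["genome1", "genome2", "AAI"])
    ani_table = pd.DataFrame(ani_rows, columns=["genome1", "genome2", "ANI"])
    return aai_table, ani_table


def simulate_detection_matrix(n_species: int, n_surveys: int,
                              mu: float, sigma: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Species x survey 0/1 detection matrix under lognormal prevalence.

    Each species draws a detection probability ``p ~ Lognormal(mu, sigma)``
    truncated (by rejection) to ``(0, 1]``; detections across surveys are
    independent Bernoulli(p).  The lognormal creates the mix of rare and
    frequent taxa that incidence-based richness estimators assume.
    """
    p = rng.lognormal(mu, sigma, size=n_species)
    for _ in range(1000):
        bad = p > 1.0
        if not bad.any():
            break
        p[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    p = np.clip(p, 0.0, 1.0)
    return (rng.random((n_species, n_surveys)) < p[:, None]).astype(np.int8)


def simulate_surveys(tree: TaxonomyTree, config: SimulationConfig,
                     genome_species: dict[str, str],
                     rng: np.random.Generator,
                     ) -> tuple[dict[str, str], np.ndarray, list[str]]:
    """Assign genomes to surveys and build the species detection matrix.

    A species with at least one genome is guaranteed at least one
    detection (a genome must have come from somewhere); its genomes are
    placed uniformly at random among the surveys where it was detected.
    """
    mu, sigma = config.prevalence_lognormal
    species_order = sorted(tree.species)
    detection = simulate_detection_matrix(len(species_order), config.n_surveys,
                                          mu, sigma, rng)
    idx = {s: i for i, s in enumerate(species_order)}
    with_genomes = sorted(set(genome_species.values()))
    for s in with_genomes:
        row = detection[idx[s]]
        if row.sum() == 0:
            row[rng.integers(config.n_surveys)] = 1
    genome_survey: dict[str, str] = {}
    for gid in sorted(genome_species):
        row = detection[idx[genome_species[gid]]]
        options = np.flatnonzero(row)
        pick = int(options[rng.integers(len(options))])
        genome_survey[gid] = f"survey{pick + 1:03d}"
    return genome_survey, detection, species_order


def mask_labels(records: list[GenomeRecord], config: SimulationConfig,
                rng: np.random.Generator) -> list[GenomeRecord]:
    """Mark a configured fraction of genomes unresolved at each rank.

    For each rank, exactly ``round(fraction * n)`` genomes (sampled without
    replacement) lose their label at that rank and every lower rank, so
    masking is always nested.  Fractions are applied independently per
    rank, from phylum downward.
    """
    for rank, f in config.label_mask_fraction.items():
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(
                f"label_mask_fraction[{rank!r}] must be in [0, 1], got {f}")
    n = len(records)
    masked_tax: list[dict[str, str | None]] = [dict(r.taxonomy) for r in records]
    for rank in RANKS:
        f = config.label_mask_fraction.get(rank, 0.0)
        k = int(round(f * n))
        if k == 0:
            continue
        chosen = rng.choice(n, size=k, replace=False)
        at_or_below = RANKS[RANKS.index(rank):]
        for i in chosen:
            for r in at_or_below:
                masked_tax[i][r] = None
    out = []
    for rec, tax in zip(records, masked_tax):
        out.append(GenomeRecord(
            genome_id=rec.genome_id, survey_id=rec.survey_id,
            completeness=rec.completeness, contamination=rec.contamination,
            genes=rec.genes, taxonomy=tax,
        ))
    return out


def simulate_community(config: SimulationConfig | None = None) -> SyntheticCommunity:
    """Run the full simulator: taxonomy, gene content, observed genomes,
    identities, surveys, and label masking, all from ``config.seed``."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    tree = simulate_taxonomy(config)
    species_genes, schema = simulate_gene_content(tree, config)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    # genomes per species: 1 + Poisson(mean - 1)
    genome_species: dict[str, str] = {}
    counter = 0
    for s in sorted(tree.species):
        n_genomes = 1 + rng.poisson(config.mean_genomes_per_species - 1.0)
        for _ in range(n_genomes):
            counter += 1
            genome_species[f"MAG{counter:05d}"] = s

    # per-genome true gene sets (species set + short terminal branch turnover)
    true_genes: dict[str, frozenset[str]] = {}
    for gid in sorted(genome_species):
        true_genes[gid] = _genome_true_genes(
            species_genes[genome_species[gid]], config, rng)

    full_pool = schema.categories["ALL"]
    observed = simulate_observed_genomes(true_genes, config, rng, full_pool)

    lineages = {gid: tree.lineage(genome_species[gid]) for gid in genome_species}
    aai_table, ani_table = simulate_identities(lineages, tree, config, rng)

    genome_survey, detection, species_order = simulate_surveys(
        tree, config, genome_species, rng)

    records: list[GenomeRecord] = []
    for gid in sorted(genome_species):
        genes, comp, contam = observed[gid]
        records.append(GenomeRecord(
            genome_id=gid, survey_id=genome_survey[gid],
            completeness=comp, contamination=contam, genes=genes,
            taxonomy={r: lineages[gid][r] for r in RANKS},
        ))
    records = mask_labels(records, config, rng)

    return SyntheticCommunity(
        config=config, tree=tree, schema=schema, records=records,
        true_genes=true_genes,
        true_taxonomy={gid: dict(lineages[gid]) for gid in sorted(genome_species)},
        aai_table=aai_table, ani_table=ani_table,
        detection=detection, species_order=species_order,
    )


def small_config(**overrides) -> SimulationConfig:
    """A reduced community (~100 genomes) for fast tests."""
    base = SimulationConfig(
        n_phyla=3,
        mean_children_per_rank={"class": 1.5, "order": 1.5, "family": 1.5,
                                "genus": 1.5, "species": 1.5},
        mean_genomes_per_species=2.0,
    )
    return replace(base, **overrides)
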