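"""Completeness-corrected gene-sharing metrics between genomes.

The central quantity is the fraction of shared genes (FSG): a Jaccard
similarity of gene-family presence between two genomes, corrected for the
incompleteness of each genome assembly.  Observed gene counts are scaled up
by the estimated completeness of each genome before forming the Jaccard
ratio, so that two fragmentary assemblies of near-identical organisms still
score close to 1.  FSG is computed separately within functional gene
categories (e.g. tiers of an ortholog hierarchy), yielding one similarity
value per category per genome pair.

The per-pair predictor table assembled here — AAI, ANI, and one FSG column
per category — is the input to the rank-level ingroup/outgroup classifiers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Taxonomic ranks from most to least inclusive.  Classifiers are trained at
#: phylum through genus; species assignments come from ANI binning.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Ranks at which ingroup/outgroup classifiers are trained.
CLASSIFIER_RANKS: tuple[str, ...] = RANKS[:-1]

#: Identifier of the implicit category holding every annotated gene family.
ALL_CATEGORY = "ALL"


@dataclass
class GenomeRecord:
    """One genome (typically a MAG) with quality, provenance and annotation.

    Parameters
    ----------
    genome_id:
        Unique opaque identifier.
    survey_id:
        Identifier of the survey (study) the genome originates from.
    completeness:
        Estimated assembly completeness, in ``(0, 1]``.
    contamination:
        Estimated contamination fraction, in ``[0, 1]``.
    genes:
        Set of gene-family identifiers detected in the genome.
    taxonomy:
        Mapping rank name -> taxon identifier, or ``None`` where the rank is
        unresolved.  Resolution must be nested: unresolved at a rank implies
        unresolved at every lower rank.
    """

    genome_id: str
    survey_id: str
    completeness: float
    contamination: float
    genes: frozenset[str] = field(default_factory=frozenset)
    taxonomy: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise InputError(
                f"genome {self.genome_id!r}: completeness must be in (0, 1], "
                f"got {self.completeness}"
            )
        if not 0.0 <= self.contamination <= 1.0:
            raise InputError(
                f"genome {self.genome_id!r}: contamination must be in [0, 1], "
                f"got {self.contamination}"
            )
        # nested resolution: once a rank is unresolved, everything below is too
        seen_unresolved = False
        for rank in RANKS:
            if rank not in self.taxonomy:
                continue
            if self.taxonomy[rank] is None:
                seen_unresolved = True
            elif seen_unresolved:
                raise InputError(
                    f"genome {self.genome_id!r}: rank {rank!r} is resolved "
                    "below an unresolved rank"
                )

    def resolved_at(self, rank: str) -> bool:
        return self.taxonomy.get(rank) is not None


@dataclass
class CategorySchema:
    """Mapping of gene categories to their member gene families.

    ``categories`` maps a category id to the set of families it contains;
    ``levels`` tags each category with its hierarchy tier (``"A"``, ``"B"``
    or ``"ALL"``).  Categories may overlap across tiers (a tier-B category is
    typically a subset of a tier-A one).  The ``ALL`` category is always the
    union of every family in the schema.
    """

    categories: dict[str, frozenset[str]]
    levels: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.categories) ^ set(self.levels)
        if missing:
            raise InputError(f"categories without level tag (or vice versa): {sorted(missing)}")
        union = frozenset().union(*self.categories.values()) if self.categories else frozenset()
        if ALL_CATEGORY not in self.categories:
            self.categories[ALL_CATEGORY] = union
            self.levels[ALL_CATEGORY] = ALL_CATEGORY

    @property
    def category_ids(self) -> list[str]:
        """Category ids with ``ALL`` first, then alphabetical."""
        rest = sorted(c for c in self.categories if c != ALL_CATEGORY)
        return [ALL_CATEGORY, *rest]

    def fsg_columns(self) -> list[str]:
        return [f"FSG_{c}" for c in self.category_ids]


def fsg(n1: int, n2: int, n12: int, c1: float, c2: float) -> float:
    """Completeness-corrected fraction of shared genes between two genomes.

    Observed counts ``n1``, ``n2`` (genes in each genome) and ``n12`` (genes
    in both) are corrected to estimated true counts ``n1/c1``, ``n2/c2`` and
    ``n12/(c1*c2)``, where ``c1``, ``c2`` are the completeness estimates.
    The returned value is the Jaccard ratio of the corrected counts,

        FSG = n̂12 / (n̂1 + n̂2 − n̂12),

    clamped into [0, 1].  The correction can overshoot for highly complete
    overlap (n̂12 exceeding the union estimate); a non-positive denominator
    is mapped to 1 with a warning.  Two genomes with no genes at all in the
    category score 0.
    """
    if n1 < 0 or n2 < 0 or n12 < 0:
        raise InputError(f"gene counts must be non-negative, got ({n1}, {n2}, {n12})")
    if n12 > min(n1, n2):
        raise InputError(f"shared count {n12} exceeds min({n1}, {n2})")
    if not (0.0 < c1 <= 1.0 and 0.0 < c2 <= 1.0):
        raise InputError(f"completeness must be in (0, 1], got ({c1}, {c2})")
    if n1 == 0 and n2 == 0:
        return 0.0
    n1_hat = n1 / c1
    n2_hat = n2 / c2
    n12_hat = n12 / (c1 * c2)
    denom = n1_hat + n2_hat - n12_hat
    if denom <= 0.0:
        logger.warning(
            "FSG correction overshoot: union estimate %.4f <= 0 for counts "
            "(%d, %d, %d) at completeness (%.3f, %.3f); returning 1",
            denom, n1, n2, n12, c1, c2,
        )
        return 1.0
    return min(1.0, max(0.0, n12_hat / denom))


def _fsg_vectorized(n1: np.ndarray, n2: np.ndarray, n12: np.ndarray,
                    c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Array version of :func:`fsg` used when assembling full pair tables."""
    n1_hat = n1 / c1
    n2_hat = n2 / c2
    n12_hat = n12 / (c1 * c2)
    denom = n1_hat + n2_hat - n12_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, n12_hat / np.where(denom > 0, denom, 1.0), 1.0)
    out = np.where((n1 == 0) & (n2 == 0), 0.0, out)
    n_overshoot = int(np.sum((denom <= 0) & ~((n1 == 0) & (n2 == 0))))
    if n_overshoot:
        logger.warning("FSG correction overshoot on %d pairs; clamped to 1", n_overshoot)
    return np.clip(out, 0.0, 1.0)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically sorted pair key; enforces symmetric storage."""
    return (a, b) if a <= b else (b, a)


def _identity_lookup(table: pd.DataFrame | None) -> dict[tuple[str, str], float]:
    if table is None or len(table) == 0:
        return {}
    lut: dict[tuple[str, str], float] = {}
    g1 = table.iloc[:, 0].astype(str).to_numpy()
    g2 = table.iloc[:, 1].astype(str).to_numpy()
    val = table.iloc[:, 2].astype(float).to_numpy()
    for a, b, v in zip(g1, g2, val):
        if np.isnan(v):
            continue
        lut[canonical_pair(a, b)] = v
    return lut


def build_pair_metrics(
    records: list[GenomeRecord],
    schema: CategorySchema,
    aai_table: pd.DataFrame | None = None,
    ani_table: pd.DataFrame | None = None,
    extra_predictors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-pair predictor table for a set of genomes.

    Returns a DataFrame with one row per unordered genome pair (canonical
    lexicographic key in columns ``genome1 < genome2``) and columns ``AAI``,
    ``ANI`` and ``FSG_<category>`` for every category in *schema*.  Identity
    values absent from the input tables are imputed as 0, reflecting pairs
    too divergent for the identity to be computable.

    ``extra_predictors`` may supply additional per-pair columns (e.g. a 16S
    similarity) as a DataFrame whose first two columns are genome ids;
    missing pairs are likewise imputed as 0.
    """
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate genome ids in records: {dupes}")
    by_id = {r.genome_id: r for r in records}

    for name, table in (("AAI", aai_table), ("ANI", ani_table)):
        if table is None or len(table) == 0:
            continue
        unknown = (set(table.iloc[:, 0].astype(str)) | set(table.iloc[:, 1].astype(str))) - set(ids)
        if unknown:
            raise InputError(
                f"{name} table references genomes absent from records: {sorted(unknown)[:5]}"
            )

    aai_lut = _identity_lookup(aai_table)
    ani_lut = _identity_lookup(ani_table)
    extra_luts: dict[str, dict[tuple[str, str], float]] = {}
    if extra_predictors is not None and len(extra_predictors.columns) > 2:
        key_cols = list(extra_predictors.columns[:2])
        for col in extra_predictors.columns[2:]:
            extra_luts[str(col)] = _identity_lookup(extra_predictors[key_cols + [col]])

    cat_ids = schema.category_ids
    cat_sets = [schema.categories[c] for c in cat_ids]
    # per-genome, per-category gene counts precomputed once
    cat_genes: dict[str, list[frozenset[str]]] = {
        r.genome_id: [frozenset(r.genes & cs) for cs in cat_sets] for r in records
    }

    sorted_ids = sorted(ids)
    n_pairs = len(sorted_ids) * (len(sorted_ids) - 1) // 2
    g1_col: list[str] = []
    g2_col: list[str] = []
    aai = np.zeros(n_pairs)
    ani = np.zeros(n_pairs)
    fsg_vals = np.zeros((n_pairs, len(cat_ids)))
    extra_vals = {name: np.zeros(n_pairs) for name in extra_luts}

    for k, (a, b) in enumerate(itertools.combinations(sorted_ids, 2)):
        g1_col.append(a)
        g2_col.append(b)
        key = (a, b)
        aai[k] = aai_lut.get(key, 0.0)
        ani[k] = ani_lut.get(key, 0.0)
        for name, lut in extra_luts.items():
            extra_vals[name][k] = lut.get(key, 0.0)
        ra, rb = by_id[a], by_id[b]
        ga, gb = cat_genes[a], cat_genes[b]
        for j in range(len(cat_ids)):
            sa, sb = ga[j], gb[j]
            fsg_vals[k, j] = fsg(len(sa), len(sb), len(sa & sb),
                                 ra.completeness, rb.completeness)

    data: dict[str, object] = {"genome1": g1_col, "genome2": g2_col,
                               "AAI": aai, "ANI": ani}
    for j, c in enumerate(cat_ids):
        data[f"FSG_{c}"] = fsg_vals[:, j]
    for name, vals in extra_vals.items():
        data[name] = vals
    return pd.DataFrame(data)


def rarefy_categories(schema: CategorySchema, min_size: int = 100,
                      seed: int = 0) -> CategorySchema:
    """Equalize category sizes by dropping small categories and subsampling.

    Categories (other than ``ALL``) with fewer than *min_size* families are
    dropped; every surviving category is subsampled without replacement to
    the size of the smallest survivor.  This removes the size-driven
    advantage large categories have when FSG values are compared across
    categories.  Deterministic for a fixed *seed*.
    """
    if min_size < 1:
        raise InputError(f"min_size must be >= 1, got {min_size}")
    survivors = {
        c: fams for c, fams in schema.categories.items()
        if c != ALL_CATEGORY and len(fams) >= min_size
    }
    if not survivors:
        raise InputError(f"no category has at least {min_size} gene families")
    target = min(len(f) for f in survivors.values())
    rng = np.random.default_rng(seed)
    new_cats: dict[str, frozenset[str]] = {}
    new_levels: dict[str, str] = {}
    for c in sorted(survivors):
        fams = sorted(survivors[c])
        keep = rng.choice(len(fams), size=target, replace=False)
        new_cats[c] = frozenset(fams[i] for i in keep)
        new_levels[c] = schema.levels[c]
    return CategorySchema(categories=new_cats, levels=new_levels)
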