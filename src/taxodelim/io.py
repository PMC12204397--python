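"""Readers and writers for the plain-TSV interchange formats.

All tables are UTF-8 TSV with a header row and '.' decimal separator;
probabilities and rates are written with 6 decimals.  Taxonomy strings
follow the seven-rank convention ``d__;p__;c__;o__;f__;g__;s__`` used by
reference-based classifiers; an empty field after a prefix marks the rank
(and everything below it) as unresolved.  Genome ids are opaque strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .metrics import RANKS, CategorySchema, GenomeRecord

logger = logging.getLogger(__name__)

#: Seven-rank prefixes in file order (domain + the five classifier ranks +
#: species).
TAXONOMY_PREFIXES: tuple[tuple[str, str], ...] = (
    ("domain", "d__"), ("phylum", "p__"), ("class", "c__"), ("order", "o__"),
    ("family", "f__"), ("genus", "g__"), ("species", "s__"),
)

_FLOAT_FORMAT = "%.6f"


def parse_taxonomy_string(s: str) -> dict[str, str | None]:
    """Parse a semicolon-delimited rank-prefixed taxonomy string.

    Returns rank -> name (or None where unresolved).  An empty field makes
    that rank and every lower rank unresolved.  Names are returned
    verbatim.  Raises on a wrong field count or an unexpected prefix,
    naming the position.
    """
    fields = [f.strip() for f in s.split(";")]
    if len(fields) != len(TAXONOMY_PREFIXES):
        raise InputError(
            f"taxonomy string must have {len(TAXONOMY_PREFIXES)} fields, "
            f"got {len(fields)}: {s!r}"
        )
    out: dict[str, str | None] = {}
    unresolved = False
    for pos, ((rank, prefix), field) in enumerate(zip(TAXONOMY_PREFIXES, fields)):
        if not field.startswith(prefix):
            raise InputError(
                f"field {pos} of taxonomy string must start with {prefix!r}, "
                f"got {field!r}"
            )
        name = field[len(prefix):]
        if name == "":
            unresolved = True  # empty rank unresolves everything below it too
        out[rank] = None if unresolved else name
    return out


def format_taxonomy_string(taxonomy: dict[str, str | None],
                           domain: str = "Bacteria") -> str:
    parts = []
    for rank, prefix in TAXONOMY_PREFIXES:
        if rank == "domain":
            parts.append(prefix + domain)
        else:
            name = taxonomy.get(rank)
            parts.append(prefix + (name if name is not None else ""))
    return ";".join(parts)


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _check_no_duplicates(frame: pd.DataFrame, keys: list[str], path: str) -> None:
    dup = frame.duplicated(subset=keys)
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # 1-based + header
        raise InputError(f"{path}: duplicate row for key {keys} at line {line}")


def read_quality(path: str | Path) -> pd.DataFrame:
    frame = read_tsv(path)
    required = {"genome_id", "completeness", "contamination"}
    if not required.issubset(frame.columns):
        raise InputError(f"{path}: expected columns {sorted(required)}")
    _check_no_duplicates(frame, ["genome_id"], str(path))
    return frame


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str | None]]:
    frame = read_tsv(path)
    if not {"genome_id", "classification"}.issubset(frame.columns):
        raise InputError(f"{path}: expected columns genome_id, classification")
    _check_no_duplicates(frame, ["genome_id"], str(path))
    out: dict[str, dict[str, str | None]] = {}
    for gid, s in zip(frame["genome_id"], frame["classification"]):
        parsed = parse_taxonomy_string(str(s))
        out[str(gid)] = {r: parsed[r] for r in RANKS}
    return out


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    frame = read_tsv(path)
    if not {"genome_id", "family_id"}.issubset(frame.columns):
        raise InputError(f"{path}: expected columns genome_id, family_id")
    out: dict[str, set[str]] = {}
    for gid, fam in zip(frame["genome_id"], frame["family_id"]):
        out.setdefault(str(gid), set()).add(str(fam))
    return {g: frozenset(v) for g, v in out.items()}


def read_categories(path: str | Path) -> CategorySchema:
    frame = read_tsv(path)
    if not {"family_id", "category_id", "level"}.issubset(frame.columns):
        raise InputError(f"{path}: expected columns family_id, category_id, level")
    cats: dict[str, set[str]] = {}
    levels: dict[str, str] = {}
    for fam, cat, level in zip(frame["family_id"], frame["category_id"], frame["level"]):
        cat, level = str(cat), str(level)
        if level not in ("A", "B"):
            raise InputError(f"{path}: level must be A or B, got {level!r} for {cat!r}")
        if levels.setdefault(cat, level) != level:
            raise InputError(f"{path}: category {cat!r} has conflicting levels")
        cats.setdefault(cat, set()).add(str(fam))
    return CategorySchema(categories={c: frozenset(v) for c, v in cats.items()},
                          levels=levels)


def read_identity(path: str | Path, value_column: str) -> pd.DataFrame:
    frame = read_tsv(path)
    if not {"genome1", "genome2", value_column}.issubset(frame.columns):
        raise InputError(f"{path}: expected columns genome1, genome2, {value_column}")
    key = frame[["genome1", "genome2"]].apply(
        lambda r: tuple(sorted((str(r.iloc[0]), str(r.iloc[1])))), axis=1)
    dup_mask = key.duplicated(keep=False)
    if dup_mask.any():
        conflicting = frame.loc[dup_mask].groupby(key[dup_mask])[value_column].nunique()
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index[0]
            raise InputError(f"{path}: conflicting duplicate identity rows for pair {bad}")
        frame = frame.loc[~key.duplicated(keep="first")]
    return frame[["genome1", "genome2", value_column]]


def read_surveys(path: str | Path) -> dict[str, str]:
    frame = read_tsv(path)
    if not {"genome_id", "survey_id"}.issubset(frame.columns):
        raise InputError(f"{path}: expected columns genome_id, survey_id")
    _check_no_duplicates(frame, ["genome_id"], str(path))
    return {str(g): str(s) for g, s in zip(frame["genome_id"], frame["survey_id"])}


def assemble_records(quality: pd.DataFrame,
                     taxonomy: dict[str, dict[str, str | None]],
                     annotations: dict[str, frozenset[str]],
                     surveys: dict[str, str]) -> list[GenomeRecord]:
    """Cross-validate the four per-genome tables and build records.

    Every annotated genome must have a quality row; taxonomy and survey
    entries are optional (missing taxonomy = fully unresolved, missing
    survey = the placeholder survey ``"unknown"``).
    """
    quality_ids = set(quality["genome_id"].astype(str))
    missing = sorted(set(annotations) - quality_ids)
    if missing:
        raise InputError(
            f"genomes with annotations but no quality row: {missing[:5]}"
        )
    records: list[GenomeRecord] = []
    for _, row in quality.iterrows():
        gid = str(row["genome_id"])
        records.append(GenomeRecord(
            genome_id=gid,
            survey_id=surveys.get(gid, "unknown"),
            completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            genes=annotations.get(gid, frozenset()),
            taxonomy=taxonomy.get(gid, {r: None for r in RANKS}),
        ))
    return records


def write_simulation(community, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic community as the six input TSVs plus ground truth.

    Emits quality, taxonomy, annotation, category-map, AAI/ANI identity
    and genome-survey tables in the formats the pipeline consumes, plus a
    true-taxonomy table and the species x survey detection matrix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records = community.records
    quality = pd.DataFrame({
        "genome_id": [r.genome_id for r in records],
        "completeness": [r.completeness for r in records],
        "contamination": [r.contamination for r in records],
    })
    paths["quality"] = outdir / "quality.tsv"
    write_tsv(quality, paths["quality"])

    taxonomy = pd.DataFrame({
        "genome_id": [r.genome_id for r in records],
        "classification": [format_taxonomy_string(r.taxonomy) for r in records],
    })
    paths["taxonomy"] = outdir / "taxonomy.tsv"
    write_tsv(taxonomy, paths["taxonomy"])

    ann_rows = [(r.genome_id, fam) for r in records for fam in sorted(r.genes)]
    paths["annotations"] = outdir / "annotations.tsv"
    write_tsv(pd.DataFrame(ann_rows, columns=["genome_id", "family_id"]),
              paths["annotations"])

    cat_rows = [
        (fam, cat, community.schema.levels[cat])
        for cat in sorted(community.schema.categories)
        if community.schema.levels[cat] in ("A", "B")
        for fam in sorted(community.schema.categories[cat])
    ]
    paths["categories"] = outdir / "categories.tsv"
    write_tsv(pd.DataFrame(cat_rows, columns=["family_id", "category_id", "level"]),
              paths["categories"])

    paths["aai"] = outdir / "aai.tsv"
    write_tsv(community.aai_table, paths["aai"])
    paths["ani"] = outdir / "ani.tsv"
    write_tsv(community.ani_table, paths["ani"])

    surveys = pd.DataFrame({
        "genome_id": [r.genome_id for r in records],
        "survey_id": [r.survey_id for r in records],
    })
    paths["surveys"] = outdir / "surveys.tsv"
    write_tsv(surveys, paths["surveys"])

    truth = pd.DataFrame([
        {"genome_id": gid, **community.true_taxonomy[gid]}
        for gid in sorted(community.true_taxonomy)
    ])
    paths["true_taxonomy"] = outdir / "true_taxonomy.tsv"
    write_tsv(truth, paths["true_taxonomy"])

    det = pd.DataFrame(
        community.detection,
        index=community.species_order,
        columns=[f"survey{j + 1:03d}" for j in range(community.detection.shape[1])],
    )
    det.index.name = "species_id"
    paths["detection"] = outdir / "detection.tsv"
    det.to_csv(paths["detection"], sep="\t")
    return paths


def read_detection_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return (frame.to_numpy(dtype=int), [str(i) for i in frame.index],
            [str(c) for c in frame.columns])
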