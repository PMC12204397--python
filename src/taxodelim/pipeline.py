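"""End-to-end pipeline: filter -> bin -> metrics -> train -> cluster -> richness.

Holds the configuration object shared by the command-line entry points and
the single `run_pipeline` orchestrator.  Every stochastic stage derives its
randomness from the one seed in the configuration; no stage reads global
random state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classifier import SearchConfig, label_pairs, train_rank_classifier
from .clustering import crossvalidate_algorithms, enumerate_taxa, partition_to_frame
from .errors import ConfigurationError, InputError
from .metrics import CLASSIFIER_RANKS, build_pair_metrics
from .quality_binning import bin_species, bins_to_frame, filter_quality
from .richness import accumulation_curve, estimate_all, incidence_counts, slope_ratio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and options for a full pipeline run."""

    quality: str
    taxonomy: str
    annotations: str
    categories: str
    aai: str
    ani: str | None = None
    surveys: str | None = None
    outdir: str = "taxodelim_out"
    ranks: tuple[str, ...] = CLASSIFIER_RANKS
    seed: int = 0
    min_completeness: float = 0.80
    max_contamination: float = 0.05
    ani_threshold: float = 95.0
    search: SearchConfig | None = None
    cluster_subset_sizes: tuple[int, ...] = (50, 100, 200)
    cluster_rounds_per_size: int = 20
    accumulation_repeats: int = 10_000
    run_sensitivity: bool = False

    def __post_init__(self) -> None:
        for rank in self.ranks:
            if rank not in CLASSIFIER_RANKS:
                raise ConfigurationError(
                    f"rank {rank!r} not in {CLASSIFIER_RANKS}")
        for name in ("quality", "taxonomy", "annotations", "categories", "aai"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name} file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        search = raw.pop("search", None)
        cfg = cls(**raw)
        if search:
            cfg.search = SearchConfig(**search)
        return cfg

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing each stage's outputs under ``outdir``.

    Returns a summary dict (counts, accuracies, estimates).  A stage
    failure raises with the stage name; outputs of completed stages remain
    on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    search = config.search or SearchConfig(seed=config.seed)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    logging.basicConfig(level=logging.INFO)
    logger.info("pipeline start: seed=%d config=%s", config.seed,
                summary["config_hash"])

    stage = "load"
    try:
        quality = io.read_quality(config.quality)
        taxonomy = io.read_taxonomy(config.taxonomy)
        annotations = io.read_annotations(config.annotations)
        schema = io.read_categories(config.categories)
        aai = io.read_identity(config.aai, "AAI")
        ani = io.read_identity(config.ani, "ANI") if config.ani else None
        surveys = io.read_surveys(config.surveys) if config.surveys else {}
        records = io.assemble_records(quality, taxonomy, annotations, surveys)

        stage = "filter_quality"
        records = filter_quality(records, config.min_completeness,
                                 config.max_contamination)
        summary["n_genomes_after_filter"] = len(records)
        if not records:
            raise InputError("no genomes pass the quality filter")

        stage = "bin_species"
        bins = bin_species(ani, records, config.ani_threshold) if ani is not None \
            else bin_species(pd.DataFrame(columns=["genome1", "genome2", "ANI"]),
                             records, config.ani_threshold)
        io.write_tsv(bins_to_frame(bins), outdir / "species_bins.tsv")
        summary["n_species_bins"] = len(bins)
        reps = {b.representative for b in bins}
        rep_records = [r for r in records if r.genome_id in reps]

        stage = "metrics"

        def _subset(table):
            if table is None:
                return None
            keep = table.iloc[:, 0].astype(str).isin(reps) \
                & table.iloc[:, 1].astype(str).isin(reps)
            return table.loc[keep]

        metrics = build_pair_metrics(rep_records, schema, _subset(aai),
                                     _subset(ani))
        io.write_tsv(metrics, outdir / "pair_metrics.tsv")

        summary["ranks"] = {}
        for rank in config.ranks:
            stage = f"train[{rank}]"
            pairs = label_pairs(rep_records, rank, metrics)
            delineator, report, _ = train_rank_classifier(pairs, search)
            rank_summary = {
                "predictors": delineator.predictors,
                "hyperparameters": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in delineator.hyperparameters.items()},
                "true_positive_rate": report.true_positive_rate,
                "true_negative_rate": report.true_negative_rate,
                "balanced_accuracy": report.balanced,
            }

            if config.run_sensitivity and len(delineator.predictors) >= 2:
                stage = f"sensitivity[{rank}]"
                from .sensitivity import backward_sensitivities, reports_to_rows
                rows = reports_to_rows(
                    backward_sensitivities(delineator, pairs, search))
                io.write_tsv(pd.DataFrame(rows),
                             outdir / f"sensitivity_{rank}.tsv")

            stage = f"cluster[{rank}]"
            cv_reports, selected = crossvalidate_algorithms(
                rep_records, pairs, delineator,
                subset_sizes=tuple(
                    s for s in config.cluster_subset_sizes
                    if s <= len(rep_records)),
                rounds_per_size=config.cluster_rounds_per_size,
                seed=config.seed,
            )
            partition, n_taxa = enumerate_taxa(rep_records, pairs, delineator,
                                               selected)
            io.write_tsv(partition_to_frame(partition),
                         outdir / f"partition_{rank}.tsv")
            rank_summary.update(
                selected_algorithm=selected.label(),
                cluster_cv_r2=max(r.r_squared for r in cv_reports),
                n_taxa=n_taxa,
            )

            if surveys:
                stage = f"richness[{rank}]"
                matrix, taxa_ids, survey_ids = _partition_incidence(
                    partition, rep_records)
                counts = incidence_counts(matrix)
                estimates = estimate_all(counts, seed=config.seed)
                io.write_tsv(pd.DataFrame([
                    {"estimator": e.estimator, "estimate": e.estimate,
                     "standard_error": e.standard_error,
                     "flags": ",".join(e.flags)} for e in estimates
                ]), outdir / f"richness_{rank}.tsv")
                curve = accumulation_curve(matrix,
                                           repeats=config.accumulation_repeats,
                                           seed=config.seed)
                io.write_tsv(pd.DataFrame({
                    "n_surveys": np.arange(len(curve.values)),
                    "mean_taxa": curve.values,
                }), outdir / f"accumulation_{rank}.tsv")
                rank_summary.update(
                    s_obs=counts.s_obs,
                    estimates={e.estimator: e.estimate for e in estimates},
                    slope_ratio=slope_ratio(curve),
                )
            summary["ranks"][rank] = rank_summary

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        logger.info("pipeline complete: %s", outdir / "summary.json")
        return summary
    except Exception:
        logger.exception("pipeline failed in stage %s", stage)
        raise


def _partition_incidence(partition, records) -> tuple[np.ndarray, list[str], list[str]]:
    """Taxon x survey detection matrix from a partition: a taxon is
    detected in every survey contributing at least one member genome."""
    survey_of = {r.genome_id: r.survey_id for r in records}
    surveys = sorted(set(survey_of.values()))
    sidx = {s: i for i, s in enumerate(surveys)}
    clusters = sorted(set(partition.assignment.values()))
    cidx = {c: i for i, c in enumerate(clusters)}
    matrix = np.zeros((len(clusters), len(surveys)), dtype=np.int8)
    for gid, c in partition.assignment.items():
        matrix[cidx[c], sidx[survey_of[gid]]] = 1
    return matrix, [str(c) for c in clusters], surveys
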