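"""Forward and backward predictor sensitivity analyses.

Forward: how well does each similarity metric do *alone*?  Each metric is
forced to be the sole predictor of a rank classifier, with hyperparameters
re-selected from scratch; FSG columns should first be recomputed on a
rarefied category schema (equal category sizes) so that accuracies are
comparable across gene categories and not driven by category size.

Backward: what does each selected predictor *uniquely* contribute?  Each
predictor of a trained rank classifier is removed in turn, hyperparameters
are re-selected on the remaining subset, and the drop in test balanced
accuracy versus the full model is reported.  A near-zero (or negative)
drop flags a redundant predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifier import (
    EvaluationReport,
    LabeledPairs,
    RankDelineator,
    SearchConfig,
    Splits,
    evaluate,
    fit_final,
    grid_search,
    make_splits,
)
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class SensitivityReport:
    rank: str
    name: str
    mode: str                      # "forward" or "backward"
    report: EvaluationReport
    delta_balanced: float | None = None   # backward only: B(full) - B(without)


def forward_sensitivities(pairs: LabeledPairs, metric_names: list[str],
                          config: SearchConfig,
                          splits: Splits | None = None,
                          ) -> list[SensitivityReport]:
    """Single-predictor classifiers, one per metric, on shared splits.

    The same train/validation/test splits are reused across metrics so the
    resulting balanced accuracies are directly comparable (split noise
    cancels out of the ranking).
    """
    if splits is None:
        splits = make_splits(pairs, config)
    out: list[SensitivityReport] = []
    for name in metric_names:
        if name not in pairs.frame.columns:
            logger.warning("metric %r absent from pair table; skipped", name)
            continue
        hp, _ = grid_search(pairs, [name], splits, config)
        model = fit_final(pairs, [name], hp, config, exclude=splits.test)
        report = evaluate(model, pairs, splits.test)
        out.append(SensitivityReport(rank=pairs.rank, name=name,
                                     mode="forward", report=report))
    return out


def backward_sensitivities(delineator: RankDelineator, pairs: LabeledPairs,
                           config: SearchConfig,
                           splits: Splits | None = None,
                           ) -> list[SensitivityReport]:
    """Leave-one-predictor-out contributions for a trained classifier."""
    predictors = delineator.predictors
    if len(predictors) < 2:
        raise InputError("backward sensitivity needs a model with >= 2 predictors")
    if splits is None:
        splits = make_splits(pairs, config)
    full_model = fit_final(pairs, predictors, delineator.hyperparameters,
                           config, exclude=splits.test)
    full_b = evaluate(full_model, pairs, splits.test).balanced
    out: list[SensitivityReport] = []
    for name in predictors:
        remaining = [p for p in predictors if p != name]
        hp, _ = grid_search(pairs, remaining, splits, config)
        model = fit_final(pairs, remaining, hp, config, exclude=splits.test)
        report = evaluate(model, pairs, splits.test)
        out.append(SensitivityReport(
            rank=pairs.rank, name=name, mode="backward", report=report,
            delta_balanced=full_b - report.balanced,
        ))
    return out


def reports_to_rows(reports: list[SensitivityReport]) -> list[dict]:
    return [
        {
            "rank": r.rank, "mode": r.mode, "name": r.name,
            "true_positive_rate": r.report.true_positive_rate,
            "true_negative_rate": r.report.true_negative_rate,
            "balanced_accuracy": r.report.balanced,
            "delta_balanced": np.nan if r.delta_balanced is None else r.delta_balanced,
        }
        for r in reports
    ]
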