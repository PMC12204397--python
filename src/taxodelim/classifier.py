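"""Per-rank ingroup/outgroup classifiers over genome-pair similarity metrics.

At each taxonomic rank (phylum .. genus) a small multilayer perceptron is
trained to predict whether a pair of genomes belongs to the same taxon
("ingroup") or not ("outgroup"), from the pair's AAI, ANI and per-category
FSG values.  The training protocol:

* pairs with unknown status (either genome unresolved at the rank) are
  excluded from training and evaluation;
* ~10% of labeled pairs are reserved as a test set; from the remainder,
  several independent train/validation splits are drawn (validation ~10%
  of the non-test data, training = the rest after class balancing);
* training sets are balanced by rarefaction and capped below a total count
  for tractability;
* hyperparameters (L2 strength alpha, activation, hidden-layer layout) are
  selected on a fixed grid by mean validation balanced accuracy;
* predictors are selected by a sequential "plus 1 minus 1" search that
  halts when the best addition gains no more than 0.005 balanced accuracy;
* the final model is refit on all labeled pairs (balanced) and evaluated
  on the held-out test set.

Balanced accuracy — 0.5 * (true-positive rate + true-negative rate) — is
the selection and reporting metric throughout, because ingroup/outgroup
counts are wildly imbalanced at higher ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InputError
from .metrics import CLASSIFIER_RANKS, GenomeRecord

logger = logging.getLogger(__name__)

INGROUP, OUTGROUP, UNKNOWN = 1, 0, -1


@dataclass
class SearchConfig:
    """Hyperparameter / predictor search settings.

    The defaults reproduce the full protocol (7 alphas x 3 activations x
    1-or-2 hidden layers, 10 train/validation splits, training sets
    balanced and capped below 20 000 pairs).  :meth:`reduced` returns a
    coarser grid for small synthetic communities, where the signal is
    strong enough that the fine grid only adds runtime.
    """

    alpha_grid: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 0.01, 0.1, 1.0, 10.0)
    activation_grid: tuple[str, ...] = ("identity", "logistic", "tanh")
    layer_count_grid: tuple[int, ...] = (1, 2)
    n_splits: int = 10
    plus_l: int = 1
    minus_r: int = 1
    halt_gain: float = 0.005
    max_input_pairs: int = 2_000_000
    test_fraction: float = 0.10
    validation_fraction: float = 0.10
    train_cap: int = 20_000
    max_iter: int = 400
    seed: int = 0

    def hidden_layouts(self, n_predictors: int) -> list[tuple[int, ...]]:
        """Hidden-layer layouts scaled to the predictor count: widths
        {max(2, p), 2p, 4p} for one layer, all ordered pairs for two."""
        p = max(1, n_predictors)
        widths = sorted({max(2, p), 2 * p, 4 * p})
        layouts: list[tuple[int, ...]] = []
        if 1 in self.layer_count_grid:
            layouts.extend((w,) for w in widths)
        if 2 in self.layer_count_grid:
            layouts.extend((w1, w2) for w1 in widths for w2 in widths)
        return layouts

    def grid(self, n_predictors: int):
        """Deterministic first-in-grid order: alpha ascending, activations
        in declared order, fewer layers first (ties broken by this order)."""
        for alpha in self.alpha_grid:
            for activation in self.activation_grid:
                for layout in self.hidden_layouts(n_predictors):
                    yield alpha, activation, layout

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "SearchConfig":
        defaults = dict(
            alpha_grid=(1e-3, 0.1),
            activation_grid=("tanh",),
            layer_count_grid=(1,),
            n_splits=3,
            max_iter=300,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class LabeledPairs:
    """Labeled genome pairs at one rank: a predictor frame plus a status
    vector (1 ingroup, 0 outgroup, -1 unknown)."""

    rank: str
    frame: pd.DataFrame          # genome1, genome2 + predictor columns
    status: np.ndarray           # int8, aligned with frame rows

    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("genome1", "genome2")]

    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.status != UNKNOWN)


@dataclass
class EvaluationReport:
    """True-positive rate P, true-negative rate N, balanced accuracy B."""

    true_positive_rate: float
    true_negative_rate: float
    balanced: float

    @classmethod
    def from_rates(cls, p: float, n: float) -> "EvaluationReport":
        return cls(p, n, balanced_accuracy(p, n))


@dataclass
class RankDelineator:
    """A trained ingroup/outgroup classifier for one taxonomic rank."""

    rank: str
    predictors: list[str]
    hyperparameters: dict
    model: Pipeline
    training_summary: dict = field(default_factory=dict)

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        """Ingroup probability for each row of a predictor frame."""
        missing = [c for c in self.predictors if c not in frame.columns]
        if missing:
            raise InputError(f"missing predictor columns: {missing}")
        x = frame[self.predictors].to_numpy(dtype=float)
        proba = self.model.predict_proba(x)
        classes = list(self.model.named_steps["mlp"].classes_)
        return proba[:, classes.index(1)]


def balanced_accuracy(p: float, n: float) -> float:
    """0.5 * (true-positive rate + true-negative rate)."""
    if not (0.0 <= p <= 1.0 and 0.0 <= n <= 1.0):
        raise InputError(f"rates must be in [0, 1], got P={p}, N={n}")
    return 0.5 * (p + n)


def pair_status(rec1: GenomeRecord, rec2: GenomeRecord, rank: str) -> int:
    """Ingroup iff both genomes resolve to the same taxon at *rank*;
    unknown if either is unresolved there."""
    t1, t2 = rec1.taxonomy.get(rank), rec2.taxonomy.get(rank)
    if t1 is None or t2 is None:
        return UNKNOWN
    return INGROUP if t1 == t2 else OUTGROUP


def label_pairs(records: list[GenomeRecord], rank: str,
                metrics: pd.DataFrame) -> LabeledPairs:
    """Attach ingroup/outgroup/unknown status to every row of a pair
    metrics table."""
    if rank not in CLASSIFIER_RANKS:
        raise InputError(f"unsupported rank {rank!r}; expected one of {CLASSIFIER_RANKS}")
    by_id = {r.genome_id: r for r in records}
    status = np.empty(len(metrics), dtype=np.int8)
    g1 = metrics["genome1"].to_numpy()
    g2 = metrics["genome2"].to_numpy()
    for i in range(len(metrics)):
        status[i] = pair_status(by_id[g1[i]], by_id[g2[i]], rank)
    return LabeledPairs(rank=rank, frame=metrics.reset_index(drop=True), status=status)


def balance_rarefy(indices: np.ndarray, status: np.ndarray, cap: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Balance classes by rarefaction, keeping the total strictly below
    *cap*: both classes subsampled to min(class sizes, (cap - 1) // 2)."""
    ingroup = indices[status[indices] == INGROUP]
    outgroup = indices[status[indices] == OUTGROUP]
    if len(ingroup) == 0 or len(outgroup) == 0:
        raise InputError(
            f"both classes required for balancing: {len(ingroup)} ingroup, "
            f"{len(outgroup)} outgroup"
        )
    per_class = min(len(ingroup), len(outgroup), (cap - 1) // 2)
    keep_in = rng.choice(ingroup, size=per_class, replace=False) \
        if per_class < len(ingroup) else ingroup
    keep_out = rng.choice(outgroup, size=per_class, replace=False) \
        if per_class < len(outgroup) else outgroup
    return np.sort(np.concatenate([keep_in, keep_out]))


@dataclass
class Splits:
    """Index sets (into the labeled-pair frame) for one rank's protocol."""

    test: np.ndarray
    train_validation: list[tuple[np.ndarray, np.ndarray]]


def make_splits(pairs: LabeledPairs, config: SearchConfig) -> Splits:
    """Reserve ~10% of labeled pairs as test data, then draw independent
    train/validation splits from the rest (validation ~10% of non-test;
    training = remaining non-test pairs after balancing)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    labeled = pairs.labeled_indices()
    if len(labeled) < 100:
        raise InputError(f"need >= 100 labeled pairs, got {len(labeled)}")
    for cls_ in (INGROUP, OUTGROUP):
        if np.sum(pairs.status[labeled] == cls_) < 5:
            raise InputError(f"too few pairs of class {cls_} for splitting")
    if len(labeled) > config.max_input_pairs:
        labeled = np.sort(rng.choice(labeled, size=config.max_input_pairs,
                                     replace=False))
    perm = rng.permutation(labeled)
    n_test = max(1, round(config.test_fraction * len(labeled)))
    test = np.sort(perm[:n_test])
    non_test = np.sort(perm[n_test:])
    n_val = max(1, round(config.validation_fraction * len(non_test)))
    tv: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(config.n_splits):
        p = rng.permutation(non_test)
        val = np.sort(p[:n_val])
        train = balance_rarefy(np.sort(p[n_val:]), pairs.status,
                               config.train_cap, rng)
        tv.append((train, val))
    return Splits(test=test, train_validation=tv)


def _make_mlp(alpha: float, activation: str, layout: tuple[int, ...],
              config: SearchConfig) -> Pipeline:
    # predictors standardized on training statistics; log-loss minimized
    # with the quasi-Newton LBFGS optimizer
    return Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(
            hidden_layer_sizes=layout, activation=activation, alpha=alpha,
            solver="lbfgs", max_iter=config.max_iter,
            random_state=config.seed % (2**31),
        )),
    ])


def _rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    pos = y_true == INGROUP
    neg = y_true == OUTGROUP
    p = float(np.mean(y_pred[pos] == INGROUP)) if pos.any() else np.nan
    n = float(np.mean(y_pred[neg] == OUTGROUP)) if neg.any() else np.nan
    return p, n


def _score_model(model: Pipeline, x: np.ndarray, y: np.ndarray) -> float:
    p, n = _rates(y, model.predict(x))
    if np.isnan(p) or np.isnan(n):
        return np.nan
    return balanced_accuracy(p, n)


def grid_search(pairs: LabeledPairs, subset: list[str], splits: Splits,
                config: SearchConfig) -> tuple[dict, float]:
    """Exhaustive hyperparameter grid search for one predictor subset.

    Each grid point is scored by the mean validation balanced accuracy
    over the train/validation splits (fit on balanced training data, score
    on the validation set).  Ties keep the first grid point in the
    deterministic grid order.  A grid point whose fit fails scores 0.
    """
    if not subset:
        raise InputError("predictor subset must be non-empty")
    x_all = pairs.frame[subset].to_numpy(dtype=float)
    y_all = pairs.status
    best: tuple[dict, float] | None = None
    import warnings

    for alpha, activation, layout in config.grid(len(subset)):
        scores = []
        for train, val in splits.train_validation:
            try:
                model = _make_mlp(alpha, activation, layout, config)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(x_all[train], y_all[train])
                s = _score_model(model, x_all[val], y_all[val])
            except Exception:  # noqa: BLE001 - a failed grid point is not fatal
                logger.warning("grid point (alpha=%g, %s, %s) failed to train",
                               alpha, activation, layout, exc_info=True)
                s = 0.0
            scores.append(0.0 if np.isnan(s) else s)
        mean_score = float(np.mean(scores))
        if best is None or mean_score > best[1]:
            best = ({"alpha": alpha, "activation": activation,
                     "hidden_layer_sizes": layout}, mean_score)
    assert best is not None
    return best


def select_predictors(pairs: LabeledPairs, pool: list[str], splits: Splits,
                      config: SearchConfig,
                      ) -> tuple[list[str], dict, list[tuple[list[str], float]]]:
    """Sequential bidirectional ("plus 1 minus 1") predictor selection.

    Starting from the empty set, repeatedly add the single predictor whose
    grid-searched score is highest, then consider removing the single
    predictor whose removal maximizes the score, keeping the removal only
    when the score does not decrease.  Halt when the best addition improves
    the incumbent score by no more than ``halt_gain`` (while keeping that
    first addition; the trace is therefore non-decreasing).

    Returns (selected predictors, best hyperparameters, score trace).
    """
    if not pool:
        raise InputError("predictor pool must be non-empty")
    selected: list[str] = []
    best_hp: dict = {}
    incumbent = -np.inf
    trace: list[tuple[list[str], float]] = []
    while True:
        candidates = [c for c in pool if c not in selected]
        if not candidates:
            break
        add_results = []
        for c in candidates:
            hp, score = grid_search(pairs, selected + [c], splits, config)
            add_results.append((score, c, hp))
        add_results.sort(key=lambda t: (-t[0], t[1]))
        best_score, best_cand, hp = add_results[0]
        if np.isfinite(incumbent) and best_score - incumbent <= config.halt_gain:
            break
        selected.append(best_cand)
        best_hp = hp
        incumbent = best_score
        trace.append((list(selected), incumbent))
        # minus-1 step: try dropping one predictor (never the one just
        # added, which would oscillate), keep the removal if not worse
        if len(selected) >= 2:
            drop_results = []
            for c in selected[:-1]:
                remaining = [s for s in selected if s != c]
                hp_d, score_d = grid_search(pairs, remaining, splits, config)
                drop_results.append((score_d, c, hp_d))
            drop_results.sort(key=lambda t: (-t[0], t[1]))
            score_d, drop_cand, hp_d = drop_results[0]
            if score_d >= incumbent:
                selected.remove(drop_cand)
                best_hp = hp_d
                incumbent = score_d
                trace.append((list(selected), incumbent))
    if not selected:
        # halting before any predictor was added cannot happen (incumbent
        # starts at -inf), but guard against an empty pool edge case
        raise InputError("predictor selection produced an empty subset")
    return selected, best_hp, trace


def fit_final(pairs: LabeledPairs, subset: list[str], hyperparameters: dict,
              config: SearchConfig,
              exclude: np.ndarray | None = None) -> RankDelineator:
    """Refit on all labeled pairs (optionally excluding the test set),
    after balancing by rarefaction."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20]))
    labeled = pairs.labeled_indices()
    if exclude is not None:
        labeled = np.setdiff1d(labeled, exclude)
    train = balance_rarefy(labeled, pairs.status, config.train_cap, rng)
    model = _make_mlp(hyperparameters["alpha"], hyperparameters["activation"],
                      tuple(hyperparameters["hidden_layer_sizes"]), config)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(pairs.frame[subset].to_numpy(dtype=float)[train],
                  pairs.status[train])
    n_iter = model.named_steps["mlp"].n_iter_
    if n_iter >= config.max_iter:
        logger.warning("final %s model hit the iteration cap (%d); "
                       "returning it anyway", pairs.rank, n_iter)
    return RankDelineator(
        rank=pairs.rank, predictors=list(subset),
        hyperparameters=dict(hyperparameters), model=model,
        training_summary={"n_train": int(len(train)), "n_iter": int(n_iter)},
    )


def evaluate(delineator: RankDelineator, pairs: LabeledPairs,
             indices: np.ndarray) -> EvaluationReport:
    """True-positive / true-negative rates at probability threshold 0.5 on
    the given (test) rows."""
    idx = indices[pairs.status[indices] != UNKNOWN]
    proba = delineator.predict_proba(pairs.frame.iloc[idx])
    pred = np.where(proba > 0.5, INGROUP, OUTGROUP)
    p, n = _rates(pairs.status[idx], pred)
    if np.isnan(p) or np.isnan(n):
        raise InputError("test set must contain both classes")
    return EvaluationReport.from_rates(p, n)


def train_rank_classifier(pairs: LabeledPairs, config: SearchConfig,
                          pool: list[str] | None = None,
                          ) -> tuple[RankDelineator, EvaluationReport, list]:
    """Full protocol for one rank: split, select predictors and
    hyperparameters, refit on non-test data, evaluate on the test set,
    then refit the returned "final" model on all labeled pairs."""
    if pool is None:
        pool = pairs.predictor_names
    splits = make_splits(pairs, config)
    subset, hp, trace = select_predictors(pairs, pool, splits, config)
    eval_model = fit_final(pairs, subset, hp, config, exclude=splits.test)
    report = evaluate(eval_model, pairs, splits.test)
    final = fit_final(pairs, subset, hp, config)
    final.training_summary.update(
        test_balanced_accuracy=report.balanced,
        n_test=int(len(splits.test)),
        selection_trace=[(list(s), float(v)) for s, v in trace],
    )
    return final, report, trace
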