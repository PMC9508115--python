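"""Balanced-subsample bootstrap ensembles of random forests for age classes.

The age classes of a long-lived breeder are heavily imbalanced (young and
senescent birds are rare), so a single classifier trained on the raw table
is biased toward the majority class.  The procedure implemented here removes
that bias by looping, for a configured number of iterations:

1. draw a *balanced subsample*: every class contributes exactly m rows,
   m = size of the smallest class, sampled without replacement;
2. fit a random-forest classifier on the balanced subset and record its
   out-of-bag (OOB) error, OOB confusion matrix and per-predictor Gini
   (mean-decrease-impurity) importance;
3. use that forest to predict the class of every nest in the original,
   unbalanced table, tallying disagreements with the true class.

Aggregates over iterations give the ensemble accuracy / sensitivity /
specificity, mean Gini importances, and a per-nest mismatch count used to
flag consistently misclassified nests.  A regression-forest variant treats
age as continuous and reports OOB pseudo-R².

Per-iteration RNG streams are derived from the master seed by iteration
index, so a run is reproducible and independent of execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .features import SCHEMES, AgeClassScheme

__all__ = [
    "EnsembleConfig",
    "IterationResult",
    "EnsembleResult",
    "balanced_subsample",
    "train_iteration",
    "run_ensemble",
    "regression_forest_variance_explained",
    "predict_dataset",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Knobs of the bootstrap ensemble.

    ``n_iterations`` defaults to the full 3000-iteration loop; analyses in
    this package typically run a few hundred, which changes the aggregate
    accuracy by well under a point.  ``mtry`` of None means floor(sqrt(p)).
    ``positive_class`` is the label whose recall is reported as sensitivity.
    """

    scheme: str = "AGE2"
    version: str = "full"
    n_iterations: int = 3000
    n_trees: int = 500
    mtry: int | None = None
    seed: int = 42
    positive_class: str = "Young"
    keep_models: bool = False  # retain fitted forests for predict_dataset
    oob_only_full_predictions: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_trees < 1:
            raise ValueError("n_iterations and n_trees must be >= 1")
        if self.scheme not in SCHEMES and self.scheme != "CONTINUOUS":
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def replace(self, **changes) -> "EnsembleConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class IterationResult:
    oob_error: float
    confusion: pd.DataFrame  # rows = true class, cols = predicted
    gini: pd.Series  # importance per predictor
    full_predictions: np.ndarray  # predicted class per row of the full table
    sensitivity: float | None = None
    specificity: float | None = None
    model: RandomForestClassifier | None = None


@dataclass
class EnsembleResult:
    """Aggregated output of the bootstrap loop (percent scales)."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    gini_aggregate: pd.Series
    mismatch_counts: pd.Series  # indexed by nest_id
    n_iterations: int
    scheme: str
    version: str
    predictors: tuple[str, ...]
    confusion_total: pd.DataFrame = field(default=None)  # summed OOB confusions
    models: list[RandomForestClassifier] | None = None
    train_index: pd.Index | None = None


def _predictor_columns(table: pd.DataFrame) -> list[str]:
    preds = table.attrs.get("predictors")
    if preds:
        return list(preds)
    drop = {"nest_id", "colony", "age", "age_class"}
    return [c for c in table.columns if c not in drop]


def _design(table: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    missing = sorted(set(predictors) - set(table.columns))
    if missing:
        raise ValueError(f"table lacks predictor columns {missing}")
    # Clutch and Year enter integer-coded; all predictors are numeric already
    return table[predictors].to_numpy(dtype=float)


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1000, iteration])


def balanced_subsample(
    table: pd.DataFrame,
    scheme: AgeClassScheme | str | None = None,
    rng: np.random.Generator | None = None,
    label_col: str = "age_class",
) -> pd.DataFrame:
    """Downsample every class to the minority-class size, without replacement."""
    rng = np.random.default_rng() if rng is None else rng
    if label_col not in table.columns:
        raise ValueError(f"table lacks a {label_col!r} column")
    scheme_obj = SCHEMES[scheme] if isinstance(scheme, str) else scheme
    labels = (
        scheme_obj.labels if scheme_obj is not None
        else tuple(sorted(table[label_col].unique()))
    )
    counts = table[label_col].value_counts()
    empty = [lab for lab in labels if counts.get(lab, 0) == 0]
    if empty:
        raise ValueError(f"no rows for class(es) {empty}; cannot balance")
    m = int(min(counts.get(lab) for lab in labels))
    parts = []
    for lab in labels:
        idx = table.index[table[label_col] == lab].to_numpy()
        take = rng.choice(idx, size=m, replace=False)
        parts.append(table.loc[take])
    out = pd.concat(parts)
    out.attrs.update(table.attrs)
    return out


def _oob_stats(
    rf: RandomForestClassifier, y: np.ndarray, positive: str | None
) -> tuple[float, pd.DataFrame, float | None, float | None]:
    classes = rf.classes_
    proba = rf.oob_decision_function_
    have = ~np.isnan(proba).any(axis=1) & (proba.sum(axis=1) > 0)
    pred = classes[np.argmax(proba[have], axis=1)]
    true = y[have]
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    oob_error = float((true != pred).mean())
    sens = spec = None
    if positive is not None and positive in classes:
        tp = int(conf.loc[positive, positive])
        fn = int(conf.loc[positive].sum()) - tp
        neg = [c for c in classes if c != positive]
        tn = int(conf.loc[neg, neg].to_numpy().sum())
        fp = int(conf.loc[neg, positive].sum())
        sens = 100.0 * tp / (tp + fn) if tp + fn else None
        spec = 100.0 * tn / (tn + fp) if tn + fp else None
    return oob_error, conf, sens, spec


def train_iteration(
    balanced: pd.DataFrame,
    full: pd.DataFrame,
    config: EnsembleConfig,
    rng: np.random.Generator,
) -> IterationResult:
    """Fit one forest on a balanced subset and score it.

    OOB error and confusion come from the forest's out-of-bag votes on the
    balanced subset; ``full_predictions`` are the forest's predicted classes
    for every row of the original table.
    """
    predictors = _predictor_columns(balanced)
    y = balanced["age_class"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("balanced table has a single class; nothing to learn")
    X = _design(balanced, predictors)
    mtry = config.mtry if config.mtry is not None else "sqrt"
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X, y)
    oob_error, conf, sens, spec = _oob_stats(rf, y, config.positive_class)
    gini = pd.Series(rf.feature_importances_, index=predictors)
    full_pred = rf.predict(_design(full, predictors))
    return IterationResult(
        oob_error=oob_error,
        confusion=conf,
        gini=gini,
        full_predictions=full_pred,
        sensitivity=sens,
        specificity=spec,
        model=rf if config.keep_models else None,
    )


def run_ensemble(table: pd.DataFrame, config: EnsembleConfig) -> EnsembleResult:
    """Run the full balanced-subsample bootstrap loop and aggregate.

    Accuracy is the mean over iterations of 100*(1 - OOB error); sensitivity
    and specificity are means of the per-iteration one-vs-rest rates for the
    positive class (None for schemes that lack it).  Gini importances are
    averaged per predictor.  ``mismatch_counts[nest]`` counts the iterations
    whose full-table prediction disagreed with the nest's true class.
    """
    if "age_class" not in table.columns:
        raise ValueError("feature table must carry an age_class column")
    scheme = SCHEMES[config.scheme]
    predictors = _predictor_columns(table)
    true = table["age_class"].to_numpy()
    mismatch = np.zeros(len(table), dtype=int)
    accs, senss, specs = [], [], []
    gini_sum = pd.Series(0.0, index=predictors)
    conf_total: pd.DataFrame | None = None
    models: list[RandomForestClassifier] = []

    for it in range(config.n_iterations):
        rng = _iteration_rng(config.seed, it)
        balanced = balanced_subsample(table, scheme, rng)
        res = train_iteration(balanced, table, config, rng)
        accs.append(100.0 * (1.0 - res.oob_error))
        if res.sensitivity is not None:
            senss.append(res.sensitivity)
        if res.specificity is not None:
            specs.append(res.specificity)
        gini_sum += res.gini
        conf_total = res.confusion if conf_total is None else conf_total + res.confusion
        mismatch += (res.full_predictions != true).astype(int)
        if config.keep_models and res.model is not None:
            models.append(res.model)

    return EnsembleResult(
        accuracy=float(np.mean(accs)),
        sensitivity=float(np.mean(senss)) if senss else None,
        specificity=float(np.mean(specs)) if specs else None,
        gini_aggregate=gini_sum / config.n_iterations,
        mismatch_counts=pd.Series(mismatch, index=table["nest_id"], name="mismatch"),
        n_iterations=config.n_iterations,
        scheme=config.scheme,
        version=config.version,
        predictors=tuple(predictors),
        confusion_total=conf_total,
        models=models if config.keep_models else None,
        train_index=table.index,
    )


def regression_forest_variance_explained(
    table: pd.DataFrame, config: EnsembleConfig
) -> float:
    """Pseudo-R² (percent) of a regression forest for continuous age.

    Returns 100*(1 - OOB MSE / var(age)); can be negative when the
    predictors carry no age information.
    """
    if "age" not in table.columns:
        raise ValueError("table lacks an age column")
    y = table["age"].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("age column is constant; variance explained undefined")
    predictors = _predictor_columns(table)
    X = _design(table, predictors)
    mtry = config.mtry if config.mtry is not None else max(1, X.shape[1] // 3)
    rf = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=int(np.random.default_rng([config.seed, 2000]).integers(2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X, y)
    mse = float(np.mean((y - rf.oob_prediction_) ** 2))
    return 100.0 * (1.0 - mse / float(np.var(y, ddof=1)))


def predict_dataset(
    result: EnsembleResult, new_table: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Majority-vote prediction for new nests across the retained forests.

    Requires a run with ``keep_models=True``.  Ties are broken against the
    positive ('Young') class — conservative toward the rarer call.  Returns
    (per-nest table with predicted_class and vote_fraction, proportion
    predicted 'Young').
    """
    if not result.models:
        raise ValueError("ensemble was run without keep_models=True; no forests retained")
    predictors = list(result.predictors)
    missing = sorted(set(predictors) - set(new_table.columns))
    if missing:
        raise ValueError(f"new table lacks predictor columns {missing}")
    X = new_table[predictors].to_numpy(dtype=float)
    preds = np.stack([m.predict(X) for m in result.models])  # (n_models, n_rows)
    labels = SCHEMES[result.scheme].labels
    votes = np.stack([(preds == lab).sum(axis=0) for lab in labels])  # (n_labels, n_rows)

    # deterministic tie-break: prefer the last label among ties in scheme order,
    # i.e. the non-'Young' class (Young is always listed first in its scheme)
    winner_idx = votes.shape[0] - 1 - np.argmax(votes[::-1], axis=0)
    predicted = np.array([labels[i] for i in winner_idx])
    vote_frac = votes[winner_idx, np.arange(votes.shape[1])] / preds.shape[0]
    out = pd.DataFrame(
        {
            "nest_id": new_table.get("nest_id", pd.RangeIndex(len(new_table))),
            "predicted_class": predicted,
            "vote_fraction": vote_frac,
        }
    )
    prop_young = float((predicted == "Young").mean())
    return out, prop_young
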