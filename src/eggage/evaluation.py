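"""Metrics and downstream analyses for the age-class ensembles.

Confusion-matrix rates, misclassification-consistency reports (which nests
are wrong in at least half of the bootstrap iterations, and how that error
distributes over years and ages), learning curves against training-set
size, and chi-square comparison of young-breeder proportions across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleConfig, EnsembleResult, run_ensemble

__all__ = [
    "MisclassificationReport",
    "ProportionComparison",
    "confusion_metrics",
    "accuracy_from_oob",
    "misclassification_report",
    "learning_curve",
    "compare_young_proportions",
]

logger = logging.getLogger(__name__)


@dataclass
class MisclassificationReport:
    per_nest: pd.DataFrame  # nest_id, true class, mismatch count, flagged
    error_by_year: pd.Series  # % of the year's nests flagged
    error_by_age: pd.Series  # % of the age's nests flagged
    n_iterations: int


@dataclass(frozen=True)
class ProportionComparison:
    groups: tuple[tuple[str, int, int], ...]  # (label, n_young, n_total)
    chi2: float
    df: int
    p: float


def confusion_metrics(
    tp: int, fn: int, tn: int, fp: int
) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %) from a 2x2 confusion matrix."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    pos, neg = tp + fn, tn + fp
    if pos == 0 or neg == 0:
        raise ValueError("need at least one positive and one negative case")
    accuracy = 100.0 * (tp + tn) / (pos + neg)
    return accuracy, 100.0 * tp / pos, 100.0 * tn / neg


def accuracy_from_oob(oob_error: float) -> float:
    """Convert an out-of-bag error rate into an accuracy percentage, 100*(1-OOB)."""
    if not 0.0 <= oob_error <= 1.0:
        raise ValueError(f"OOB error must be in [0, 1], got {oob_error}")
    return 100.0 * (1.0 - oob_error)


def misclassification_report(
    mismatch_counts: pd.Series,
    nests: pd.DataFrame,
    n_iterations: int,
) -> MisclassificationReport:
    """Flag consistently misclassified nests and localize the error.

    A nest is flagged when it was mismatched in at least half of the
    bootstrap iterations (count >= n_iterations / 2, inclusive).  Per-year
    and per-age error is the percentage of that stratum's nests flagged.
    ``nests`` needs nest_id, year and age columns (age_class optional).
    """
    counts = mismatch_counts.reindex(nests["nest_id"])
    if counts.isna().any():
        missing = nests["nest_id"][counts.isna().to_numpy()].tolist()[:5]
        raise ValueError(f"no mismatch counts for nests {missing}...")
    arr = counts.to_numpy()
    if arr.min() < 0 or arr.max() > n_iterations:
        raise ValueError("mismatch counts outside [0, n_iterations]")
    flagged = arr >= n_iterations / 2.0
    per_nest = pd.DataFrame(
        {
            "nest_id": nests["nest_id"].to_numpy(),
            "year": nests["year"].to_numpy(),
            "age": nests["age"].to_numpy(),
            "mismatch_count": arr,
            "flagged": flagged,
        }
    )
    if "age_class" in nests.columns:
        per_nest.insert(3, "age_class", nests["age_class"].to_numpy())
    by_year = 100.0 * per_nest.groupby("year")["flagged"].mean()
    by_age = 100.0 * per_nest.groupby("age")["flagged"].mean()
    return MisclassificationReport(
        per_nest=per_nest,
        error_by_year=by_year.rename("error_pct"),
        error_by_age=by_age.rename("error_pct"),
        n_iterations=n_iterations,
    )


def learning_curve(
    table: pd.DataFrame,
    config: EnsembleConfig,
    sizes: list[int],
    reps: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean ensemble accuracy as a function of training-set size.

    For each n in ``sizes``, draws ``reps`` independent stratified subsamples
    of n nests, runs the balanced-bootstrap ensemble on each, and reports the
    mean and SD of the aggregated accuracy.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_rows = len(table)
    bad = [n for n in sizes if n > n_rows or n < 2]
    if bad:
        raise ValueError(f"sizes {bad} outside (2, {n_rows}] rows available")
    master = config.seed if seed is None else seed
    rows = []
    for n in sizes:
        accs = []
        for rep in range(reps):
            rng = np.random.default_rng([master, 3000, n, rep])
            # stratified draw keeps both classes present at small n
            frac = n / n_rows
            parts = []
            for _, grp in table.groupby("age_class", sort=True):
                k = max(1, int(round(frac * len(grp))))
                parts.append(grp.loc[rng.choice(grp.index, size=min(k, len(grp)), replace=False)])
            sub = pd.concat(parts)
            sub.attrs.update(table.attrs)
            res = run_ensemble(
                sub, config.replace(seed=int(rng.integers(2**31 - 1)))
            )
            accs.append(res.accuracy)
        rows.append(
            {
                "n": n,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if reps > 1 else 0.0,
                "reps": reps,
                "n_iterations": config.n_iterations,
            }
        )
    return pd.DataFrame(rows)


def compare_young_proportions(
    groups: list[tuple[str, int, int]], correction: bool = False
) -> ProportionComparison:
    """Pearson chi-square test of homogeneity of young-breeder proportions.

    ``groups`` is a list of (label, n_young, n_total); the test is on the
    k x 2 table of (young, not-young) counts with df = k - 1.  No Yates
    continuity correction by default.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for label, ny, nt in groups:
        if nt <= 0 or ny < 0 or ny > nt:
            raise ValueError(f"group {label!r}: need 0 <= n_young <= n_total, n_total > 0")
    obs = np.array([[ny, nt - ny] for _, ny, nt in groups], dtype=float)
    expected = stats.contingency.expected_freq(obs)
    if (expected < 1).any():
        logger.warning("chi-square expected cell below 1; test may be unreliable")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return ProportionComparison(
        groups=tuple((str(l), int(ny), int(nt)) for l, ny, nt in groups),
        chi2=float(chi2),
        df=int(df),
        p=float(p),
    )
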