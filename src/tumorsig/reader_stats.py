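"""Reader-study ("visual Turing test") statistics.

Raters judge pairs of images (real vs model-generated); each decision is
right or wrong, so a rater's score over ``n`` items is modeled as
Binomial(n, p) with chance at p = 0.5. The exact two-sided test (tail
doubling, capped at 1) gives, for a given significance level, an interval
of accuracies statistically indistinguishable from guessing — for 40
items at alpha = 0.05 this is [0.35, 0.65]. A majority-vote ensemble
rater, Fleiss' kappa for inter-rater agreement, and Welch t-tests on
decision times complete the analysis. No multiple-comparison correction
is applied, by design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import inter_rater

__all__ = [
    "ReaderStudy", "binomial_two_sided_p", "chance_interval",
    "is_above_chance", "ensemble_majority", "fleiss_kappa", "compare_times",
    "analyze_study",
]


@dataclass(frozen=True)
class ReaderStudy:
    """Rater x item data of one experiment.

    ``choices`` holds each rater's chosen label per item (any hashable
    coding); ``answer_key`` the true labels; ``times`` optional per-
    decision seconds. ``correct`` derives the 0/1 correctness matrix.
    """

    choices: np.ndarray  # (raters, items)
    answer_key: np.ndarray  # (items,)
    times: np.ndarray | None = None  # (raters, items) seconds

    def __post_init__(self) -> None:
        choices = np.asarray(self.choices)
        key = np.asarray(self.answer_key)
        if choices.ndim != 2 or key.ndim != 1:
            raise ValueError("choices must be (raters, items), answer_key "
                             "(items,)")
        if choices.shape[1] != key.shape[0]:
            raise ValueError(
                f"choices have {choices.shape[1]} items but answer key has "
                f"{key.shape[0]}")
        if self.times is not None:
            times = np.asarray(self.times, dtype=float)
            if times.shape != choices.shape:
                raise ValueError("times must match choices in shape")
            if np.any(times <= 0):
                raise ValueError("decision times must be positive")

    @property
    def n_raters(self) -> int:
        return np.asarray(self.choices).shape[0]

    @property
    def n_items(self) -> int:
        return np.asarray(self.choices).shape[1]

    @property
    def correct(self) -> np.ndarray:
        return (np.asarray(self.choices)
                == np.asarray(self.answer_key)[None, :]).astype(int)

    @property
    def accuracies(self) -> np.ndarray:
        return self.correct.mean(axis=1)


def binomial_two_sided_p(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value by tail doubling, capped at 1.

    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` for X ~ Binomial(n, p0).
    At p0 = 0.5 this coincides with the equal-tailed exact test.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)  # P(X >= k)
    return float(min(1.0, 2.0 * min(lower, upper)))


def chance_interval(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Accuracy interval indistinguishable from chance at level ``alpha``.

    The upper endpoint is the largest ``k / n`` such that every success
    count from ``n/2`` up to ``k`` has an exact two-sided p-value
    >= alpha under Binomial(n, 0.5); the lower endpoint is its mirror
    ``1 - upper``. Endpoints are inclusive: accuracies strictly above the
    upper endpoint are significantly above chance.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    upper_k = n // 2
    for k in range(int(np.ceil(n / 2)), n + 1):
        if binomial_two_sided_p(k, n, 0.5) >= alpha:
            upper_k = k
        else:
            break
    return (1.0 - upper_k / n, upper_k / n)


def is_above_chance(accuracy: float, n: int, alpha: float = 0.05
                    ) -> tuple[bool, float]:
    """Flag an observed accuracy as significantly above chance.

    ``accuracy * n`` must be an integral success count. Returns
    ``(flag, p_value)`` where the flag is True iff the accuracy exceeds
    the upper endpoint of :func:`chance_interval`.
    """
    k_float = accuracy * n
    k = int(round(k_float))
    if abs(k_float - k) > 1e-9:
        raise ValueError(
            f"accuracy {accuracy} does not correspond to an integral "
            f"success count out of {n}")
    p = binomial_two_sided_p(k, n, 0.5)
    _, upper = chance_interval(n, alpha)
    return (accuracy > upper + 1e-12, p)


def ensemble_majority(choices: np.ndarray, answer_key: np.ndarray,
                      tie_rule=None) -> tuple[np.ndarray, float]:
    """Majority-vote ensemble rater.

    ``choices`` is (raters, items). With an even rater count a
    ``tie_rule(item_choices) -> choice`` callable must be supplied; with
    an odd count over binary choices ties cannot occur. Returns the
    per-item majority decisions and the ensemble accuracy against the
    answer key. The result is invariant to rater order.
    """
    choices = np.asarray(choices)
    answer_key = np.asarray(answer_key)
    n_raters, n_items = choices.shape
    if n_raters % 2 == 0 and tie_rule is None:
        raise ValueError("even number of raters: supply a tie_rule")
    decisions = []
    for j in range(n_items):
        vals, counts = np.unique(choices[:, j], return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        if len(winners) > 1:
            if tie_rule is None:
                raise ValueError(
                    f"tie among {list(winners)} on item {j} and no tie_rule")
            decisions.append(tie_rule(choices[:, j]))
        else:
            decisions.append(winners[0])
    decisions = np.asarray(decisions)
    accuracy = float(np.mean(decisions == answer_key))
    return decisions, accuracy


def fleiss_kappa(counts: np.ndarray) -> float:
    """Fleiss' kappa from an items x categories count table.

    Every item must be rated by the same number of raters (>= 2). Exactly
    1 under perfect agreement; NaN (with a warning) when all ratings fall
    in one category, where expected agreement is 1 and kappa is undefined.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D items x categories table")
    row_sums = counts.sum(axis=1)
    r = row_sums[0]
    if r < 2:
        raise ValueError("each item needs ratings from >= 2 raters")
    if not np.all(row_sums == r):
        raise ValueError(
            f"unequal rater counts per item: {sorted(set(row_sums))}")
    p_cat = counts.sum(axis=0) / counts.sum()
    if np.sum(p_cat**2) >= 1.0 - 1e-15:
        warnings.warn("all ratings in a single category: expected agreement "
                      "is 1, kappa undefined", stacklevel=2)
        return float("nan")
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def compare_times(times_a, times_b, equal_var: bool = False
                  ) -> tuple[float, float]:
    """Two-sided two-sample t-test on decision times (Welch by default).

    Degenerate case: both samples with zero variance and equal means
    returns ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return (0.0, 1.0)
        return (float("inf") * np.sign(a.mean() - b.mean()), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return (float(t), float(p))


def analyze_study(study: ReaderStudy, alpha: float = 0.05) -> dict:
    """Full per-experiment report: per-rater and ensemble inference.

    Mirrors the reader-study table layout: accuracy, exact p-value and
    above-chance flag per rater, the majority-vote ensemble row, the
    chance interval, Fleiss' kappa over the chosen labels, and mean
    decision times where available.
    """
    n = study.n_items
    interval = chance_interval(n, alpha)
    raters = []
    for i, acc in enumerate(study.accuracies):
        flag, p = is_above_chance(float(acc), n, alpha)
        row = {"rater": i + 1, "accuracy": float(acc), "p_value": p,
               "above_chance": bool(flag)}
        if study.times is not None:
            row["mean_time_s"] = float(np.mean(study.times[i]))
            row["sd_time_s"] = float(np.std(study.times[i], ddof=1))
        raters.append(row)

    _, ens_acc = ensemble_majority(study.choices, study.answer_key)
    ens_flag, ens_p = is_above_chance(ens_acc, n, alpha)

    choices = np.asarray(study.choices)
    cats = np.unique(choices)
    table = np.stack([
        (choices == cat).sum(axis=0) for cat in cats
    ], axis=1)
    kappa = fleiss_kappa(table)

    return {
        "n_items": n,
        "alpha": alpha,
        "chance_interval": list(interval),
        "raters": raters,
        "ensemble": {"accuracy": float(ens_acc), "p_value": ens_p,
                     "above_chance": bool(ens_flag)},
        "fleiss_kappa": kappa,
    }


def load_ratings(path) -> ReaderStudy:
    """Read a ratings CSV (columns: rater, item, choice, correct, time_s).

    ``correct`` is used to reconstruct an answer key on a 0/1 coding where
    choice labels are arbitrary: the stored choice is kept and the key is
    inferred as the choice where correct == 1 (must be consistent).
    """
    df = pd.read_csv(path)
    raters = np.sort(df["rater"].unique())
    items = np.sort(df["item"].unique())
    choices = df.pivot(index="rater", columns="item", values="choice") \
        .loc[raters, items].to_numpy()
    correct = df.pivot(index="rater", columns="item", values="correct") \
        .loc[raters, items].to_numpy()
    domain = np.unique(choices)
    key = []
    for j in range(len(items)):
        right = choices[correct[:, j] == 1, j]
        wrong = np.unique(choices[correct[:, j] == 0, j])
        if len(right):
            key.append(right[0])
        else:
            # everyone wrong: in a binary coding all wrong choices must be
            # the same value and the key is the other one
            others = [v for v in domain if v not in wrong]
            if len(others) != 1:
                raise ValueError(f"item {items[j]}: ambiguous answer key "
                                 f"(choice domain {domain.tolist()})")
            key.append(others[0])
    times = None
    if "time_s" in df.columns and df["time_s"].notna().all():
        times = df.pivot(index="rater", columns="item", values="time_s") \
            .loc[raters, items].to_numpy()
    return ReaderStudy(choices, np.asarray(key), times)


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
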