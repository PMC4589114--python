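"""Misclassification rate and binomial significance of a clustering.

Cluster labels are only defined up to permutation, so errors are counted
after the best bijection between predicted and true label sets.  The
significance of an outcome is judged against random assignment: with k
groups a random guess is correct with probability 1/k per sequence, so
the number of errors among N sequences is Binomial(N, (k-1)/k) under the
null, and the reported p-value is the lower tail P(errors <= n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import binom

__all__ = ["TrialOutcome", "missrate", "error_pmf", "pvalue_at_most"]


@dataclass
class TrialOutcome:
    """Error count and significance of one clustering trial."""

    N: int
    n_errors: int
    k: int
    missrate: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_errors <= self.N:
            raise ValueError("error count outside [0, N]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _check_labels(labels: np.ndarray, k: int, name: str) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 1 or labels.max() > k):
        raise ValueError(f"{name} labels must lie in [1, {k}]")
    return labels


def missrate(
    truth: np.ndarray, predicted: np.ndarray, k: int
) -> tuple[int, float]:
    """Error count and rate under optimal label matching.

    Minimizes mismatches over bijections of the predicted label set onto
    the truth label set: exhaustive over the k! maps for k <= 8, optimal
    assignment on the confusion matrix beyond (both reach the same
    optimum; the assignment step is the standard Hungarian route).
    Returns ``(n_errors, n_errors / N)``.
    """
    truth = _check_labels(truth, k, "truth")
    predicted = _check_labels(predicted, k, "predicted")
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    N = len(truth)
    if N == 0:
        raise ValueError("empty label vectors")
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (truth - 1, predicted - 1), 1)
    if k <= 8:
        best = max(
            sum(confusion[perm[j], j] for j in range(k))
            for perm in permutations(range(k))
        )
    else:
        rows, cols = linear_sum_assignment(-confusion)
        best = int(confusion[rows, cols].sum())
    n_errors = N - int(best)
    return n_errors, n_errors / N


def error_pmf(N: int, n: int, k: int) -> float:
    """Probability of exactly n random-assignment errors among N items.

    The null model assigns each item independently, succeeding with
    probability p_s = 1/k, so n errors occur with binomial mass
    C(N, n) p_s^(N-n) (1 - p_s)^n.  Evaluated in log space.
    """
    if k < 2:
        raise ValueError("need at least k = 2 groups")
    if not 0 <= n <= N:
        raise ValueError("n must lie in [0, N]")
    return float(np.exp(binom.logpmf(n, N, (k - 1) / k)))


def pvalue_at_most(N: int, n: int, k: int) -> float:
    """Lower-tail probability of n errors or fewer under random assignment.

    Strictly increasing in n and equal to 1 at n = N.  Small values mean
    the observed error count is far below what chance alone produces.
    """
    if k < 2:
        raise ValueError("need at least k = 2 groups")
    if not 0 <= n <= N:
        raise ValueError("n must lie in [0, N]")
    return float(binom.cdf(n, N, (k - 1) / k))
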