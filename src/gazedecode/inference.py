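"""Within-participant permutation testing and group-level inference.

The permutation test shuffles trial labels once per permutation and
re-runs the entire cross-validated decoding, giving a valid add-one
p-value.  Group inference is a one-sided Wilcoxon signed-rank test of
participant accuracies against chance, with zero differences kept in
the ranking (Pratt convention) and an exact null for small groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps


class InferenceError(ValueError):
    pass


@dataclass
class TestReport:
    statistic: float
    p_value: float
    alpha: float = 0.05
    n_null: int = 0
    significant: bool = False
    correction: str = "none"
    p_values: Optional[list[float]] = None        # per-timepoint, if applicable
    adjusted_alpha: Optional[float] = None
    extra: dict = field(default_factory=dict)


def permutation_test(
    decode_fn: Callable,
    trials,
    labels: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    runs: Optional[Sequence] = None,
) -> TestReport:
    """Label-permutation null for a cross-validated decoding accuracy.

    ``decode_fn(trials, labels) -> accuracy`` must run the complete CV
    pipeline; labels are permuted once per permutation, before any fold
    split.  p = (1 + #{perm >= observed}) / (n_perm + 1), never exactly
    zero.

    When ``runs`` is given, labels are permuted independently within
    each run.  With a run-balanced design (every run presents every
    label once) this re-draws the labels exactly the way the experiment
    schedule randomizes them, making the test exact; a whole-session
    permutation would break the run balance and shift the null of a
    leave-one-run-out decoder below chance, inflating false positives.
    Without ``runs`` the labels are permuted across the whole session.
    """
    if n_perm < 1:
        raise InferenceError("n_perm must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if runs is not None:
        runs = np.asarray(runs)
        run_groups = [np.nonzero(runs == r)[0] for r in np.unique(runs)]

        def draw():
            perm = labels.copy()
            for idx in run_groups:
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
            return perm
    else:
        def draw():
            return rng.permutation(labels)

    observed = float(decode_fn(trials, labels))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = decode_fn(trials, draw())
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_perm + 1.0)
    return TestReport(
        statistic=observed, p_value=float(p), alpha=alpha, n_null=n_perm,
        significant=p < alpha, extra={"null_mean": float(null.mean())},
    )


def _exact_pratt_greater(diffs: np.ndarray) -> tuple[float, float]:
    """Exact one-sided (greater) signed-rank p with zeros kept in ranking.

    Ranks all |d| including zeros, discards the zero ranks, and
    enumerates the sign-flip null of the remaining ranks by dynamic
    programming over the rank-sum distribution.  Average ranks for ties
    are handled by doubling to integers.
    """
    ranks = sps.rankdata(np.abs(diffs))
    nonzero = diffs != 0
    if not nonzero.any():
        return 0.0, 1.0
    r2 = np.rint(2.0 * ranks[nonzero]).astype(int)  # doubled ranks are integral
    w_obs2 = int(np.rint(2.0 * np.sum(ranks[nonzero & (diffs > 0)])))
    total = int(r2.sum())
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dp)
        shifted[r:] = dp[:-r] if r > 0 else dp
        dp = 0.5 * (dp + shifted)
    p = float(dp[w_obs2:].sum())
    return w_obs2 / 2.0, min(p, 1.0)


def wilcoxon_group(
    accuracies: Sequence[float],
    chance: float = 1.0 / 8.0,
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> TestReport:
    """One-sided group test: are accuracies above chance?

    Wilcoxon signed-rank on (accuracy - chance), alternative 'greater',
    zero differences included in the ranking (Pratt).  Exact null
    distribution up to ``exact_max_n`` participants, normal
    approximation beyond.  All-zero differences give p = 1 by
    convention.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size < 2:
        raise InferenceError("group test needs >= 2 participants")
    diffs = accuracies - chance
    if np.all(diffs == 0):
        return TestReport(statistic=0.0, p_value=1.0, alpha=alpha,
                          significant=False, extra={"n": int(diffs.size)})
    if diffs.size <= exact_max_n:
        w, p = _exact_pratt_greater(diffs)
        mode = "exact"
    else:
        res = sps.wilcoxon(diffs, zero_method="pratt", alternative="greater",
                           method="approx")
        w, p = float(res.statistic), float(res.pvalue)
        mode = "approx"
    return TestReport(statistic=w, p_value=p, alpha=alpha, significant=p < alpha,
                      extra={"n": int(diffs.size), "mode": mode})


def bonferroni_timepoints(p_values: Sequence[float], alpha: float = 0.05) -> TestReport:
    """Bonferroni control over per-timepoint tests.

    A timepoint is significant iff its raw p < alpha / n_tests; the
    report carries both the adjusted threshold and min-adjusted p.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size < 1:
        raise InferenceError("need at least one p-value")
    n = p_values.size
    threshold = alpha / n
    sig = p_values < threshold
    p_min_adj = float(min(1.0, p_values.min() * n))
    return TestReport(
        statistic=float(p_values.min()), p_value=p_min_adj, alpha=alpha,
        significant=bool(sig.any()), correction="bonferroni",
        p_values=[float(v) for v in p_values], adjusted_alpha=threshold,
        extra={"n_tests": int(n), "n_significant": int(sig.sum())},
    )
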