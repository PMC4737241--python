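"""Bootstrap confidence intervals and permutation tests over contig sets.

Contigs (not sites) are the resampling unit throughout: divergence and
polymorphism counts are correlated within a contig, so resampling whole
contigs preserves that dependence.  The percentile bootstrap is used for
confidence intervals; permutation tests redraw category labels over the
pooled contigs with group sizes fixed, and p-values carry add-one
smoothing so they are never smaller than 1/(n_perm + 1).

Two surfaces are provided: a generic one taking an arbitrary statistic of
a record list, and vectorized ratio-of-sums kernels used by the rate
estimators, which resample index matrices and reduce with numpy (all of
the pipeline's statistics are functions of per-category column sums).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

ONE_TAILED_GREATER = "one_tailed_greater"
TWO_TAILED = "two_tailed"


@dataclass
class ResamplingPlan:
    """Replicate counts, seed and tail for one inference task."""

    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    tail: str = ONE_TAILED_GREATER

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")
        if self.tail not in (ONE_TAILED_GREATER, TWO_TAILED):
            raise ValueError(f"unknown tail {self.tail!r}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one named stream of this plan."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


MAX_UNDEFINED_FRACTION = 0.5


def _finite_or_error(values: np.ndarray, what: str) -> np.ndarray:
    ok = np.isfinite(values)
    frac_bad = 1.0 - ok.mean() if values.size else 1.0
    if frac_bad > MAX_UNDEFINED_FRACTION:
        raise ValueError(
            f"{what}: statistic undefined on {frac_bad:.0%} of replicates "
            f"(more than {MAX_UNDEFINED_FRACTION:.0%})"
        )
    return values[ok]


def bootstrap_ci(
    records: Sequence,
    statistic: Callable[[Sequence], float],
    plan: ResamplingPlan,
) -> tuple[float, float]:
    """Percentile 95% CI of ``statistic`` under contig resampling.

    Records are resampled with replacement ``plan.n_boot`` times and the
    2.5th/97.5th percentiles of the replicate statistics returned.
    Replicates on which the statistic is undefined (NaN/inf, e.g. a zero
    synonymous sum) are dropped; if more than half are undefined the CI is
    refused.
    """
    if not records:
        raise ValueError("bootstrap_ci: empty record list")
    rng = plan.rng(stream=1)
    n = len(records)
    reps = np.empty(plan.n_boot)
    for b in range(plan.n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps[b] = statistic([records[i] for i in idx])
        except (ZeroDivisionError, ValueError):
            reps[b] = np.nan
    reps = _finite_or_error(reps, "bootstrap_ci")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_test(
    records_a: Sequence,
    records_b: Sequence,
    statistic_difference: Callable[[Sequence, Sequence], float],
    plan: ResamplingPlan,
) -> float:
    """Label-permutation p-value for a two-group statistic difference.

    Pools the two groups, redraws group membership with sizes fixed, and
    recomputes ``statistic_difference(group_a, group_b)`` each time.  With
    the one-tailed-greater tail, p = (1 + #{replicate >= observed}) /
    (n_perm + 1); the two-tailed variant compares absolute values.
    """
    if not records_a or not records_b:
        raise ValueError("permutation_test: both groups must be non-empty")
    observed = statistic_difference(records_a, records_b)
    pooled = list(records_a) + list(records_b)
    n_a = len(records_a)
    rng = plan.rng(stream=2)
    reps = np.empty(plan.n_perm)
    for b in range(plan.n_perm):
        perm = rng.permutation(len(pooled))
        ga = [pooled[i] for i in perm[:n_a]]
        gb = [pooled[i] for i in perm[n_a:]]
        try:
            reps[b] = statistic_difference(ga, gb)
        except (ZeroDivisionError, ValueError):
            reps[b] = np.nan
    reps = _finite_or_error(reps, "permutation_test")
    return _smoothed_p(observed, reps, len(reps), plan.tail)


def _smoothed_p(observed: float, reps: np.ndarray, n: int, tail: str) -> float:
    if tail == TWO_TAILED:
        count = int(np.sum(np.abs(reps) >= abs(observed)))
    else:
        count = int(np.sum(reps >= observed))
    return (1 + count) / (n + 1)


# ---------------------------------------------------------------------------
# vectorized kernels for statistics that are functions of column sums


def bootstrap_sums(X: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Column sums of ``n_boot`` with-replacement row resamples of X (n x k).

    Returns an (n_boot x k) matrix; row b holds the column sums of the
    b-th bootstrap resample.
    """
    n = X.shape[0]
    idx = rng.integers(0, n, (n_boot, n))
    return X[idx].sum(axis=1)


def bootstrap_ci_sums(
    X: np.ndarray,
    stat_of_sums: Callable[[np.ndarray], np.ndarray],
    plan: ResamplingPlan,
    stream: int = 1,
) -> tuple[float, float]:
    """Percentile CI for a statistic defined on column sums of X."""
    sums = bootstrap_sums(np.asarray(X, dtype=float), plan.n_boot, plan.rng(stream))
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = np.asarray(stat_of_sums(sums), dtype=float)
    reps = _finite_or_error(reps, "bootstrap_ci")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_ci_two_group(
    X_a: np.ndarray,
    X_b: np.ndarray,
    stat_of_sums: Callable[[np.ndarray, np.ndarray], np.ndarray],
    plan: ResamplingPlan,
) -> tuple[float, float]:
    """Percentile CI for a statistic of the column sums of two groups.

    Each group is resampled independently (within-category resampling).
    """
    rng_a, rng_b = plan.rng(stream=1), plan.rng(stream=11)
    sums_a = bootstrap_sums(np.asarray(X_a, dtype=float), plan.n_boot, rng_a)
    sums_b = bootstrap_sums(np.asarray(X_b, dtype=float), plan.n_boot, rng_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = np.asarray(stat_of_sums(sums_a, sums_b), dtype=float)
    reps = _finite_or_error(reps, "bootstrap_ci")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_p_two_group(
    X_a: np.ndarray,
    X_b: np.ndarray,
    stat_of_sums: Callable[[np.ndarray, np.ndarray], np.ndarray],
    plan: ResamplingPlan,
) -> float:
    """Vectorized label-permutation p for a column-sum statistic.

    ``stat_of_sums`` maps (sums_a, sums_b), each (B x k), to B statistic
    values; the observed value uses B = 1.
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        observed = float(
            np.asarray(stat_of_sums(X_a.sum(0, keepdims=True), X_b.sum(0, keepdims=True)))[0]
        )
    if not np.isfinite(observed):
        raise ValueError("permutation test: observed statistic undefined")
    pooled = np.vstack([X_a, X_b])
    n_a, n = X_a.shape[0], pooled.shape[0]
    rng = plan.rng(stream=2)
    # one permutation per row: argsort of iid uniforms
    order = np.argsort(rng.random((plan.n_perm, n)), axis=1)
    sums_a = pooled[order[:, :n_a]].sum(axis=1)
    sums_b = pooled.sum(axis=0, keepdims=True) - sums_a
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = np.asarray(stat_of_sums(sums_a, sums_b), dtype=float)
    reps = _finite_or_error(reps, "permutation_test")
    return _smoothed_p(observed, reps, len(reps), plan.tail)
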