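"""Concatenated per-category divergence rates and the Faster-Z ratio.

Rates are always the ratio of summed counts to summed sites across all
contigs in a category (d_N = sum D_N / sum N, d_S = sum D_S / sum S),
never the mean of per-contig ratios: concatenation avoids the unstable,
effectively infinite dN/dS values thrown off by short contigs with tiny
synonymous divergence and weights every site equally.  The Faster-Z
effect is the ratio of category omegas, (d_NZ/d_SZ) / (d_NA/d_SA); a
polymorphism-based analogue uses p_N/p_S built from the same estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fasterz.resampling import (
    ResamplingPlan,
    bootstrap_ci_sums,
    bootstrap_ci_two_group,
    permutation_p_two_group,
)

logger = logging.getLogger("fasterz")

_FIELD_PAIRS = {
    "D_N": "N", "D_S": "S",   # divergence
    "P_N": "N", "P_S": "S",   # polymorphism
    "P_4D": "L_4D",           # fourfold-degenerate diversity
}


@dataclass
class RateEstimate:
    """A concatenated rate: Σ events / Σ sites with a bootstrap 95% CI."""

    sum_events: float
    sum_sites: float
    rate: float
    ci_low: float
    ci_high: float
    n_contigs: int

    def to_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class RatioResult:
    """Ratio of two category rates (the Faster-Z effect) with inference."""

    numerator_rate: float
    denominator_rate: float
    ratio: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_boot: int
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def saturation_filter(records: Sequence, ds_max: float = 2.0) -> list:
    """Drop contigs whose whole-tree synonymous divergence exceeds ds_max.

    Synonymous sites saturate at high divergence, biasing dS downward and
    dN/dS upward; contigs with tree-wide dS above the threshold are
    removed.  The inequality is strict: a contig at exactly ds_max is kept.
    """
    if ds_max <= 0:
        raise ValueError("ds_max must be positive")
    kept = [r for r in records if r.tree_dS <= ds_max]
    if len(kept) < len(records):
        logger.info("saturation filter (dS > %g): removed %d of %d contigs",
                    ds_max, len(records) - len(kept), len(records))
    return kept


def _events_sites(records: Sequence, events_field: str, sites_field: str | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    if events_field not in _FIELD_PAIRS:
        raise ValueError(f"unknown events field {events_field!r}")
    sites_field = sites_field or _FIELD_PAIRS[events_field]
    ev = np.array([getattr(r, events_field) for r in records], dtype=float)
    si = np.array([getattr(r, sites_field) for r in records], dtype=float)
    return ev, si


def concatenated_rate(
    records: Sequence,
    events_field: str,
    sites_field: str | None = None,
    plan: ResamplingPlan | None = None,
) -> RateEstimate:
    """Σ events / Σ sites over a category, with optional bootstrap CI.

    ``sites_field`` defaults to the natural partner of ``events_field``
    (N for D_N/P_N, S for D_S/P_S, L_4D for P_4D).  Without a plan the CI
    bounds are NaN.
    """
    if not records:
        raise ValueError(f"concatenated_rate({events_field}): empty record list")
    ev, si = _events_sites(records, events_field, sites_field)
    total_sites = si.sum()
    if total_sites <= 0:
        raise ValueError(f"concatenated_rate({events_field}): zero site total")
    rate = ev.sum() / total_sites
    ci_low = ci_high = float("nan")
    if plan is not None:
        X = np.column_stack([ev, si])
        ci_low, ci_high = bootstrap_ci_sums(X, lambda s: s[:, 0] / s[:, 1], plan)
    return RateEstimate(float(ev.sum()), float(total_sites), float(rate),
                        ci_low, ci_high, len(records))


def omega(rate_N: RateEstimate, rate_S: RateEstimate) -> float:
    """dN/dS (or pN/pS) from two concatenated rates."""
    if rate_S.rate <= 0:
        raise ValueError("undefined omega: synonymous rate is zero")
    return rate_N.rate / rate_S.rate


def _omega_of_sums(s: np.ndarray) -> np.ndarray:
    # s columns: [events_N, sites_N, events_S, sites_S]
    return (s[:, 0] / s[:, 1]) / (s[:, 2] / s[:, 3])


def faster_z(
    records_z: Sequence,
    records_ref: Sequence,
    events_n_field: str = "D_N",
    events_s_field: str = "D_S",
    plan: ResamplingPlan | None = None,
    with_permutation: bool = True,
) -> RatioResult:
    """Faster-Z effect: (dN_Z/dS_Z) / (dN_A/dS_A), with inference.

    Works identically for polymorphism fields (P_N/P_S), yielding the
    pN/pS-based effect.  The bootstrap resamples contigs with replacement
    within each category; the permutation test redraws Z/reference labels
    over the pooled contigs.  By default the permutation p is one-tailed
    (is the Z ratio greater?), following the directional Faster-Z
    hypothesis.
    """
    if not records_z or not records_ref:
        raise ValueError("faster_z: both categories must be non-empty")

    def matrix(records):
        ev_n, si_n = _events_sites(records, events_n_field)
        ev_s, si_s = _events_sites(records, events_s_field)
        return np.column_stack([ev_n, si_n, ev_s, si_s])

    X_z, X_a = matrix(records_z), matrix(records_ref)
    w_z = _omega_of_sums(X_z.sum(0, keepdims=True))[0]
    w_a = _omega_of_sums(X_a.sum(0, keepdims=True))[0]
    if not np.isfinite(w_z) or not np.isfinite(w_a) or w_a == 0:
        raise ValueError("undefined omega: zero synonymous rate in a category")
    ratio = float(w_z / w_a)

    ci_low = ci_high = p_perm = float("nan")
    n_boot = n_perm = 0
    seed = 0
    if plan is not None:
        ci_low, ci_high = bootstrap_ci_two_group(
            X_z, X_a, lambda sa, sb: _omega_of_sums(sa) / _omega_of_sums(sb), plan)
        n_boot, seed = plan.n_boot, plan.seed
        if with_permutation:
            p_perm = permutation_p_two_group(
                X_z, X_a, lambda sa, sb: _omega_of_sums(sa) / _omega_of_sums(sb), plan)
            n_perm = plan.n_perm
    return RatioResult(float(w_z), float(w_a), ratio, ci_low, ci_high,
                       p_perm, n_boot, n_perm, seed)


def rate_contrast_p(
    records_z: Sequence,
    records_ref: Sequence,
    events_field: str,
    plan: ResamplingPlan,
) -> float:
    """Permutation p for a single-rate contrast (e.g. dN_Z vs dN_A).

    Statistic: difference of concatenated rates, Z minus reference;
    one-tailed-greater by default per the plan.
    """
    ev_z, si_z = _events_sites(records_z, events_field)
    ev_a, si_a = _events_sites(records_ref, events_field)
    X_z = np.column_stack([ev_z, si_z])
    X_a = np.column_stack([ev_a, si_a])
    return permutation_p_two_group(
        X_z, X_a, lambda sa, sb: sa[:, 0] / sa[:, 1] - sb[:, 0] / sb[:, 1], plan)


def ds_homogeneity_test(
    records_by_species: dict[str, Sequence],
    plan: ResamplingPlan,
) -> float:
    """Permutation test for differences in concatenated dS across species.

    Guards the Faster-Z comparison against lineage-specific mutation-rate
    variation (e.g. differing male mutation bias).  Statistic: variance of
    the per-species concatenated dS; species labels are permuted over the
    pooled contigs with group sizes fixed; p is the upper tail.
    """
    names = sorted(records_by_species)
    if len(names) < 2:
        raise ValueError("need at least two species")
    mats = []
    sizes = []
    for name in names:
        ev, si = _events_sites(records_by_species[name], "D_S")
        mats.append(np.column_stack([ev, si]))
        sizes.append(len(ev))
    pooled = np.vstack(mats)
    bounds = np.cumsum([0] + sizes)

    def stat(order: np.ndarray) -> np.ndarray:
        # order: (B, n) row indices; returns per-row variance of group rates
        rates = np.empty((order.shape[0], len(sizes)))
        for g in range(len(sizes)):
            grp = pooled[order[:, bounds[g]:bounds[g + 1]]]
            s = grp.sum(axis=1)
            rates[:, g] = s[:, 0] / s[:, 1]
        return rates.var(axis=1)

    n = pooled.shape[0]
    observed = float(stat(np.arange(n)[None, :])[0])
    rng = plan.rng(stream=3)
    order = np.argsort(rng.random((plan.n_perm, n)), axis=1)
    reps = stat(order)
    return (1 + int(np.sum(reps >= observed))) / (plan.n_perm + 1)
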