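"""SNP filtering, polymorphism-based Faster-Z, McDonald-Kreitman tests
and contingency analyses.

The McDonald-Kreitman test contrasts fixed differences (D_N, D_S) with
polymorphisms (P_N, P_S) in a 2x2 table: under neutrality the
nonsynonymous/synonymous ratio is the same within and between species.
An excess of nonsynonymous divergence relative to polymorphism,
(D_N/D_S) > (P_N/P_S), indicates positive selection; the reverse excess
indicates relaxed purifying selection (segregating mildly deleterious
alleles).  Per-contig tests are corrected with q-values; the
concatenated P_N/P_S contrast between the Z chromosome and autosomes
uses a single chi-squared test per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from fasterz.divergence_rates import RatioResult, faster_z
from fasterz.resampling import ResamplingPlan
from fasterz.tables_io import RunConfig, SnpCall

logger = logging.getLogger("fasterz")

DIRECTION_POSITIVE = "positive"
DIRECTION_RELAXED = "relaxed"
DIRECTION_NONE = "none"

MK_MARGINAL_MIN = 6  # minimum marginal row/column sum for per-contig MK tests


@dataclass
class MKResult:
    contig_id: str
    D_N: float
    D_S: float
    P_N: float
    P_S: float
    included: bool
    chi2: float | None = None
    p: float | None = None
    q: float | None = None
    direction: str | None = None


@dataclass
class ContingencyResult:
    """2x2 contingency test outcome; ratio is the cross-ratio (a/b)/(c/d)."""

    table: tuple[tuple[float, float], tuple[float, float]]
    chi2: float
    p: float
    ratio: float | None


def filter_snps(calls: Sequence[SnpCall], config: RunConfig) -> list[SnpCall]:
    """Apply the SNP quality filter.

    A call is retained when its minor allele frequency strictly exceeds
    ``config.maf_min`` and at least 4 samples support it with read depth
    > 20 and Phred quality > 20.  Rejection counts per rule are logged.
    """
    kept: list[SnpCall] = []
    rej_maf = rej_support = 0
    for call in calls:
        if call.maf <= config.maf_min:
            rej_maf += 1
            continue
        support = sum(
            1 for d, q in zip(call.per_sample_depth, call.per_sample_qual)
            if d > 20 and q > 20
        )
        if support < 4:
            rej_support += 1
            continue
        kept.append(call)
    logger.info(
        "SNP filter: %d in, %d rejected on MAF <= %g, %d on depth/quality support, %d retained",
        len(calls), rej_maf, config.maf_min, rej_support, len(kept),
    )
    return kept


def pnps_faster_z(
    records_z: Sequence,
    records_a: Sequence,
    plan: ResamplingPlan | None = None,
) -> RatioResult:
    """Polymorphism-based Faster-Z: (pN_Z/pS_Z) / (pN_A/pS_A)."""
    return faster_z(records_z, records_a, events_n_field="P_N",
                    events_s_field="P_S", plan=plan)


def chi2_2x2(
    a: float, b: float, c: float, d: float,
    method: str = "yates",
    n_mc: int = 2000,
    seed: int = 0,
) -> ContingencyResult:
    """Chi-squared test of independence on the 2x2 table [[a, b], [c, d]].

    ``yates`` applies the continuity correction
    chi2 = n (|ad - bc| - n/2)^2 / (r1 r2 c1 c2), with the corrected
    numerator floored at zero; ``pearson`` is the uncorrected statistic;
    ``montecarlo`` keeps the Pearson statistic but takes the p-value from
    ``n_mc`` tables drawn with both margins fixed (hypergeometric), with
    add-one smoothing.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("degenerate table: empty")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: a zero margin")

    def pearson_stat(aa, bb, cc, dd):
        return n * (aa * dd - bb * cc) ** 2 / (r1 * r2 * c1 * c2)

    if method == "yates":
        num = max(abs(a * d - b * c) - n / 2.0, 0.0)
        chi2 = n * num * num / (r1 * r2 * c1 * c2)
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "pearson":
        chi2 = pearson_stat(a, b, c, d)
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "montecarlo":
        chi2 = pearson_stat(a, b, c, d)
        rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
        # draw cell (1,1) with both margins fixed
        aa = rng.hypergeometric(int(round(r1)), int(round(r2)), int(round(c1)), n_mc)
        sim = pearson_stat(aa, r1 - aa, c1 - aa, r2 - c1 + aa)
        p = (1 + int(np.sum(sim >= chi2 - 1e-12))) / (n_mc + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    ratio = (a / b) / (c / d) if b > 0 and c > 0 and d > 0 else None
    return ContingencyResult(((a, b), (c, d)), float(chi2), float(p), ratio)


def mk_test(
    contig_id: str,
    D_N: float, D_S: float, P_N: float, P_S: float,
    method: str = "yates",
    n_mc: int = 2000,
    seed: int = 0,
) -> MKResult:
    """McDonald-Kreitman test for one contig.

    The contig enters the test only when every marginal sum of the 2x2
    table [[D_N, D_S], [P_N, P_S]] is at least 6; sparser tables carry
    too little information and are marked ``included=False`` (a state,
    not an error).  Direction is ``positive`` when (D_N/D_S) > (P_N/P_S)
    with both ratios defined, ``relaxed`` for the reverse (including the
    effectively infinite polymorphism ratio P_S = 0 < P_N when D_N/D_S is
    finite), and ``none`` for ties or undefined comparisons (D_S = 0, or
    P_N = P_S = 0).
    """
    if min(D_N, D_S, P_N, P_S) < 0:
        raise ValueError("counts must be nonnegative")
    margins = (D_N + D_S, P_N + P_S, D_N + P_N, D_S + P_S)
    if min(margins) < MK_MARGINAL_MIN:
        return MKResult(contig_id, D_N, D_S, P_N, P_S, included=False)
    res = chi2_2x2(D_N, D_S, P_N, P_S, method=method, n_mc=n_mc, seed=seed)

    if D_S == 0:
        direction = DIRECTION_NONE
    elif P_S == 0:
        direction = DIRECTION_RELAXED if P_N > 0 else DIRECTION_NONE
    else:
        div_ratio, poly_ratio = D_N / D_S, P_N / P_S
        if div_ratio > poly_ratio:
            direction = DIRECTION_POSITIVE
        elif div_ratio < poly_ratio:
            direction = DIRECTION_RELAXED
        else:
            direction = DIRECTION_NONE
    return MKResult(contig_id, D_N, D_S, P_N, P_S, included=True,
                    chi2=res.chi2, p=res.p, direction=direction)


def mk_tests(
    div_records: Sequence,
    poly_records: Sequence,
    method: str = "yates",
    fdr: float = 0.05,
    qvalue_lambda: float = 0.0,
    seed: int = 0,
) -> list[MKResult]:
    """Run MK tests contig-by-contig and attach q-values across the set.

    Divergence and polymorphism records are joined on contig_id; contigs
    present in only one table are skipped with a logged count.
    """
    poly_by_id = {r.contig_id: r for r in poly_records}
    results = []
    unmatched = 0
    for div in div_records:
        poly = poly_by_id.get(div.contig_id)
        if poly is None:
            unmatched += 1
            continue
        results.append(mk_test(div.contig_id, div.D_N, div.D_S,
                               poly.P_N, poly.P_S, method=method, seed=seed))
    if unmatched:
        logger.info("MK: %d divergence contigs had no polymorphism record", unmatched)
    included = [r for r in results if r.included]
    if included:
        qs = qvalues([r.p for r in included], lam=qvalue_lambda)
        for r, q in zip(included, qs):
            r.q = float(q)
    logger.info("MK: %d contigs tested, %d excluded by the marginal>=%d rule",
                len(included), len(results) - len(included), MK_MARGINAL_MIN)
    return results


def qvalues(pvals: Sequence[float], lam: float = 0.0) -> np.ndarray:
    """Storey q-values with a fixed pi0 tuning parameter ``lam``.

    pi0 is estimated as #{p > lam} / ((1 - lam) m), clamped to (0, 1];
    with lam = 0 (and no p exactly 0) pi0 = 1 and the q-values coincide
    with Benjamini-Hochberg adjusted p-values: q(i) = min over j >= i of
    pi0 * m * p(j) / j on the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 <= lam < 1):
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = np.sum(p > lam) / ((1.0 - lam) * m)
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def concatenated_pnps_test(
    records_z: Sequence,
    records_a: Sequence,
    method: str = "yates",
) -> ContingencyResult:
    """Chi-squared contrast of concatenated P_N/P_S between Z and autosomes.

    Sums P_N and P_S over each category and tests the 2x2 table
    [[P_NZ, P_SZ], [P_NA, P_SA]]; the reported ratio
    (P_NZ/P_SZ)/(P_NA/P_SA) is the count-based Faster-Z effect.
    """
    if not records_z or not records_a:
        raise ValueError("both categories must be non-empty")
    pn_z = sum(r.P_N for r in records_z)
    ps_z = sum(r.P_S for r in records_z)
    pn_a = sum(r.P_N for r in records_a)
    ps_a = sum(r.P_S for r in records_a)
    return chi2_2x2(pn_z, ps_z, pn_a, ps_a, method=method)


def proportion_selected_test(
    k_z: int, n_z: int, k_a: int, n_a: int, method: str = "yates"
) -> ContingencyResult:
    """Compare the proportion of positively selected loci on Z vs autosomes."""
    if k_z > n_z or k_a > n_a:
        raise ValueError("selected count exceeds category size")
    return chi2_2x2(k_z, n_z - k_z, k_a, n_a - k_a, method=method)
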