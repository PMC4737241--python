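"""Sex-bias expression classification and per-class Faster-Z.

Genes are classified from gonad RPKM as male-biased, female-biased,
unbiased or sex-limited, using a fold-change threshold of |log2 FC| >= 1
together with a Welch t-test corrected by Benjamini-Hochberg.  Cross-
species class maps (a strict all-species-conserved scheme and a relaxed
majority scheme) feed per-class Faster-Z contrasts: if positive
selection on sexually antagonistic variation drives Faster-Z, the
effect should concentrate in female-biased genes (which spend most of
their selective history hemizygous in females); if drift dominates, the
effect should be uniform across classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fasterz.divergence_rates import RatioResult, faster_z
from fasterz.resampling import TWO_TAILED, ResamplingPlan, permutation_p_two_group

logger = logging.getLogger("fasterz")

MALE_BIASED = "male_biased"
FEMALE_BIASED = "female_biased"
UNBIASED = "unbiased"
MALE_LIMITED = "male_limited"
FEMALE_LIMITED = "female_limited"

PUTATIVE_FEMALE = "putative_female"
PUTATIVE_MALE = "putative_male"
OTHER = "other"


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    species: str
    tissue: str
    sample_values: tuple[float, ...]
    sample_sex: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_values) != len(self.sample_sex):
            raise ValueError(f"{self.gene_id}: values/sex labels differ in length")
        if any(v < 0 for v in self.sample_values):
            raise ValueError(f"{self.gene_id}: negative RPKM")

    def by_sex(self, sex: str) -> np.ndarray:
        return np.array([v for v, s in zip(self.sample_values, self.sample_sex)
                         if s == sex], dtype=float)


@dataclass
class SexBiasCall:
    gene_id: str
    species: str
    log2fc: float  # log2(mean male RPKM) - log2(mean female RPKM)
    p: float
    padj: float
    klass: str


def rpkm_filter(records: Sequence[ExpressionRecord], threshold: float = 2.0
                ) -> list[ExpressionRecord]:
    """Keep genes expressed above ``threshold`` RPKM (unlogged) in at
    least half of the samples of at least one sex-tissue group.

    The comparison is strict: a sample at exactly the threshold does not
    count as expressed.  Filtering is per gene; a gene is judged on all
    its records (one per species-tissue) jointly within each record.
    """
    kept = []
    for rec in records:
        groups: dict[tuple[str, str], list[float]] = {}
        for v, s in zip(rec.sample_values, rec.sample_sex):
            groups.setdefault((s, rec.tissue), []).append(v)
        if not groups:
            raise ValueError(f"{rec.gene_id}: no sample groups")
        if any(sum(v > threshold for v in vals) >= 0.5 * len(vals)
               for vals in groups.values()):
            kept.append(rec)
    logger.info("RPKM filter (> %g in >= half of a sex-tissue group): %d of %d genes kept",
                threshold, len(kept), len(records))
    return kept


def _log2fc(male_mean: float, female_mean: float) -> float:
    if male_mean == 0 and female_mean == 0:
        return 0.0
    if female_mean == 0:
        return math.inf
    if male_mean == 0:
        return -math.inf
    return math.log2(male_mean) - math.log2(female_mean)


def classify_sex_bias(
    records: Sequence[ExpressionRecord],
    fdr: float = 0.05,
) -> list[SexBiasCall]:
    """Classify genes of one species-tissue set by sex bias.

    Fold change is log2(mean male RPKM) - log2(mean female RPKM) on raw
    means.  A Welch two-sample t-test on log2(RPKM + 1) provides p-values,
    Benjamini-Hochberg adjusted across the whole gene set.  Classes:

    - sex-limited: one sex's mean RPKM is exactly 0 (fold change infinite);
    - male/female-biased: significant (adjusted p < fdr) and |log2 FC| >= 1;
    - unbiased: everything else.
    """
    if not records:
        return []
    raw_p = np.empty(len(records))
    fcs = np.empty(len(records))
    for i, rec in enumerate(records):
        male = rec.by_sex("M")
        female = rec.by_sex("F")
        if len(male) < 2 or len(female) < 2:
            raise ValueError(f"{rec.gene_id}: need >= 2 samples per sex")
        fcs[i] = _log2fc(float(male.mean()), float(female.mean()))
        with np.errstate(invalid="ignore", divide="ignore"):
            t_res = stats.ttest_ind(np.log2(male + 1.0), np.log2(female + 1.0),
                                    equal_var=False)
        raw_p[i] = 1.0 if math.isnan(t_res.pvalue) else float(t_res.pvalue)
    padj = multipletests(raw_p, method="fdr_bh")[1]

    calls = []
    for rec, fc, p, q in zip(records, fcs, raw_p, padj):
        if math.isinf(fc):
            klass = MALE_LIMITED if fc > 0 else FEMALE_LIMITED
        elif q < fdr and fc >= 1.0:
            klass = MALE_BIASED
        elif q < fdr and fc <= -1.0:
            klass = FEMALE_BIASED
        else:
            klass = UNBIASED
        calls.append(SexBiasCall(rec.gene_id, rec.species, float(fc),
                                 float(p), float(q), klass))
    return calls


_POOLED = {
    MALE_BIASED: MALE_BIASED, MALE_LIMITED: MALE_BIASED,
    FEMALE_BIASED: FEMALE_BIASED, FEMALE_LIMITED: FEMALE_BIASED,
    UNBIASED: UNBIASED,
}


def conserved_classes(calls_by_species: Mapping[str, Sequence[SexBiasCall]]
                      ) -> dict[str, str]:
    """Genes whose expression class is conserved across every species.

    Sex-limited and sex-biased are pooled per sex.  A gene is assigned a
    class only when all species agree (and every species has a call);
    disagreements leave the gene unassigned.  Restricting to conserved
    classes avoids diluting selection signals with genes whose expression
    has turned over during the clade's history.
    """
    per_gene: dict[str, list[str]] = {}
    n_species = len(calls_by_species)
    for calls in calls_by_species.values():
        for call in calls:
            per_gene.setdefault(call.gene_id, []).append(_POOLED[call.klass])
    out = {}
    for gene, klasses in per_gene.items():
        if len(klasses) == n_species and len(set(klasses)) == 1:
            out[gene] = klasses[0]
    logger.info("conserved classes: %d of %d genes assigned", len(out), len(per_gene))
    return out


def relaxed_classes(calls_by_species: Mapping[str, Sequence[SexBiasCall]]
                    ) -> dict[str, str]:
    """Majority-rule sex-bias classes across species.

    A gene is putatively female-biased when at least half of the species
    call it female-limited or female-biased AND its fold change is
    negative in every species; mirrored for putatively male-biased.  All
    other genes are ``other``.
    """
    per_gene: dict[str, list[SexBiasCall]] = {}
    n_species = len(calls_by_species)
    for calls in calls_by_species.values():
        for call in calls:
            per_gene.setdefault(call.gene_id, []).append(call)
    out = {}
    for gene, calls in per_gene.items():
        if len(calls) != n_species:
            out[gene] = OTHER
            continue
        n_f = sum(c.klass in (FEMALE_BIASED, FEMALE_LIMITED) for c in calls)
        n_m = sum(c.klass in (MALE_BIASED, MALE_LIMITED) for c in calls)
        if n_f >= n_species / 2 and all(c.log2fc < 0 for c in calls):
            out[gene] = PUTATIVE_FEMALE
        elif n_m >= n_species / 2 and all(c.log2fc > 0 for c in calls):
            out[gene] = PUTATIVE_MALE
        else:
            out[gene] = OTHER
    return out


def faster_z_by_class(
    div_records: Sequence,
    class_map: Mapping[str, str],
    plan: ResamplingPlan | None = None,
) -> dict[str, RatioResult]:
    """Faster-Z computed within each expression class.

    Classes missing either Z-linked or autosomal contigs are skipped with
    a log entry.  Between-class differences use two-tailed pairwise
    permutation tests (see ``class_difference_p``): there is no a-priori
    direction for which class should evolve faster.
    """
    from fasterz.tables_io import Category, split_by_category

    by_class: dict[str, list] = {}
    for rec in div_records:
        klass = class_map.get(rec.contig_id)
        if klass is not None:
            by_class.setdefault(klass, []).append(rec)
    results = {}
    for klass, recs in sorted(by_class.items()):
        cats = split_by_category(recs)
        z = cats[Category.Z]
        a = cats[Category.AUTO_1_10]
        if not z or not a:
            logger.info("class %s skipped: %d Z / %d autosomal contigs", klass, len(z), len(a))
            continue
        results[klass] = faster_z(z, a, plan=plan)
    return results


def class_difference_p(
    div_records: Sequence,
    class_map: Mapping[str, str],
    class_a: str,
    class_b: str,
    plan: ResamplingPlan,
) -> float:
    """Two-tailed permutation p for a difference in Faster-Z between two
    expression classes.

    Class labels are permuted over the pooled genes of the two classes,
    with chromosome assignments travelling with their genes; the statistic
    is the difference of within-class Faster-Z ratios.
    """
    from fasterz.tables_io import Category, assign_category

    def class_matrix(klass):
        rows = []
        for rec in div_records:
            if class_map.get(rec.contig_id) != klass:
                continue
            cats = assign_category(rec.chrom)
            is_z = Category.Z in cats
            if not is_z and Category.AUTO_1_10 not in cats:
                continue
            # columns: Z D_N, Z N, Z D_S, Z S, A D_N, A N, A D_S, A S
            z = [rec.D_N, rec.N, rec.D_S, rec.S, 0, 0, 0, 0]
            a = [0, 0, 0, 0, rec.D_N, rec.N, rec.D_S, rec.S]
            rows.append(z if is_z else a)
        return np.array(rows, dtype=float)

    X_a, X_b = class_matrix(class_a), class_matrix(class_b)
    if X_a.size == 0 or X_b.size == 0:
        raise ValueError("both classes must contain contigs")

    def stat(sa, sb):
        def ratio(s):
            return ((s[:, 0] / s[:, 1]) / (s[:, 2] / s[:, 3])) / (
                (s[:, 4] / s[:, 5]) / (s[:, 6] / s[:, 7]))
        return ratio(sa) - ratio(sb)

    two_tailed = ResamplingPlan(n_boot=plan.n_boot, n_perm=plan.n_perm,
                                seed=plan.seed, tail=TWO_TAILED)
    return permutation_p_two_group(X_a, X_b, stat, two_tailed)
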