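import math

import numpy as np
import pytest

from fasterz.expression_bias import (
    FEMALE_BIASED,
    FEMALE_LIMITED,
    MALE_BIASED,
    MALE_LIMITED,
    OTHER,
    PUTATIVE_FEMALE,
    PUTATIVE_MALE,
    UNBIASED,
    ExpressionRecord,
    SexBiasCall,
    classify_sex_bias,
    conserved_classes,
    faster_z_by_class,
    relaxed_classes,
    rpkm_filter,
)
from conftest import div


def record(gene="g1", male=(10, 10, 10, 10, 10), female=(10, 10, 10, 10, 10),
           species="sp1", tissue="gonad"):
    values = tuple(float(v) for v in male) + tuple(float(v) for v in female)
    sexes = ("M",) * len(male) + ("F",) * len(female)
    return ExpressionRecord(gene, species, tissue, values, sexes)


def call(gene, klass, fc=0.0, species="sp1"):
    return SexBiasCall(gene, species, fc, 0.5, 0.5, klass)


class TestRpkmFilter:
    def test_minority_above_threshold_removed(self):
        rec = record(male=(2.5, 2.5, 0.1, 0.1, 0.1), female=(0.1,) * 5)
        assert rpkm_filter([rec]) == []

    def test_half_above_threshold_retained(self):
        rec = record(male=(3, 3, 3, 0, 0), female=(0.1,) * 5)
        assert rpkm_filter([rec]) == [rec]

    def test_exactly_at_threshold_removed(self):
        rec = record(male=(2.0,) * 5, female=(2.0,) * 5)
        assert rpkm_filter([rec]) == []

    def test_either_sex_group_suffices(self):
        rec = record(male=(0.1,) * 5, female=(5, 5, 5, 5, 5))
        assert rpkm_filter([rec]) == [rec]


class TestClassify:
    def test_male_biased(self):
        genes = [record("g0", male=(40, 42, 38, 41, 39), female=(10, 11, 9, 10, 10))]
        genes += [record(f"u{i}", male=(10,) * 5, female=(10,) * 5) for i in range(5)]
        calls = {c.gene_id: c for c in classify_sex_bias(genes)}
        assert calls["g0"].klass == MALE_BIASED
        assert calls["g0"].log2fc == pytest.approx(2.0, abs=0.1)

    def test_equal_means_unbiased(self):
        calls = classify_sex_bias([record("g", male=(10,) * 4, female=(10,) * 4)])
        assert calls[0].klass == UNBIASED
        assert calls[0].log2fc == 0.0

    def test_sex_limited_when_one_sex_silent(self):
        calls = classify_sex_bias([record("g", male=(0,) * 4, female=(12, 13, 11, 12))])
        assert calls[0].klass == FEMALE_LIMITED
        assert calls[0].log2fc == -math.inf

    def test_large_fold_change_without_significance_is_unbiased(self):
        # 2 samples per sex with huge within-sex spread: fc > 1 but p large
        calls = classify_sex_bias([record("g", male=(100, 0.2), female=(1, 30))])
        assert calls[0].klass == UNBIASED

    def test_label_swap_symmetry(self):
        """Swapping sex labels negates log2fc and mirrors the class."""
        male, female = (40, 45, 38, 42, 41), (9, 11, 10, 10, 9)
        fwd = classify_sex_bias([record("g", male=male, female=female)])[0]
        rev = classify_sex_bias([record("g", male=female, female=male)])[0]
        assert fwd.log2fc == pytest.approx(-rev.log2fc)
        assert (fwd.klass, rev.klass) == (MALE_BIASED, FEMALE_BIASED)
        assert fwd.p == pytest.approx(rev.p)

    def test_sample_order_invariance(self):
        values = (40.0, 45.0, 38.0, 9.0, 11.0, 10.0)
        sexes = ("M", "M", "M", "F", "F", "F")
        rec1 = ExpressionRecord("g", "sp", "gonad", values, sexes)
        perm = [3, 0, 4, 1, 5, 2]
        rec2 = ExpressionRecord("g", "sp", "gonad",
                                tuple(values[i] for i in perm),
                                tuple(sexes[i] for i in perm))
        c1, c2 = classify_sex_bias([rec1])[0], classify_sex_bias([rec2])[0]
        assert (c1.log2fc, c1.p, c1.klass) == (c2.log2fc, c2.p, c2.klass)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples per sex"):
            classify_sex_bias([record("g", male=(5,), female=(5, 5))])

    def test_padj_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(0)
        genes = [record(f"g{i}", male=tuple(rng.lognormal(3, 1, 4)),
                        female=tuple(rng.lognormal(3, 1, 4))) for i in range(40)]
        calls = classify_sex_bias(genes)
        assert all(c.padj >= c.p - 1e-12 for c in calls)


class TestCrossSpeciesClasses:
    def test_unanimous_conserved(self):
        by_sp = {f"s{i}": [call("g", MALE_BIASED)] for i in range(6)}
        assert conserved_classes(by_sp) == {"g": MALE_BIASED}

    def test_limited_pooled_with_biased(self):
        by_sp = {f"s{i}": [call("g", MALE_BIASED if i else MALE_LIMITED)]
                 for i in range(6)}
        assert conserved_classes(by_sp) == {"g": MALE_BIASED}

    def test_single_disagreement_unassigns(self):
        by_sp = {f"s{i}": [call("g", MALE_BIASED)] for i in range(5)}
        by_sp["s5"] = [call("g", UNBIASED)]
        assert conserved_classes(by_sp) == {}

    def test_missing_species_unassigns(self):
        by_sp = {f"s{i}": [call("g", UNBIASED)] for i in range(5)}
        by_sp["s5"] = []
        assert conserved_classes(by_sp) == {}

    def test_relaxed_majority_with_consistent_sign(self):
        by_sp = {}
        for i in range(6):
            klass = FEMALE_BIASED if i < 3 else UNBIASED
            by_sp[f"s{i}"] = [call("g", klass, fc=-0.5)]
        assert relaxed_classes(by_sp) == {"g": PUTATIVE_FEMALE}

    def test_relaxed_sign_violation(self):
        by_sp = {}
        for i in range(6):
            fc = 0.2 if i == 5 else -1.5
            klass = FEMALE_BIASED if i < 4 else UNBIASED
            by_sp[f"s{i}"] = [call("g", klass, fc=fc)]
        assert relaxed_classes(by_sp) == {"g": OTHER}

    def test_all_male_limited(self):
        by_sp = {f"s{i}": [call("g", MALE_LIMITED, fc=5.0)] for i in range(6)}
        assert relaxed_classes(by_sp) == {"g": PUTATIVE_MALE}


class TestFasterZByClass:
    def _records(self, seed=0, n_z=30, n_a=120, omega_z=1.2):
        rng = np.random.default_rng(seed)
        recs, class_map = [], {}
        for i in range(n_z + n_a):
            is_z = i < n_z
            name = f"c{i}"
            n_sites, s_sites = 600.0, 200.0
            dn = float(rng.poisson(n_sites * 0.15 * 0.12 * (omega_z if is_z else 1.0)))
            ds = float(rng.poisson(s_sites * 0.15))
            recs.append(div(contig_id=name, chrom="Z" if is_z else "3",
                            D_N=dn, D_S=max(ds, 1.0), N=n_sites, S=s_sites))
            class_map[name] = UNBIASED if i % 2 else MALE_BIASED
        return recs, class_map

    def test_single_class_reduces_to_faster_z(self):
        from fasterz.divergence_rates import faster_z
        from fasterz.tables_io import Category, split_by_category

        recs, _ = self._records()
        class_map = {r.contig_id: MALE_BIASED for r in recs}
        out = faster_z_by_class(recs, class_map)
        cats = split_by_category(recs)
        direct = faster_z(cats[Category.Z], cats[Category.AUTO_1_10])
        assert out == {MALE_BIASED: direct} or out[MALE_BIASED].ratio == direct.ratio

    def test_empty_class_skipped(self):
        recs, class_map = self._records()
        # a class with only autosomal contigs is skipped, not an error
        class_map = {name: (FEMALE_BIASED if not name.startswith("c0") else klass)
                     for name, klass in class_map.items()}
        class_map["c0"] = "z_only_class"
        out = faster_z_by_class(recs, class_map)
        assert "z_only_class" not in out

    def test_injected_class_ordering_recovered(self):
        """Classes given stronger Z-specific omega show larger Faster-Z."""
        rng = np.random.default_rng(3)
        recs, class_map = [], {}
        for klass, boost in ((FEMALE_BIASED, 1.8), (UNBIASED, 1.0)):
            for i in range(400):
                name = f"{klass}_{i}"
                is_z = i < 120
                dn = float(rng.poisson(900 * 0.15 * 0.12 * (boost if is_z else 1.0)))
                ds = float(rng.poisson(300 * 0.15))
                recs.append(div(contig_id=name, chrom="Z" if is_z else "4",
                                D_N=dn, D_S=max(ds, 1.0), N=900.0, S=300.0))
                class_map[name] = klass
        out = faster_z_by_class(recs, class_map)
        assert out[FEMALE_BIASED].ratio > out[UNBIASED].ratio
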