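import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from fasterz.polymorphism_mk import (
    DIRECTION_NONE,
    DIRECTION_POSITIVE,
    DIRECTION_RELAXED,
    MK_MARGINAL_MIN,
    chi2_2x2,
    concatenated_pnps_test,
    filter_snps,
    mk_test,
    mk_tests,
    pnps_faster_z,
    proportion_selected_test,
    qvalues,
)
from fasterz.tables_io import RunConfig, SnpCall
from conftest import div, poly


def snp(maf=0.2, depths=(25, 25, 25, 25, 25), quals=(30,) * 5, **kw):
    return SnpCall(kw.get("contig_id", "c1"), kw.get("pos", 10), "A", "G",
                   maf, tuple(depths), tuple(quals), "synonymous")


class TestFilterSnps:
    def test_maf_threshold_strict(self):
        cfg = RunConfig()
        assert filter_snps([snp(maf=0.10)], cfg) == []
        assert filter_snps([snp(maf=0.15)], cfg) == []  # strictly greater
        assert len(filter_snps([snp(maf=0.20)], cfg)) == 1

    def test_depth_support_rule(self):
        cfg = RunConfig()
        # only 3 samples with depth > 20
        assert filter_snps([snp(depths=(25, 25, 25, 5, 5))], cfg) == []
        assert len(filter_snps([snp(depths=(25, 25, 25, 25, 5))], cfg)) == 1

    def test_quality_counts_with_depth(self):
        cfg = RunConfig()
        # 5 deep samples but only 3 with quality > 20
        assert filter_snps([snp(quals=(30, 30, 30, 15, 15))], cfg) == []


class TestChi2:
    def test_turkey_counts_yates(self):
        res = chi2_2x2(51, 83, 1174, 3276, method="yates")
        assert res.chi2 == pytest.approx(8.47, abs=0.01)
        assert res.p == pytest.approx(0.004, abs=5e-4)

    def test_peafowl_counts_yates(self):
        res = chi2_2x2(38, 63, 610, 1301, method="yates")
        assert res.p == pytest.approx(0.277, abs=5e-4)

    def test_identical_proportions(self):
        res = chi2_2x2(10, 10, 10, 10, method="yates")
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_hand_evaluated_correction(self):
        assert chi2_2x2(10, 20, 30, 40, method="yates").chi2 == pytest.approx(
            0.446, abs=5e-4)

    def test_pearson_matches_scipy(self):
        from scipy.stats import chi2_contingency
        res = chi2_2x2(12, 30, 44, 21, method="pearson")
        ref = chi2_contingency([[12, 30], [44, 21]], correction=False)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_2x2(0, 0, 10, 10)

    @given(a=st.integers(1, 60), b=st.integers(1, 60),
           c=st.integers(1, 60), d=st.integers(1, 60))
    @settings(max_examples=50, deadline=None)
    def test_row_and_column_swap_symmetry(self, a, b, c, d):
        base = chi2_2x2(a, b, c, d, method="yates")
        rows = chi2_2x2(c, d, a, b, method="yates")
        cols = chi2_2x2(b, a, d, c, method="yates")
        assert base.chi2 == pytest.approx(rows.chi2)
        assert base.chi2 == pytest.approx(cols.chi2)
        assert base.p == pytest.approx(rows.p) == pytest.approx(cols.p)

    def test_montecarlo_converges_to_asymptotic(self):
        res_mc = chi2_2x2(60, 90, 110, 70, method="montecarlo", n_mc=20000, seed=1)
        res_pearson = chi2_2x2(60, 90, 110, 70, method="pearson")
        assert res_mc.p == pytest.approx(res_pearson.p, abs=0.01)


def brute_force_mk(D_N, D_S, P_N, P_S):
    """Independent oracle for inclusion and direction."""
    margins = [D_N + D_S, P_N + P_S, D_N + P_N, D_S + P_S]
    if any(m < 6 for m in margins):
        return (False, None)
    if D_S == 0:
        return (True, DIRECTION_NONE)
    if P_S == 0:
        return (True, DIRECTION_RELAXED if P_N > 0 else DIRECTION_NONE)
    lhs, rhs = D_N * P_S, P_N * D_S  # cross-multiplied ratio comparison
    if lhs > rhs:
        return (True, DIRECTION_POSITIVE)
    if lhs < rhs:
        return (True, DIRECTION_RELAXED)
    return (True, DIRECTION_NONE)


class TestMKTest:
    def test_positive_direction_example(self):
        res = mk_test("c", 10, 5, 2, 10)
        assert res.included and res.direction == DIRECTION_POSITIVE

    def test_marginal_filter_excludes(self):
        res = mk_test("c", 3, 2, 1, 1)
        assert not res.included
        assert res.p is None and res.q is None and res.direction is None

    def test_infinite_polymorphism_ratio_is_relaxed(self):
        res = mk_test("c", 0, 10, 10, 0)
        assert res.included and res.direction == DIRECTION_RELAXED

    def test_enumerated_counts_match_oracle(self):
        """Sweep all small 2x2 count tables against the brute-force rules."""
        for counts in itertools.product(range(0, 13, 3), repeat=4):
            expect = brute_force_mk(*counts)
            res = mk_test("c", *counts)
            assert (res.included, res.direction) == expect, counts

    def test_inclusion_invariant_to_contig_order(self):
        divs = [div(contig_id="a", D_N=8, D_S=9), div(contig_id="b", D_N=2, D_S=1)]
        polys = [poly(contig_id="a", P_N=5, P_S=7), poly(contig_id="b", P_N=1, P_S=1)]
        res1 = {r.contig_id: r.included for r in mk_tests(divs, polys)}
        res2 = {r.contig_id: r.included for r in mk_tests(divs[::-1], polys)}
        assert res1 == res2

    def test_qvalues_attached_across_set(self):
        rng = np.random.default_rng(0)
        divs, polys = [], []
        for i in range(40):
            divs.append(div(contig_id=f"c{i}", D_N=float(rng.poisson(8)),
                            D_S=float(rng.poisson(8))))
            polys.append(poly(contig_id=f"c{i}", P_N=int(rng.poisson(8)),
                              P_S=int(rng.poisson(8))))
        results = mk_tests(divs, polys)
        included = [r for r in results if r.included]
        assert included
        assert all(r.q is not None and r.q >= r.p - 1e-12 for r in included)


class TestQvalues:
    def test_hand_step_up(self):
        assert qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert qvalues([0.03]) == pytest.approx([0.03])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_lambda_zero_equals_bh(self, pvals):
        """With lambda = 0 and no zero p-values, pi0 = 1 and q-values are
        exactly Benjamini-Hochberg adjusted p-values."""
        q = qvalues(pvals, lam=0.0)
        bh = multipletests(pvals, method="fdr_bh")[1]
        assert q == pytest.approx(bh)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.2])


class TestConcatenatedTests:
    @pytest.mark.parametrize("pn_z,ps_z,pn_a,ps_a,ratio,p", [
        (51, 83, 1174, 3276, 1.715, 0.004),    # M. gallopavo
        (29, 100, 1339, 3737, 0.809, 0.372),   # N. meleagris
        (126, 351, 2417, 9542, 1.417, 0.001),  # A. platyrhynchos
        (127, 206, 2138, 5657, 1.631, None),   # A. cygnoides, printed p < 0.001
        (38, 63, 610, 1301, 1.286, 0.277),     # P. cristatus
    ])
    def test_species_pnps_contrasts(self, pn_z, ps_z, pn_a, ps_a, ratio, p):
        z = [poly(contig_id="z", chrom="Z", P_N=pn_z, P_S=ps_z)]
        a = [poly(contig_id="a", chrom="1", P_N=pn_a, P_S=ps_a)]
        res = concatenated_pnps_test(z, a)
        assert res.ratio == pytest.approx(ratio, abs=5e-4)
        if p is None:
            assert res.p < 0.001
        else:
            assert res.p == pytest.approx(p, abs=5e-4)

    def test_proportional_table(self):
        z = [poly(contig_id="z", chrom="Z", P_N=10, P_S=20)]
        a = [poly(contig_id="a", chrom="1", P_N=100, P_S=200)]
        res = concatenated_pnps_test(z, a)
        assert res.ratio == pytest.approx(1.0)
        assert res.p == 1.0

    def test_pnps_faster_z_uses_sites(self):
        z = [poly(contig_id="z", chrom="Z", P_N=51, P_S=83, N=1, S=1)]
        a = [poly(contig_id="a", chrom="1", P_N=1174, P_S=3276, N=1, S=1)]
        assert pnps_faster_z(z, a).ratio == pytest.approx(1.715, abs=5e-4)

    def test_all_zero_counts_rejected(self):
        z = [poly(contig_id="z", chrom="Z", P_N=0, P_S=0)]
        a = [poly(contig_id="a", chrom="1", P_N=0, P_S=0)]
        with pytest.raises(ValueError):
            pnps_faster_z(z, a)


class TestProportionSelected:
    def test_no_difference_floored_to_zero(self):
        res = proportion_selected_test(5, 160, 51, 1690)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_clear_difference(self):
        res = proportion_selected_test(10, 20, 0, 20)
        assert res.chi2 == pytest.approx(10.8, abs=0.7)
        assert res.p < 0.05

    def test_zero_margin_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            proportion_selected_test(0, 10, 0, 10)

    def test_k_bounded_by_n(self):
        with pytest.raises(ValueError):
            proportion_selected_test(11, 10, 0, 10)
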