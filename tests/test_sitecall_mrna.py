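"""mRNA IVT-background caller: t-test, binomial test, eight criteria."""

import math

import numpy as np
import pytest
from scipy import stats

from craci.calibration import BackgroundTable
from craci.io_formats import RegionSet
from craci.sitecall_mrna import (
    InsufficientReplicatesError,
    MrnaCallConfig,
    binom_test_greater,
    call_sites_mrna,
    welch_ttest_two_sided,
)
from tests.conftest import count_frame, count_row

REF = {"tx1": "CCCCCGATAGCCCCC"}  # clean GATAG context, central T at 8
POS = 8


class TestWelchTTest:
    def test_identical_degenerate_gives_one(self):
        assert welch_ttest_two_sided([0.3, 0.3], [0.3, 0.3]) == 1.0

    def test_degenerate_different_means_gives_zero(self):
        assert welch_ttest_two_sided([0.3, 0.3], [0.1, 0.1]) == 0.0

    def test_matches_hand_welch_formula(self):
        # independent oracle: Welch t and Satterthwaite df evaluated by hand
        a, b = [0.30, 0.28], [0.03, 0.04]
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = va / 2 + vb / 2
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / 2) ** 2 / 1 + (vb / 2) ** 2 / 1)
        expected = 2 * stats.t.sf(abs(t), df)
        assert welch_ttest_two_sided(a, b) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        a = list(rng.uniform(0.2, 0.4, size=3))
        b = list(rng.uniform(0.0, 0.1, size=4))
        expected = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert welch_ttest_two_sided(a, b) == pytest.approx(expected, rel=1e-10)

    def test_single_value_group_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            welch_ttest_two_sided([0.3], [0.1, 0.2])


class TestBinomTestGreater:
    def test_all_successes_at_half(self):
        assert binom_test_greater(3, 3, 0.5) == pytest.approx(0.125)

    def test_zero_successes_is_full_tail(self):
        assert binom_test_greater(0, 17, 0.3) == 1.0
        assert binom_test_greater(0, 5, 0.0) == 1.0

    def test_matches_direct_summation(self):
        # independent oracle: sum_{i=k..n} C(n,i) p^i (1-p)^(n-i)
        k, n, p0 = 5, 10, 0.07
        expected = sum(math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
                       for i in range(k, n + 1))
        assert binom_test_greater(k, n, p0) == pytest.approx(expected, abs=1e-15)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binom_test_greater(11, 10, 0.1)


def mrna_inputs(cell_ratios=(0.30, 0.28), cell_depth=200,
                ivt_ratios=(0.03, 0.04), ivt_depth=200,
                input2_ratio=0.02, input2_depth=100):
    def frame(cond, ratio, depth, rep):
        n_c = round(ratio * depth)
        return count_frame([count_row(ref_id="tx1", pos=POS, n_C=n_c,
                                      n_T=depth - n_c, condition=cond, replicate=rep)])
    cell = [frame("treated", r, cell_depth, i + 1) for i, r in enumerate(cell_ratios)]
    ivt = [frame("ivt", r, ivt_depth, i + 1) for i, r in enumerate(ivt_ratios)]
    n_c = round(input2_ratio * input2_depth)
    input2 = count_frame([count_row(ref_id="tx1", pos=POS, n_C=n_c,
                                    n_T=input2_depth - n_c, condition="input2")])
    return cell, ivt, input2


@pytest.fixture
def bg():
    return BackgroundTable(rates={"GATAG": 0.05})


class TestCallSitesMrna:
    def test_clean_site_passes_all_eight(self, bg, unit_curves):
        cell, ivt, i2 = mrna_inputs()
        calls = call_sites_mrna(cell, ivt, i2, unit_curves, bg, None, REF)
        assert len(calls) == 1
        c = calls[0]
        assert c.called and all(c.criteria.values())
        assert c.fold_ivt == pytest.approx(0.29 / 0.035)
        assert c.p_ttest < 0.05 and c.p_binom < 0.05
        assert c.d_fraction == pytest.approx((0.29 - 0.05) / 0.9)

    def test_trna_overlap_excluded(self, bg, unit_curves):
        cell, ivt, i2 = mrna_inputs()
        trna = RegionSet([("tx1", 5, 12, "tRNA-x")])
        calls = call_sites_mrna(cell, ivt, i2, unit_curves, bg, trna, REF)
        assert not calls[0].criteria["not_trna"] and not calls[0].called

    def test_high_ivt_ratio_fails_both_ivt_criteria(self, bg, unit_curves):
        cell, ivt, i2 = mrna_inputs(ivt_ratios=(0.22, 0.25))
        calls = call_sites_mrna(cell, ivt, i2, unit_curves, bg, None, REF)
        c = calls[0]
        assert not c.criteria["ivt_ratio"] and not c.criteria["ivt_ttest_fold"]
        assert not c.called

    def test_low_depth_fails(self, bg, unit_curves):
        cell, ivt, i2 = mrna_inputs(cell_depth=12)  # merged depth 24 < 30
        calls = call_sites_mrna(cell, ivt, i2, unit_curves, bg, None, REF)
        assert not calls[0].criteria["depth"] and not calls[0].called

    def test_site_universe_requires_ivt_coverage(self, bg, unit_curves):
        cell, _, i2 = mrna_inputs()
        empty_ivt = [count_frame([]), count_frame([])]
        assert call_sites_mrna(cell, empty_ivt, i2, unit_curves, bg, None, REF) == []

    def test_single_replicate_is_provisional_never_called(self, bg, unit_curves):
        cell, ivt, i2 = mrna_inputs(cell_ratios=(0.30,), ivt_ratios=(0.03,))
        calls = call_sites_mrna(cell, ivt, i2, unit_curves, bg, None, REF)
        c = calls[0]
        assert "provisional_single_replicate" in c.flags
        assert not c.called

    def test_multi_u_context_excluded(self, bg, unit_curves):
        ref = {"tx1": "CCCCCGATTGCCCCC"}  # GATTG: right neighbor U
        bg2 = BackgroundTable(rates={"GATTG": 0.05})
        cell, ivt, i2 = mrna_inputs()
        calls = call_sites_mrna(cell, ivt, i2, unit_curves, bg2, None, ref)
        assert not calls[0].criteria["not_multi_u"]

    def test_bh_is_never_more_permissive_on_binomial(self, bg, unit_curves):
        # same counts, both modes: BH-adjusted p >= raw p, so the BH-called
        # binomial criterion set is a subset of the raw one
        rng = np.random.default_rng(11)
        rows_c1, rows_c2, rows_v1, rows_v2, rows_i2 = [], [], [], [], []
        seq = "C" * 5 + "GATAG" * 40 + "C" * 5
        positions = [i + 1 for i, ch in enumerate(seq) if ch == "T"]
        for pos in positions:
            ratio = rng.uniform(0.0, 0.35)
            for rows, cond, rep in ((rows_c1, "treated", 1), (rows_c2, "treated", 2)):
                n_c = int(rng.binomial(100, ratio))
                rows.append(count_row(ref_id="tx1", pos=pos, n_C=n_c, n_T=100 - n_c,
                                      condition=cond, replicate=rep))
            for rows, cond, rep in ((rows_v1, "ivt", 1), (rows_v2, "ivt", 2)):
                n_c = int(rng.binomial(100, 0.05))
                rows.append(count_row(ref_id="tx1", pos=pos, n_C=n_c, n_T=100 - n_c,
                                      condition=cond, replicate=rep))
            n_c = int(rng.binomial(100, 0.04))
            rows_i2.append(count_row(ref_id="tx1", pos=pos, n_C=n_c, n_T=100 - n_c,
                                     condition="input2"))
        ref = {"tx1": seq}
        bg_many = BackgroundTable(rates={"GATAG": 0.05, "GGATA": 0.05, "ATAGG": 0.05,
                                         "AGGAT": 0.05, "TAGGA": 0.05})
        cell = [count_frame(rows_c1), count_frame(rows_c2)]
        ivt = [count_frame(rows_v1), count_frame(rows_v2)]
        i2 = count_frame(rows_i2)
        raw = call_sites_mrna(cell, ivt, i2, None, bg_many, None, ref,
                              MrnaCallConfig(multiple_testing="none"))
        bh = call_sites_mrna(cell, ivt, i2, None, bg_many, None, ref,
                             MrnaCallConfig(multiple_testing="bh"))
        raw_pass = {c.site for c in raw if c.criteria["binom"]}
        bh_pass = {c.site for c in bh if c.criteria["binom"]}
        assert bh_pass <= raw_pass
        assert {c.site for c in bh if c.called} <= {c.site for c in raw if c.called}


class TestMrnaConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            MrnaCallConfig(max_p_ttest=1.5)
        with pytest.raises(ValueError):
            MrnaCallConfig(fold_over_ivt=0.5)
        with pytest.raises(ValueError):
            MrnaCallConfig(multiple_testing="bonferroni")
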