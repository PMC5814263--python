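import math

import numpy as np
import pytest
from scipy import stats

from clonevo.paired_comparison import (
    burden_summary,
    classify_tp53_status,
    clinical_summary,
    detect_burden_outliers,
    fraction_selected,
    grubbs_test,
    partition_shared_unique,
    validation_summary,
    vaf_stratified_counts,
)
from clonevo.variant_model import PairedCase, SampleCall, load_builtin_cohort
from tests.conftest import make_variant


def paired(diag_pos, rel_pos, pid="p1", **case_kw):
    d = SampleCall(patient_id=pid, timepoint="diagnosis",
                   variants=[make_variant(pos=p) for p in diag_pos])
    r = SampleCall(patient_id=pid, timepoint="relapse",
                   variants=[make_variant(pos=p) for p in rel_pos])
    return PairedCase(patient_id=pid, diagnosis=d, relapse=r, **case_kw)


class TestPartition:
    @pytest.mark.parametrize("dpos,rpos,shared,ud,ur", [
        ((1, 2, 3), (2, 3, 4), 2, 1, 1),
        ((1, 2), (1, 2), 2, 0, 0),
        ((1, 2), (3, 4), 0, 2, 2),
    ])
    def test_set_algebra(self, dpos, rpos, shared, ud, ur):
        part = partition_shared_unique(paired(dpos, rpos))
        assert (len(part.shared), len(part.unique_diagnosis),
                len(part.unique_relapse)) == (shared, ud, ur)
        union = part.shared | part.unique_diagnosis | part.unique_relapse
        assert len(union) == shared + ud + ur  # pairwise disjoint

    def test_swap_symmetry(self, rng):
        dpos = rng.choice(100, size=20, replace=False)
        rpos = rng.choice(100, size=20, replace=False)
        case = paired(dpos, rpos)
        swapped = paired(rpos, dpos)
        a, b = partition_shared_unique(case), partition_shared_unique(swapped)
        assert a.shared == b.shared
        assert a.unique_diagnosis == b.unique_relapse
        assert a.unique_relapse == b.unique_diagnosis


class TestBurden:
    def test_single_patient_totals(self):
        df = burden_summary([paired((1, 2, 3), (2, 3, 4))])
        row = df.iloc[0]
        assert row.total_diagnosis == 3 and row.total_relapse == 3
        assert row.shared == 2
        assert row.total_diagnosis == row.shared + row.unique_diagnosis
        assert row.total_relapse == row.shared + row.unique_relapse

    def test_consequence_restriction(self):
        d = SampleCall(patient_id="p1", timepoint="diagnosis", variants=[
            make_variant(pos=1, consequence="nonsynonymous"),
            make_variant(pos=2, consequence="synonymous"),
        ])
        r = SampleCall(patient_id="p1", timepoint="relapse",
                       variants=[make_variant(pos=1, consequence="nonsynonymous")])
        case = PairedCase(patient_id="p1", diagnosis=d, relapse=r)
        df = burden_summary([case],
                            consequence_subset=("nonsynonymous", "splice_site"))
        assert df.iloc[0].total_diagnosis == 1  # synonymous variant absent

    def test_group_means_match_hand_computation(self, rng):
        cases = []
        expected = []
        for i in range(5):
            dpos = list(range(1, 4 + i))
            rpos = list(range(2 + i, 8))
            cases.append(paired(dpos, rpos, pid=f"p{i}", treatment="treated"))
            expected.append((len(dpos), len(rpos)))
        df = burden_summary(cases)
        means = df.attrs["group_means"].loc["treated"]
        assert means["total_diagnosis"] == pytest.approx(
            np.mean([e[0] for e in expected]))
        assert means["total_relapse"] == pytest.approx(
            np.mean([e[1] for e in expected]))

    def test_excluded_patient_left_out_of_means(self):
        cases = [paired((1,), (1,), pid="a"), paired((1, 2, 3), (1, 2, 3), pid="b")]
        df = burden_summary(cases, excluded_patients=["b"])
        assert df.attrs["group_means"].loc["treated", "total_diagnosis"] == 1


class TestTp53AndVafStrata:
    def _sample(self, **variant_kw):
        return SampleCall(patient_id="p", timepoint="diagnosis",
                          variants=[make_variant(**variant_kw)])

    def test_classification_rules(self):
        mut = self._sample(gene="TP53", consequence="nonsynonymous",
                           damaging_pred=True)
        assert classify_tp53_status(mut) == "mutant"
        syn = self._sample(gene="TP53", consequence="synonymous",
                           damaging_pred=True)
        assert classify_tp53_status(syn) == "wildtype"
        tolerated = self._sample(gene="TP53", consequence="nonsynonymous",
                                 damaging_pred=False)
        assert classify_tp53_status(tolerated) == "wildtype"
        assert classify_tp53_status(tolerated, require_damaging=False) == "mutant"

    def test_vaf_cutoff_boundary(self):
        d = SampleCall(patient_id="p", timepoint="diagnosis", variants=[
            make_variant(pos=1, vaf=0.1), make_variant(pos=2, vaf=0.4),
            make_variant(pos=3, vaf=0.9), make_variant(pos=4, vaf=0.39),
        ])
        r = SampleCall(patient_id="p", timepoint="relapse", variants=[])
        df = vaf_stratified_counts(PairedCase(patient_id="p", diagnosis=d, relapse=r))
        diag = df[df.timepoint == "diagnosis"].iloc[0]
        assert diag.low_vaf == 2 and diag.high_vaf == 2  # 0.4 goes high
        assert diag.low_vaf + diag.high_vaf == 4


def grubbs_oracle(values, alpha=0.05, two_sided=True):
    """Direct textbook formula, independent of the implementation."""
    x = np.asarray(values, float)
    n = len(x)
    g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
    t = stats.t.ppf(1 - (alpha / (2 * n) if two_sided else alpha / n), n - 2)
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    return g, crit


class TestGrubbs:
    def test_obvious_outlier_flagged(self):
        values = [10, 11, 12, 10, 11, 50]
        res = grubbs_test(values)
        g, crit = grubbs_oracle(values)
        assert res.statistic == pytest.approx(g)
        assert res.critical == pytest.approx(crit)
        assert res.outlier_index == 5
        assert res.p_bound < 0.05

    def test_mild_spread_not_flagged(self):
        values = [10, 11, 12, 10, 11, 13]
        res = grubbs_test(values)
        g, crit = grubbs_oracle(values)
        assert res.statistic == pytest.approx(g)
        assert not res.is_outlier
        assert g <= crit

    def test_single_repeated_deviation_is_maximal_g(self):
        # [5,5,5,5,6] attains the maximum possible G = (n-1)/sqrt(n), which
        # exceeds any critical value, so the test flags it at alpha 0.05
        values = [5, 5, 5, 5, 6]
        res = grubbs_test(values)
        assert res.statistic == pytest.approx(4 / math.sqrt(5))
        g, crit = grubbs_oracle(values)
        assert res.is_outlier == (g > crit) == True  # noqa: E712

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            grubbs_test([3, 3, 3, 3])
        with pytest.raises(ValueError):
            grubbs_test([1, 2])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.normal(0, 1, n)
            if x.std(ddof=1) == 0:
                continue
            res = grubbs_test(x)
            g, crit = grubbs_oracle(x)
            assert res.statistic == pytest.approx(g, rel=1e-12)
            assert res.critical == pytest.approx(crit, rel=1e-12)
            assert res.is_outlier == (g > crit)

    def test_burden_outlier_screen(self):
        cases = [paired(tuple(range(3)), tuple(range(10 + i)), pid=f"p{i}")
                 for i in range(6)]
        cases.append(paired((1,), tuple(range(200)), pid="hyper"))
        assert detect_burden_outliers(cases) == ["hyper"]


class TestValidationArithmetic:
    def test_pooled_validation_rate(self):
        assays = [("SNV", True)] * 34 + [("SNV", False)] * 2 \
            + [("INDEL", True)] * 5 + [("INDEL", False)] * 5
        out = validation_summary(assays)
        assert out["pooled"]["percent_whole"] == 85
        assert out["classes"]["SNV"]["percent_whole"] == 94
        assert out["classes"]["INDEL"]["percent_whole"] == 50

    def test_fraction_selected(self):
        out = fraction_selected(138, 5357)
        assert out["percent_1dp"] == 2.6

    def test_zero_validated(self):
        out = validation_summary([("SNV", False)] * 10)
        assert out["pooled"]["percent_whole"] == 0

    def test_empty_or_zero_total_errors(self):
        with pytest.raises(ValueError):
            validation_summary([])
        with pytest.raises(ValueError):
            fraction_selected(1, 0)


class TestClinicalSummary:
    def test_builtin_cohort_groups_and_medians(self):
        out = clinical_summary(load_builtin_cohort())
        assert out["treated"]["n"] == 18
        assert out["untreated"]["n"] == 3
        assert out["treated"]["median_time_to_recurrence_months"] == 9

    def test_empty_group_yields_missing(self):
        case = paired((1,), (1,), treatment="treated")
        out = clinical_summary([case])
        assert out["untreated"]["n"] == 0
        assert out["untreated"]["median_time_to_recurrence_months"] is None

    def test_even_group_midpoint_median(self):
        cases = [paired((1,), (1,), pid=f"p{i}", treatment="treated",
                        time_to_recurrence_months=t)
                 for i, t in enumerate([4, 8, 10, 20])]
        out = clinical_summary(cases)
        assert out["treated"]["median_time_to_recurrence_months"] == 9
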