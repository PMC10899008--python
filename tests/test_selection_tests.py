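import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from regmk.selection_tests import (
    GeneMKResult,
    MKTable,
    OmitReason,
    SelectionClass,
    SiteCall,
    bootstrap_mk,
    classify_coding_sites,
    classify_gene,
    mk_chi_square,
    neutrality_index,
    ni_haldane,
)


class TestNeutralityIndex:
    @pytest.mark.parametrize(
        "counts, ni, alpha",
        [
            ((739, 555, 18, 46), 0.294, 0.706),       # Y/S1/testis noncoding table
            ((89_313, 52_716, 243, 923), 0.155, 0.845),  # Y/S1/liver
            ((10, 10, 10, 10), 1.0, 0.0),              # neutral identity
        ],
    )
    def test_worked_examples(self, counts, ni, alpha):
        got_ni, got_alpha = neutrality_index(*counts)
        assert got_ni == pytest.approx(ni, abs=5e-4)
        assert got_alpha == pytest.approx(alpha, abs=5e-4)

    def test_alpha_plus_ni_is_one_identically(self, rng):
        for _ in range(200):
            counts = rng.integers(1, 10_000, size=4)
            ni, alpha = neutrality_index(*counts)
            assert alpha + ni == 1.0

    def test_zero_denominator_undefined(self):
        with pytest.raises(ZeroDivisionError, match="ni_haldane"):
            neutrality_index(0, 10, 5, 5)
        with pytest.raises(ZeroDivisionError):
            neutrality_index(10, 10, 5, 0)
        # zero focal polymorphism is fine (NI = 0)
        assert neutrality_index(10, 10, 0, 5)[0] == 0.0


class TestChiSquare:
    def test_uncorrected_matches_printed_value(self):
        stat, p = mk_chi_square(739, 555, 18, 46, "none")
        assert stat == pytest.approx(20.77, abs=0.05)
        assert p < 0.001

    def test_yates_matches_printed_value(self):
        stat, _ = mk_chi_square(89_313, 52_716, 243, 923, "yates")
        assert stat == pytest.approx(870.81, abs=0.05)

    def test_proportional_rows_give_zero(self):
        stat, p = mk_chi_square(20, 40, 10, 20)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_flagged(self):
        with pytest.raises(ValueError, match="marginal"):
            mk_chi_square(0, 0, 5, 5)

    def test_agrees_with_independent_contingency_implementation(self, rng):
        # dual route: scipy's chi2_contingency on 200 random tables
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(1, 500, size=4))
            table = [[a, b], [c, d]]
            for correction in ("none", "yates"):
                stat, p = mk_chi_square(a, b, c, d, correction)
                ref = chi2_contingency(table, correction=(correction == "yates"))
                assert stat == pytest.approx(ref.statistic, rel=1e-10, abs=1e-10)
                assert p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-12)

    def test_mk_table_carries_both_variants(self):
        table = MKTable(739, 555, 18, 46, label="t")
        assert table.ni == pytest.approx(0.294, abs=5e-4)
        assert table.alpha == pytest.approx(1 - table.ni)
        assert table.chi2 == pytest.approx(20.77, abs=0.05)
        assert table.chi2_yates < table.chi2


class TestNIHaldane:
    def test_all_zero_table_is_zero(self):
        assert ni_haldane(0, 0, 0, 0) == 0.0

    def test_direct_evaluation(self):
        # whole-Y coding counts
        expect = np.log((59.5 / 34.5) / (16_892.5 / 23_964.5))
        assert ni_haldane(16_892, 23_964, 59, 34) == pytest.approx(expect, abs=1e-12)
        assert ni_haldane(16_892, 23_964, 59, 34) == pytest.approx(0.895, abs=5e-4)

    def test_balanced_odds_give_zero(self):
        assert ni_haldane(3, 7, 3, 7) == pytest.approx(0.0, abs=1e-12)

    @given(
        dn=st.integers(0, 10_000), ds=st.integers(0, 10_000),
        pn=st.integers(0, 10_000), ps=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetric_under_pd_swap(self, dn, ds, pn, ps):
        assert ni_haldane(dn, ds, pn, ps) == pytest.approx(
            -ni_haldane(pn, ps, dn, ds), abs=1e-12
        )

    def test_finite_for_any_zero_pattern(self):
        for counts in [(0, 5, 5, 5), (5, 0, 5, 5), (5, 5, 0, 5), (5, 5, 5, 0)]:
            assert np.isfinite(ni_haldane(*counts))


class TestClassification:
    @pytest.mark.parametrize(
        "value, expect",
        [
            (0.3, SelectionClass.PURIFYING),
            (-0.3, SelectionClass.POSITIVE),
            (0.0, SelectionClass.RELAXED),
            (0.25, SelectionClass.RELAXED),   # boundary -> relaxed
            (-0.25, SelectionClass.RELAXED),
        ],
    )
    def test_thresholds(self, value, expect):
        assert classify_gene(value) is expect

    def test_gene_result_derives_class(self):
        res = GeneMKResult("g1", dn=16_892, ds=23_964, pn=59, ps=34)
        assert res.selection_class is SelectionClass.PURIFYING

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_gene(float("nan"))


class TestCodingSites:
    def test_synonymous_third_position(self):
        res = classify_coding_sites("GAC", "GAT")  # Asp -> Asp
        assert (res.dn, res.ds) == (0, 1)
        assert res.calls[0].call is SiteCall.SYNONYMOUS

    def test_nonsynonymous_first_position(self):
        res = classify_coding_sites("CAT", "GAT")  # Asp -> His
        assert (res.dn, res.ds) == (1, 0)

    def test_gapped_codon_fully_omitted(self):
        res = classify_coding_sites("GA-AAA", "GATAAA")
        reasons = [c.reason_omitted for c in res.calls if c.codon_index == 0]
        assert reasons == [OmitReason.CODON_GAP] * 3
        assert (res.dn, res.ds, res.pn, res.ps) == (0, 0, 0, 0)

    def test_n_site_omitted(self):
        res = classify_coding_sites("GAN", "GAT")
        assert res.calls[0].reason_omitted is OmitReason.N_BASE

    def test_missing_genotype_omitted(self):
        res = classify_coding_sites("GAC", "GAT", {2: ["C", None]})
        assert res.calls[0].reason_omitted is OmitReason.MISSING_GENOTYPE

    def test_triallelic_site_omitted(self):
        res = classify_coding_sites("GAC", "GAT", {2: ["C", "T", "G"]})
        assert res.calls[0].reason_omitted is OmitReason.NOT_BIALLELIC

    def test_segregating_site_counts_as_polymorphism(self):
        # T/C segregating at third position of GAT: both code Asp -> PS
        res = classify_coding_sites("GAT", "GAT", {2: ["T", "C"]})
        assert (res.pn, res.ps) == (0, 1)
        # segregating nonsynonymous at first position
        res = classify_coding_sites("GAT", "GAT", {0: ["G", "C"]})
        assert (res.pn, res.ps) == (1, 0)

    def test_premature_stop_flags_gene_and_omits_codon(self):
        res = classify_coding_sites("TAAGAC", "TAAGAT")
        assert res.premature_stop
        assert all(
            c.reason_omitted is OmitReason.PREMATURE_STOP
            for c in res.calls
            if c.codon_index == 0
        )
        assert res.ds == 1  # second codon still classified

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_coding_sites("GATA", "GATA")


class TestBootstrap:
    def _records(self, rng, n=30):
        return pd.DataFrame(
            {
                "factor": ["focal"] * n + ["neutral"] * n,
                "D": np.concatenate([rng.poisson(25, n), rng.poisson(18, n)]),
                "P": np.concatenate([rng.poisson(1, n), rng.poisson(2, n)]),
            }
        )

    def test_identical_regions_give_zero_sd(self):
        records = pd.DataFrame(
            {"factor": ["focal"] * 10 + ["neutral"] * 10, "D": [5] * 20, "P": [2] * 20}
        )
        res = bootstrap_mk(records, n_reps=500, seed=0)
        assert res.ni_sd == 0.0

    def test_seeded_runs_identical(self, rng):
        records = self._records(rng)
        a = bootstrap_mk(records, n_reps=1_000, seed=7)
        b = bootstrap_mk(records, n_reps=1_000, seed=7)
        assert (a.ni_sd, a.ni_mean) == (b.ni_sd, b.ni_mean)

    def test_bootstrap_mean_consistent_with_pooled_ni(self, rng):
        # pooled counts matching the Y/S1/testis noncoding row, split
        # across 30 regions per factor: the bootstrap mean NI should sit
        # within 2 bootstrap SDs of the pooled point estimate 0.294
        def split(total, n):
            base = np.full(n, total // n)
            base[: total % n] += 1
            return base

        records = pd.DataFrame(
            {
                "factor": ["focal"] * 30 + ["neutral"] * 30,
                "D": np.concatenate([split(739, 30), split(555, 30)]),
                "P": np.concatenate([split(18, 30), split(46, 30)]),
            }
        )
        res = bootstrap_mk(records, n_reps=5_000, seed=1)
        assert abs(res.ni_mean - 0.294) < 2 * res.ni_sd

    def test_too_few_units_rejected(self):
        records = pd.DataFrame({"factor": ["focal", "neutral"], "D": [1, 1], "P": [1, 1]})
        with pytest.raises(ValueError, match="resampling units"):
            bootstrap_mk(records)

    def test_mostly_undefined_replicates_flagged_unstable(self):
        records = pd.DataFrame(
            {"factor": ["focal"] * 4 + ["neutral"] * 4, "D": [1, 0, 0, 0] * 2, "P": [0] * 4 + [1, 0, 0, 0]}
        )
        with pytest.warns(UserWarning, match="unstable"):
            res = bootstrap_mk(records, n_reps=500, seed=2)
        assert res.unstable
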