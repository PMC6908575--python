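import itertools

import numpy as np
import pytest

import _oracles
from imprintscan import (
    AmpliconRef,
    BimodalityThresholds,
    ReadMethProfile,
    allelic_methylation_test,
    assign_allele,
    bisulfite_align,
    classify_bimodality,
    imprinting_call,
    parental_origin,
)
from imprintscan.errors import MendelianInconsistencyError, UsageError


def profile(mean, allele=None, read_id="r"):
    p = ReadMethProfile(read_id, {}, mean, 4, 0, 10)
    p.allele = allele
    return p


class TestBimodality:
    def test_clean_bimodal_mixture(self):
        profiles = [profile(0.95)] * 10 + [profile(0.02)] * 10
        v = classify_bimodality(profiles)
        assert v.verdict == "bimodal" and (v.n_hyper, v.n_hypo) == (10, 10)

    def test_uniform_intermediate_reads_are_not_bimodal(self):
        v = classify_bimodality([profile(0.5)] * 20)
        assert v.verdict == "not_bimodal" and v.n_intermediate == 20

    def test_uniformly_hypermethylated_fails_overall_mean_window(self):
        v = classify_bimodality([profile(0.95)] * 20)
        assert v.verdict == "not_bimodal"

    def test_too_few_reads_undetermined(self):
        assert classify_bimodality([profile(0.9)] * 5).verdict == "undetermined"

    def test_grid_sweep_matches_direct_rule_evaluation(self):
        th = BimodalityThresholds()
        lo, hi = th.overall_mean_window
        for n_hyper, n_hypo in itertools.product(range(0, 21, 2), repeat=2):
            n_int = 20 - n_hyper - n_hypo
            if n_int < 0:
                continue
            profiles = ([profile(0.9)] * n_hyper + [profile(0.1)] * n_hypo
                        + [profile(0.5)] * n_int)
            overall = np.mean([p.mean for p in profiles])
            expected = (
                n_hyper / 20 >= th.min_class_fraction
                and n_hypo / 20 >= th.min_class_fraction
                and n_int / 20 <= th.max_intermediate_fraction
                and lo <= overall <= hi
            )
            got = classify_bimodality(profiles, th).verdict
            assert got == ("bimodal" if expected else "not_bimodal")


class TestAssignAllele:
    REF = AmpliconRef("amp", "ATCGATTAGATCCATCGAA", snp=(8, "G", "A"))

    def _aln(self, read, strand="top"):
        return bisulfite_align(read, self.REF, strand=strand)

    def test_ref_and_alt_assignment(self):
        assert assign_allele(self._aln("ATCGATTAGATTTATCGAA"), self.REF) == "ref"
        assert assign_allele(self._aln("ATCGATTAAATTTATCGAA"), self.REF) == "alt"

    def test_ct_snp_on_top_strand_always_ambiguous(self):
        ref = AmpliconRef("amp", "ATCGATTACATCCATCGAA", snp=(8, "C", "T"))
        for base in "CT":
            read = "ATCGATTA" + base + "ATTTATCGAA"
            assert assign_allele(bisulfite_align(read, ref), ref) == "ambiguous"

    def test_ga_snp_on_bottom_strand_ambiguous(self):
        assert assign_allele(self._aln(self.REF.sequence, "bottom"), self.REF) == "ambiguous"

    def test_c_allele_read_as_t_matches_bisulfite_aware(self):
        ref = AmpliconRef("amp", "ATCGATTACATCCATCGAA", snp=(8, "C", "G"))
        read = "ATCGATTATATTTATCGAA"  # converted C allele reads T
        assert assign_allele(bisulfite_align(read, ref), ref) == "ref"

    def test_uncovered_snp_is_ambiguous(self):
        aln = self._aln("TCGAA")  # aligns to the reference tail
        assert assign_allele(aln, self.REF) == "ambiguous"

    def test_simulated_reads_assign_perfectly_without_noise(self):
        from imprintscan import AmpliconSimConfig, simulate_amplicon_reads

        reads, ref, truth = simulate_amplicon_reads(AmpliconSimConfig(
            seed=5, n_reads=100, conversion_failure_rate=0.0, seq_error_rate=0.0))
        want = dict(zip(truth.per_read.read_id, truth.per_read.allele))
        for read in reads:
            aln = bisulfite_align(read.sequence, ref, read_id=read.id)
            got = assign_allele(aln, ref)
            assert {"ref": "maternal", "alt": "paternal"}[got] == want[read.id]


class TestAllelicTest:
    def test_perfect_segregation(self):
        profiles = [profile(0.95, "ref")] * 10 + [profile(0.02, "alt")] * 10
        r = allelic_methylation_test(profiles)
        assert r.status == "allelic" and r.concordance == 1.0
        assert r.methylated_allele == "ref"

    def test_class_independent_of_allele_is_not_allelic(self):
        profiles = (
            [profile(0.95, "ref")] * 5 + [profile(0.02, "ref")] * 5
            + [profile(0.95, "alt")] * 5 + [profile(0.02, "alt")] * 5
        )
        r = allelic_methylation_test(profiles)
        assert r.status == "not_allelic" and r.concordance == pytest.approx(0.5)

    def test_one_allele_absent_is_undetermined(self):
        r = allelic_methylation_test([profile(0.95, "ref")] * 10)
        assert r.status == "undetermined"

    def test_intermediate_reads_excluded_from_table(self):
        profiles = ([profile(0.95, "ref")] * 6 + [profile(0.02, "alt")] * 6
                    + [profile(0.5, "ref")] * 20)
        r = allelic_methylation_test(profiles)
        assert r.table.sum() == 12 and r.status == "allelic"

    def test_exact_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            table = rng.integers(5, 15, size=(2, 2))
            profiles = (
                [profile(0.95, "ref")] * table[0, 0] + [profile(0.02, "ref")] * table[0, 1]
                + [profile(0.95, "alt")] * table[1, 0] + [profile(0.02, "alt")] * table[1, 1]
            )
            r = allelic_methylation_test(profiles)
            assert r.p == pytest.approx(_oracles.fisher_two_sided(table.tolist()), rel=1e-9)

    def test_label_swap_preserves_verdict_and_p(self):
        profiles = [profile(0.95, "ref")] * 9 + [profile(0.02, "ref")] * 1 \
            + [profile(0.02, "alt")] * 9 + [profile(0.95, "alt")] * 1
        swapped = [profile(p.mean, {"ref": "alt", "alt": "ref"}[p.allele])
                   for p in profiles]
        a, b = allelic_methylation_test(profiles), allelic_methylation_test(swapped)
        assert a.status == b.status and a.p == pytest.approx(b.p)
        assert a.concordance == pytest.approx(b.concordance)
        assert {a.methylated_allele, b.methylated_allele} == {"ref", "alt"}


class TestParentalOrigin:
    def test_opposite_homozygous_parents_are_informative(self):
        assert parental_origin(("A", "G"), ("A", "A"), ("G", "G")) == \
            {"A": "maternal", "G": "paternal"}

    def test_double_heterozygous_parents_are_uninformative(self):
        assert parental_origin(("A", "G"), ("A", "G"), ("A", "G")) is None

    def test_mendelian_inconsistency_raises(self):
        with pytest.raises(MendelianInconsistencyError):
            parental_origin(("A", "G"), ("A", "A"), ("A", "A"))

    def test_all_27_genotype_combinations_match_enumeration_oracle(self):
        genotypes = [("A", "A"), ("A", "G"), ("G", "G")]
        for off, mo, fa in itertools.product(genotypes, repeat=3):
            want = _oracles.parental_origin(off, mo, fa)
            if want == "error":
                with pytest.raises(MendelianInconsistencyError):
                    parental_origin(off, mo, fa)
            else:
                assert parental_origin(off, mo, fa) == want


class TestImprintingCall:
    BIMODAL = classify_bimodality([profile(0.95)] * 10 + [profile(0.02)] * 10)
    NOT_BIMODAL = classify_bimodality([profile(0.5)] * 20)
    UNDET = classify_bimodality([profile(0.9)] * 3)
    ALLELIC = allelic_methylation_test(
        [profile(0.95, "ref")] * 10 + [profile(0.02, "alt")] * 10)

    def test_allelic_with_maternal_origin(self):
        call = imprinting_call(self.BIMODAL, self.ALLELIC,
                               {"A": "maternal", "G": "paternal"}, ("A", "G"))
        assert call.final == "maternal_methylated"

    def test_allelic_with_paternal_origin(self):
        call = imprinting_call(self.BIMODAL, self.ALLELIC,
                               {"A": "paternal", "G": "maternal"}, ("A", "G"))
        assert call.final == "paternal_methylated"

    def test_allelic_without_origin(self):
        assert imprinting_call(self.BIMODAL, self.ALLELIC, None,
                               ("A", "G")).final == "allelic_origin_unknown"

    def test_bimodal_without_snp(self):
        assert imprinting_call(self.BIMODAL, None, None).final == "bimodal_only"

    def test_not_bimodal_is_none(self):
        assert imprinting_call(self.NOT_BIMODAL, None, None).final == "none"

    def test_undetermined_propagates(self):
        assert imprinting_call(self.UNDET, None, None).final == "undetermined"

    def test_removing_information_moves_calls_down_the_lattice(self):
        order = ["undetermined", "none", "bimodal_only", "allelic_origin_unknown",
                 "maternal_methylated"]
        full = imprinting_call(self.BIMODAL, self.ALLELIC,
                               {"A": "maternal", "G": "paternal"}, ("A", "G"))
        no_trio = imprinting_call(self.BIMODAL, self.ALLELIC, None, ("A", "G"))
        no_snp = imprinting_call(self.BIMODAL, None, None)
        ranks = [order.index(c.final) for c in (no_snp, no_trio, full)]
        assert ranks == sorted(ranks)
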