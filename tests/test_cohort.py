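"""Per-patient summaries, recurrence filters, census intersection, HLA frequencies."""

import pytest

from neogc.binding import BindingCall
from neogc.cohort import (
    CohortError,
    hla_carrier_frequencies,
    intersect_census,
    mutation_incidence,
    neoantigen_gene_recurrence,
    recurrent_genes,
    summarize_patients,
)
from neogc.peptides import PeptideCandidate
from neogc.types import HLAGenotype, Patient, SomaticVariant


def missense(pid, gene):
    return SomaticVariant(pid, gene, "missense")


def call(pid, gene, pep, allele="A*02:01", ic50=50.0):
    cand = PeptideCandidate(pep, 0, gene, "A1C")
    return BindingCall(cand, allele, ic50, True, ic50 < 100, patient_id=pid)


class TestSummaries:
    def test_tmb_convention_median_patient(self):
        clin = [Patient("P1", "M", 60, "T2N0M0")]
        variants = [missense("P1", f"G{i}") for i in range(138)]
        (s,) = summarize_patients(variants, [], clin)
        assert s.tmb == pytest.approx(4.6)
        assert not s.is_hypermutator()

    def test_patient_without_variants_gets_zero_row(self):
        clin = [Patient("P1", "M", 60, "T2N0M0")]
        (s,) = summarize_patients([], [], clin)
        assert (s.n_missense, s.n_indel, s.n_neoantigen, s.tmb) == (0, 0, 0, 0.0)
        assert not s.is_hypermutator()

    def test_hypermutator_flag_above_40_per_mb(self):
        clin = [Patient("P1", "F", 45, "T4aN3bM0")]
        variants = [missense("P1", f"G{i}") for i in range(1336)]
        (s,) = summarize_patients(variants, [], clin)
        assert s.tmb == pytest.approx(44.533, abs=1e-3)
        assert s.is_hypermutator()

    def test_distinct_peptide_allele_pairs_counted_once(self):
        clin = [Patient("P1", "M", 60, "T2N0M0")]
        calls = [
            call("P1", "G1", "ACDEFGHIK", "A*02:01"),
            call("P1", "G1", "ACDEFGHIK", "A*02:01", ic50=50.0),  # duplicate pair
            call("P1", "G1", "ACDEFGHIK", "B*15:01"),
        ]
        (s,) = summarize_patients([], calls, clin)
        assert s.n_neoantigen == 2

    def test_orphan_patient_ids_listed(self):
        clin = [Patient("P1", "M", 60, "T2N0M0")]
        with pytest.raises(CohortError, match="P9"):
            summarize_patients([missense("P9", "G1")], [], clin)


class TestRecurrence:
    def test_nine_of_thirty_two_patients(self):
        variants = [missense(f"P{i}", "TP53") for i in range(9)]
        variants += [missense(f"P{i}", "OTHER") for i in range(2)]
        recs = recurrent_genes(variants, min_patients=3, cohort_size=32)
        assert [r.gene for r in recs] == ["TP53"]
        assert recs[0].n_patients == 9
        assert recs[0].fraction == pytest.approx(9 / 32)
        from neogc.cohort import format_percent

        assert format_percent(recs[0].fraction) == "28.13"  # half-up convention
        assert format_percent(15 / 32, 1) == "46.9"

    def test_multiple_hits_in_one_patient_count_once(self):
        variants = [missense("P1", "MUC4"), missense("P1", "MUC4")]
        assert recurrent_genes(variants, min_patients=3) == []
        recs = recurrent_genes(variants, min_patients=1)
        assert recs[0].n_patients == 1 and recs[0].total_mutations == 2

    def test_min_patients_one_partitions_missense_total(self):
        variants = [
            missense(p, g)
            for p, g in [("P1", "A"), ("P1", "B"), ("P2", "A"), ("P3", "C"), ("P3", "A")]
        ]
        recs = recurrent_genes(variants, min_patients=1)
        assert sum(r.total_mutations for r in recs) == len(variants)

    def test_sorted_by_patients_then_symbol(self):
        variants = [missense(f"P{i}", "ZZZ") for i in range(3)]
        variants += [missense(f"P{i}", "AAA") for i in range(3)]
        variants += [missense(f"P{i}", "MMM") for i in range(5)]
        recs = recurrent_genes(variants, min_patients=3)
        assert [r.gene for r in recs] == ["MMM", "AAA", "ZZZ"]


class TestCensus:
    def test_case_insensitive_exact_match(self, tmp_path):
        census = tmp_path / "census.txt"
        census.write_text("Tp53\n")
        recs = recurrent_genes(
            [missense(f"P{i}", g) for g in ("TP53", "MUC4") for i in range(3)],
            min_patients=3,
        )
        kept = intersect_census(recs, census)
        assert [r.gene for r in kept] == ["TP53"]
        assert kept[0].in_census

    def test_empty_recurrence_yields_empty(self, tmp_path):
        census = tmp_path / "census.txt"
        census.write_text("TP53\n")
        assert intersect_census([], census) == []


class TestHLAFrequencies:
    def geno(self, pid, *alleles):
        return HLAGenotype(pid, frozenset(alleles))

    def test_reference_style_fractions(self):
        genos = [self.geno(f"P{i}", "A*11:01", "B*40:01") for i in range(15)]
        genos += [self.geno(f"Q{i}", "C*01:02") for i in range(12)]
        genos += [self.geno(f"R{i}", "B*40:01") for i in range(5)]
        freqs = hla_carrier_frequencies(genos)
        assert freqs["A*11:01"] == pytest.approx(15 / 32)
        assert round(100 * freqs["A*11:01"], 1) == 46.9
        assert freqs["C*01:02"] == pytest.approx(0.375)
        assert list(freqs.values()) == sorted(freqs.values(), reverse=True)

    def test_universal_allele_is_100_percent(self):
        genos = [self.geno(f"P{i}", "A*02:01") for i in range(4)]
        assert hla_carrier_frequencies(genos)["A*02:01"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(CohortError):
            hla_carrier_frequencies([])


class TestIncidence:
    def test_neoantigen_gene_recurrence_threshold(self):
        calls = [call(f"P{i}", "GNAQ", "ACDEFGHIK") for i in range(3)]
        calls += [call(f"P{i}", "RARE", "CCDEFGHIK") for i in range(2)]
        m = neoantigen_gene_recurrence(calls, min_patients=3)
        assert list(m.index) == ["GNAQ"]
        m1 = neoantigen_gene_recurrence(calls, min_patients=2)
        assert set(m1.index) == {"GNAQ", "RARE"}

    def test_matrix_row_sums_recount_calls(self):
        calls = [
            call("P1", "GNAQ", "ACDEFGHIK", "A*02:01"),
            call("P1", "GNAQ", "ACDEFGHIK", "B*15:01"),
            call("P2", "GNAQ", "CCDEFGHIK"),
            call("P3", "GNAQ", "DCDEFGHIK"),
        ]
        m = neoantigen_gene_recurrence(calls, min_patients=3)
        distinct = {(c.patient_id, c.peptide.sequence, c.allele) for c in calls}
        assert int(m.loc["GNAQ"].sum()) == len(distinct)

    def test_mutation_incidence_marginals_match_recurrence(self):
        variants = [
            missense(p, g)
            for p, g in [("P1", "A"), ("P1", "A"), ("P2", "A"), ("P2", "B"), ("P3", "B")]
        ]
        m = mutation_incidence(variants)
        recs = {r.gene: r for r in recurrent_genes(variants, min_patients=1)}
        for gene in m.index:
            assert int(m.loc[gene].sum()) == recs[gene].total_mutations
        assert list(m.columns) == ["P1", "P2", "P3"]
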