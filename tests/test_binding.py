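"""Predictor contract, affinity thresholds, and monotonicity of calling."""

import numpy as np
import pytest

from neogc.binding import (
    AffinityTableError,
    BindingCall,
    EmptyGenotypeError,
    MockPredictor,
    NotCoveredError,
    ScaledPredictor,
    TablePredictor,
    call_neoantigens,
)
from neogc.peptides import PeptideCandidate, enumerate_mutant_peptides
from neogc.types import AffinityRecord, HLAGenotype

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_peptides(n, rng, length=9):
    return ["".join(rng.choice(list(AAS), length)) for _ in range(n)]


def make_candidate(seq, offset=0):
    return PeptideCandidate(seq, offset, "G1", "A1C")


class TestMockPredictor:
    def test_deterministic_per_seed_peptide_allele(self):
        p1, p2 = MockPredictor(3), MockPredictor(3)
        assert p1.score("ACDEFGHIK", "A*02:01") == p2.score("ACDEFGHIK", "A*02:01")
        assert MockPredictor(4).score("ACDEFGHIK", "A*02:01") != p1.score(
            "ACDEFGHIK", "A*02:01"
        )

    def test_alleles_generally_disagree_on_the_same_peptide(self):
        rng = np.random.default_rng(0)
        pred = MockPredictor(1)
        peps = random_peptides(100, rng)
        differ = sum(
            pred.score(p, "A*02:01") != pred.score(p, "B*15:01") for p in peps
        )
        assert differ >= 95

    def test_distribution_spans_both_thresholds(self):
        rng = np.random.default_rng(1)
        pred = MockPredictor(7)
        ic = np.array([pred.score(p, "A*11:01") for p in random_peptides(10000, rng)])
        assert ic.min() >= 1.0 and ic.max() <= 5e4
        assert 0 < (ic < 100).mean() < 1
        assert 0 < (ic > 500).mean() < 1


class TestTablePredictor:
    def test_lookup_and_not_covered(self):
        pred = TablePredictor([AffinityRecord("ACDEFGHIK", "A*02:01", 50.0)])
        assert pred.score("ACDEFGHIK", "A*02:01") == 50.0
        with pytest.raises(NotCoveredError):
            pred.score("ACDEFGHIK", "B*15:01")
        with pytest.raises(NotCoveredError):
            pred.score("CCDEFGHIK", "A*02:01")

    def test_conflicting_duplicates_rejected_identical_allowed(self):
        rows = [
            AffinityRecord("ACDEFGHIK", "A*02:01", 50.0),
            AffinityRecord("ACDEFGHIK", "A*02:01", 60.0),
        ]
        with pytest.raises(AffinityTableError, match="ACDEFGHIK"):
            TablePredictor(rows)
        TablePredictor([rows[0], rows[0]])  # identical duplicate is fine


class TestCallNeoantigens:
    def geno(self, *alleles):
        return HLAGenotype("P1", frozenset(alleles))

    def test_threshold_arithmetic(self):
        peps = ["ACDEFGHIK", "CCDEFGHIK", "DCDEFGHIK"]
        pred = TablePredictor(
            [AffinityRecord(p, "A*02:01", v) for p, v in zip(peps, [50.0, 150.0, 600.0])]
        )
        calls = call_neoantigens(
            [make_candidate(p) for p in peps], self.geno("A*02:01"), pred
        )
        assert len(calls) == 2
        assert sum(c.is_strong for c in calls) == 1
        assert [c.ic50_nm for c in calls] == sorted(c.ic50_nm for c in calls)

    def test_infinite_weak_threshold_returns_every_pair(self):
        rng = np.random.default_rng(2)
        cands = [make_candidate(p) for p in random_peptides(20, rng)]
        calls = call_neoantigens(
            cands, self.geno("A*02:01", "B*15:01"), MockPredictor(0), weak_nm=float("inf")
        )
        assert len(calls) == 40

    def test_empty_genotype_is_an_error(self):
        class Bare:
            patient_id = "P1"
            alleles = frozenset()

        with pytest.raises(EmptyGenotypeError):
            call_neoantigens([make_candidate("ACDEFGHIK")], Bare(), MockPredictor(0))

    def test_matches_brute_force_filter_over_lookup_table(self):
        # one interior mutation -> 38 candidates; genotype of 5 alleles
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(AAS), 40))
        cands = enumerate_mutant_peptides(seq, 20, gene="G1", protein_change="A1C")
        assert len(cands) == 38
        alleles = ["A*02:01", "A*11:01", "B*15:01", "B*40:01", "C*01:02"]
        rows = [
            AffinityRecord(c.sequence, a, float(rng.uniform(1, 2000)))
            for c in cands
            for a in alleles
        ]
        expected = sum(r.ic50_nm <= 500.0 for r in rows)
        calls = call_neoantigens(
            cands, HLAGenotype("P1", frozenset(alleles)), TablePredictor(rows)
        )
        assert len(calls) == expected

    def test_lowering_weak_threshold_never_adds_calls(self):
        rng = np.random.default_rng(4)
        cands = [make_candidate(p) for p in random_peptides(50, rng)]
        geno = self.geno("A*02:01", "B*15:01", "C*01:02")
        pred = MockPredictor(5)
        previous = None
        for weak in (2000.0, 500.0, 100.0, 20.0):
            calls = call_neoantigens(cands, geno, pred, weak_nm=weak)
            strong = {(c.peptide.sequence, c.allele) for c in calls if c.is_strong}
            neo = {(c.peptide.sequence, c.allele) for c in calls}
            assert strong <= neo
            if previous is not None:
                assert neo <= previous
            previous = neo

    def test_burden_nondecreasing_in_missense_count(self):
        # more mutations (superset of candidates) => at least as many calls
        rng = np.random.default_rng(6)
        cands = [make_candidate(p) for p in random_peptides(80, rng)]
        geno = self.geno("A*02:01", "B*15:01")
        pred = MockPredictor(8)
        sizes = [
            len(call_neoantigens(cands[:k], geno, pred)) for k in (10, 30, 50, 80)
        ]
        assert sizes == sorted(sizes)

    def test_strong_implies_neoantigen_enforced(self):
        with pytest.raises(ValueError):
            BindingCall(make_candidate("ACDEFGHIK"), "A*02:01", 50.0, False, True)


class TestScaledPredictor:
    def test_divides_ic50_and_rejects_nonpositive_factor(self):
        base = TablePredictor([AffinityRecord("ACDEFGHIK", "A*02:01", 300.0)])
        assert ScaledPredictor(base, 3.0).score("ACDEFGHIK", "A*02:01") == 100.0
        with pytest.raises(ValueError):
            ScaledPredictor(base, 0.0)
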