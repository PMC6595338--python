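"""Peptide-MHC binding calls through a pluggable predictor contract.

Real affinity prediction is an external neural-network service; this module
abstracts it behind a small contract (``score(peptide, allele) -> IC50 nM``)
with two implementations:

* :class:`TablePredictor` — lookup over a precomputed affinity TSV, for
  users who ran a real predictor; missing pairs are a hard error, never a
  silent default.
* :class:`MockPredictor` — a seeded, deterministic, explicitly
  NON-BIOLOGICAL scorer used for pipeline testing and synthetic cohorts.
  Its IC50s are derived from per-allele anchor-position weights (position 2
  and the C-terminus, the canonical class-I anchors) plus a hash-derived
  peptide-allele perturbation, spanning roughly 1-50,000 nM so that both
  the 500 nM binder and 100 nM strong-binder thresholds are exercised.

A peptide-allele pair is called a neoantigen when IC50 <= ``weak_nm``
(default 500 nM, the conventional binder cutoff) and a strong binder when
IC50 < ``strong_nm`` (default 100 nM).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .peptides import PeptideCandidate
from .types import AffinityRecord, normalize_hla_allele

DEFAULT_WEAK_NM = 500.0
DEFAULT_STRONG_NM = 100.0


class NotCoveredError(KeyError):
    """The predictor has no affinity for a requested peptide-allele pair."""


class AffinityTableError(ValueError):
    """The affinity table is internally inconsistent."""


class EmptyGenotypeError(ValueError):
    """A patient without typed HLA alleles cannot be profiled."""


@runtime_checkable
class PredictorContract(Protocol):
    """Callable surface every binding predictor implements."""

    deterministic: bool

    def score(self, peptide: str, allele: str) -> float:
        """Predicted IC50 in nM for one peptide-allele pair."""
        ...

    def supported_alleles(self) -> frozenset[str] | None:
        """Alleles the predictor covers, or None when unrestricted."""
        ...


def _digest(*parts: object) -> int:
    h = hashlib.blake2b("|".join(str(p) for p in parts).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big")


class MockPredictor:
    """Deterministic stand-in scorer for testing and synthetic cohorts.

    Identical (seed, peptide, allele) always yields an identical IC50; the
    scores carry no biological meaning and are labelled as such in every
    output that records a predictor name.
    """

    name = "mock(non-biological)"
    deterministic = True

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._pwm_cache: dict[str, tuple[dict[str, float], dict[str, float]]] = {}

    def _allele_pwm(self, allele: str) -> tuple[dict[str, float], dict[str, float]]:
        pwm = self._pwm_cache.get(allele)
        if pwm is None:
            rng = np.random.default_rng(_digest("pwm", self.seed, allele) % (2**32))
            aas = "ACDEFGHIKLMNPQRSTVWY"
            anchor2 = dict(zip(aas, rng.normal(0.0, 0.6, size=len(aas))))
            cterm = dict(zip(aas, rng.normal(0.0, 0.6, size=len(aas))))
            pwm = (anchor2, cterm)
            self._pwm_cache[allele] = pwm
        return pwm

    def score(self, peptide: str, allele: str) -> float:
        allele = normalize_hla_allele(allele)
        anchor2, cterm = self._allele_pwm(allele)
        w = anchor2.get(peptide[1], 0.0) + cterm.get(peptide[-1], 0.0)
        u = _digest("pep", self.seed, allele, peptide) / 2**64  # uniform in [0, 1)
        log10_ic50 = 2.35 + 0.9 * w + 3.6 * (u - 0.5)
        return float(min(5e4, max(1.0, 10.0**log10_ic50)))

    def supported_alleles(self) -> frozenset[str] | None:
        return None


class TablePredictor:
    """Lookup-backed predictor over precomputed affinity records."""

    name = "table"
    deterministic = True

    def __init__(self, records: Iterable[AffinityRecord]):
        self._table: dict[tuple[str, str], float] = {}
        conflicts = []
        for rec in records:
            key = (rec.peptide, rec.allele)
            prior = self._table.get(key)
            if prior is not None and not math.isclose(prior, rec.ic50_nm):
                conflicts.append(key)
            self._table[key] = rec.ic50_nm
        if conflicts:
            raise AffinityTableError(
                f"conflicting duplicate affinity rows for pairs: {sorted(set(conflicts))}"
            )

    def score(self, peptide: str, allele: str) -> float:
        try:
            return self._table[(peptide, normalize_hla_allele(allele))]
        except KeyError:
            raise NotCoveredError(
                f"affinity table does not cover peptide {peptide!r} with allele {allele!r}"
            ) from None

    def supported_alleles(self) -> frozenset[str] | None:
        return frozenset(a for _, a in self._table)


class ScaledPredictor:
    """Wrap a predictor, dividing its IC50 by a positive factor.

    Used by the synthetic-cohort harness to impose a per-patient latent
    neoantigen rate (factor > 1 means tighter apparent binding, hence more
    calls) without touching the underlying scorer.
    """

    deterministic = True

    def __init__(self, base: PredictorContract, factor: float):
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        self.base = base
        self.factor = float(factor)
        self.name = f"{getattr(base, 'name', 'predictor')}/x{factor:g}"

    def score(self, peptide: str, allele: str) -> float:
        return self.base.score(peptide, allele) / self.factor

    def supported_alleles(self) -> frozenset[str] | None:
        return self.base.supported_alleles()


def load_affinity_table(records_or_path) -> TablePredictor:
    """Build a lookup predictor from AffinityRecords or an affinity TSV path."""
    from . import io as _io

    if isinstance(records_or_path, (str, bytes)) or hasattr(records_or_path, "__fspath__"):
        records = _io.read_affinity_records(records_or_path)
    else:
        records = records_or_path
    return TablePredictor(records)


@dataclass(frozen=True)
class BindingCall:
    """One peptide-allele pair passing the binder threshold."""

    peptide: PeptideCandidate
    allele: str
    ic50_nm: float
    is_neoantigen: bool
    is_strong: bool
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.is_strong and not self.is_neoantigen:
            raise ValueError("a strong binder must also be a neoantigen call")


def call_neoantigens(
    candidates: Iterable[PeptideCandidate],
    genotype,
    predictor: PredictorContract,
    weak_nm: float = DEFAULT_WEAK_NM,
    strong_nm: float = DEFAULT_STRONG_NM,
) -> list[BindingCall]:
    """Score every candidate against every allele and keep binders.

    One call per (candidate, allele) pair with IC50 <= ``weak_nm``;
    ``is_strong`` where IC50 < ``strong_nm``. Output is sorted by IC50
    ascending (ties broken by peptide then allele, for determinism).
    """
    alleles = sorted(genotype.alleles)
    if not alleles:
        raise EmptyGenotypeError(f"patient {genotype.patient_id!r} has no typed HLA alleles")
    supported = predictor.supported_alleles()
    calls: list[BindingCall] = []
    for cand in candidates:
        for allele in alleles:
            if supported is not None and allele not in supported:
                raise NotCoveredError(
                    f"predictor does not cover allele {allele!r} "
                    f"(patient {genotype.patient_id!r})"
                )
            ic50 = predictor.score(cand.sequence, allele)
            if ic50 <= weak_nm:
                calls.append(
                    BindingCall(
                        peptide=cand,
                        allele=allele,
                        ic50_nm=ic50,
                        is_neoantigen=True,
                        is_strong=ic50 < strong_nm,
                        patient_id=genotype.patient_id,
                    )
                )
    calls.sort(key=lambda c: (c.ic50_nm, c.peptide.sequence, c.allele))
    return calls
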