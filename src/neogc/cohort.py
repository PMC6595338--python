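"""Cohort-level summaries: per-patient counts, TMB, recurrence, HLA frequencies.

Conventions fixed here and used throughout:

* Recurrence counts *patients*, not mutations — a gene hit eight times in
  one patient contributes one carrier.
* Neoantigen burden counts distinct (peptide sequence, allele) pairs per
  patient; the same mutation yields different counts in different patients
  because their HLA genotypes differ.
* Carrier frequency is the fraction of patients carrying at least one copy
  of an allele (set semantics over genotypes).
* Fractions are kept at full precision; rounding to the 28.13% / 46.9%
  style happens only in report formatting.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .binding import BindingCall
from .io import read_census
from .types import DEFAULT_EXOME_MB, Patient, PatientSummary, HLAGenotype, SomaticVariant


class CohortError(ValueError):
    """Cross-table inconsistency at cohort level (e.g. orphan patient ids)."""


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage, rounding half up (9/32 -> '28.13')."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(str(100 * fraction)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneRecurrence:
    """Recurrence of one gene across the cohort (missense carriers)."""

    gene: str
    n_patients: int
    fraction: float
    total_mutations: int
    in_census: bool = False


def _distinct_call_count(calls: Iterable[BindingCall]) -> int:
    return len({(c.peptide.sequence, c.allele) for c in calls})


def summarize_patients(
    variants: Sequence[SomaticVariant],
    calls: Sequence[BindingCall],
    clinical: Sequence[Patient],
    exome_mb: float = DEFAULT_EXOME_MB,
) -> list[PatientSummary]:
    """Per-patient missense/indel/neoantigen counts and TMB.

    Every patient in the clinical table gets a row (zero counts are legal);
    a variant or call whose patient id is absent from the clinical table is
    an error listing the offenders.
    """
    known = {p.patient_id for p in clinical}
    orphans = sorted(
        {v.patient_id for v in variants if v.patient_id not in known}
        | {c.patient_id for c in calls if c.patient_id and c.patient_id not in known}
    )
    if orphans:
        raise CohortError(f"patient ids absent from clinical table: {orphans}")
    mis: dict[str, int] = defaultdict(int)
    ind: dict[str, int] = defaultdict(int)
    for v in variants:
        if v.is_missense:
            mis[v.patient_id] += 1
        else:
            ind[v.patient_id] += 1
    by_patient: dict[str, list[BindingCall]] = defaultdict(list)
    for c in calls:
        by_patient[c.patient_id].append(c)
    return [
        PatientSummary.from_counts(
            p.patient_id,
            mis.get(p.patient_id, 0),
            ind.get(p.patient_id, 0),
            _distinct_call_count(by_patient.get(p.patient_id, [])),
            exome_mb,
        )
        for p in clinical
    ]


def recurrent_genes(
    variants: Sequence[SomaticVariant],
    min_patients: int = 3,
    cohort_size: int | None = None,
) -> list[GeneRecurrence]:
    """Genes with missense mutations in at least ``min_patients`` patients.

    ``cohort_size`` (for the fraction denominator) defaults to the number of
    distinct patients seen in the variant list. Sorted by carrier count
    descending, then gene symbol.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    carriers: dict[str, set[str]] = defaultdict(set)
    totals: dict[str, int] = defaultdict(int)
    patients: set[str] = set()
    for v in variants:
        patients.add(v.patient_id)
        if v.is_missense:
            carriers[v.gene].add(v.patient_id)
            totals[v.gene] += 1
    n = cohort_size if cohort_size is not None else len(patients)
    recs = [
        GeneRecurrence(gene, len(pats), len(pats) / n, totals[gene])
        for gene, pats in carriers.items()
        if len(pats) >= min_patients
    ]
    recs.sort(key=lambda r: (-r.n_patients, r.gene))
    return recs


def intersect_census(
    recurrence: Sequence[GeneRecurrence], census_path
) -> list[GeneRecurrence]:
    """Restrict a recurrence table to cancer-census genes (case-insensitive)."""
    census = read_census(census_path)
    return [replace(r, in_census=True) for r in recurrence if r.gene.upper() in census]


def hla_carrier_frequencies(genotypes: Sequence[HLAGenotype]) -> dict[str, float]:
    """Fraction of patients carrying each allele, sorted descending.

    Ties are broken by allele name so the ordering is deterministic.
    """
    if not genotypes:
        raise CohortError("cannot compute carrier frequencies over an empty cohort")
    carriers: dict[str, int] = defaultdict(int)
    for g in genotypes:
        for allele in g.alleles:
            carriers[allele] += 1
    n = len(genotypes)
    return dict(sorted(((a, c / n) for a, c in carriers.items()), key=lambda kv: (-kv[1], kv[0])))


def mutation_incidence(
    variants: Sequence[SomaticVariant], genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Gene x patient matrix of missense mutation counts."""
    counts: dict[tuple[str, str], int] = defaultdict(int)
    all_patients: set[str] = set()
    for v in variants:
        all_patients.add(v.patient_id)
        if v.is_missense:
            counts[(v.gene, v.patient_id)] += 1
    gene_list = sorted({g for g, _ in counts}) if genes is None else list(genes)
    cols = sorted(all_patients)
    data = [[counts.get((g, p), 0) for p in cols] for g in gene_list]
    return pd.DataFrame(data, index=gene_list, columns=cols)


def neoantigen_gene_recurrence(
    calls: Sequence[BindingCall], min_patients: int = 3
) -> pd.DataFrame:
    """Gene x patient matrix of neoantigen calls for recurrently hit genes.

    Keeps genes whose neoantigen-bearing mutations occur in at least
    ``min_patients`` distinct patients; cells are distinct (peptide, allele)
    call counts per gene per patient.
    """
    pairs: dict[tuple[str, str], set[tuple[str, str]]] = defaultdict(set)
    all_patients: set[str] = set()
    for c in calls:
        if c.patient_id is None:
            raise CohortError("binding call without patient id cannot enter recurrence")
        all_patients.add(c.patient_id)
        pairs[(c.peptide.gene, c.patient_id)].add((c.peptide.sequence, c.allele))
    gene_patients: dict[str, set[str]] = defaultdict(set)
    for gene, patient in pairs:
        gene_patients[gene].add(patient)
    keep = sorted(
        (g for g, pats in gene_patients.items() if len(pats) >= min_patients),
        key=lambda g: (-len(gene_patients[g]), g),
    )
    cols = sorted(all_patients)
    data = [[len(pairs.get((g, p), ())) for p in cols] for g in keep]
    return pd.DataFrame(data, index=keep, columns=cols)


def recurrence_table(recs: Sequence[GeneRecurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n_patients": r.n_patients,
                "fraction": r.fraction,
                "total_mutations": r.total_mutations,
                "in_census": r.in_census,
            }
            for r in recs
        ],
        columns=["gene", "n_patients", "fraction", "total_mutations", "in_census"],
    )
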