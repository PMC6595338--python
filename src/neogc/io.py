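"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are tab-delimited UTF-8 with a header row. FASTA handling is
delegated to Biopython. Readers validate every record through the domain
types and raise :class:`~neogc.types.FormatError` (layout problems, named
column) or :class:`~neogc.types.RecordError` (bad record, with line number).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AffinityRecord,
    FormatError,
    HLAGenotype,
    Patient,
    PatientSummary,
    RecordError,
    SomaticVariant,
    VariantClass,
    parse_hla_alleles,
    parse_protein_change,
)

VARIANT_COLUMNS = [
    "patient_id",
    "gene",
    "variant_class",
    "ref_base",
    "alt_base",
    "protein_change",
]


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _opt(value: str) -> str | None:
    value = value.strip()
    return value or None


def read_variant_table(path: str | os.PathLike) -> list[SomaticVariant]:
    """Read an annotated somatic variant table.

    Required columns: ``patient_id``, ``gene``, ``variant_class``. Optional:
    ``ref_base``/``alt_base`` and either a compact ``protein_change`` column
    ("T96S") or the triple ``ref_aa``/``protein_pos``/``alt_aa``.
    """
    df = _read_tsv(path, ["patient_id", "gene", "variant_class"])
    variants: list[SomaticVariant] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            ref_aa = alt_aa = None
            protein_pos = None
            change = _opt(row["protein_change"]) if "protein_change" in df.columns else None
            if change is not None:
                ref_aa, protein_pos, alt_aa = parse_protein_change(change)
            elif "protein_pos" in df.columns and _opt(row["protein_pos"]) is not None:
                ref_aa = _opt(row.get("ref_aa", ""))
                alt_aa = _opt(row.get("alt_aa", ""))
                protein_pos = int(row["protein_pos"])
            variants.append(
                SomaticVariant(
                    patient_id=row["patient_id"].strip(),
                    gene=row["gene"].strip(),
                    variant_class=VariantClass(row["variant_class"].strip().lower()),
                    ref_base=_opt(row["ref_base"]) if "ref_base" in df.columns else None,
                    alt_base=_opt(row["alt_base"]) if "alt_base" in df.columns else None,
                    protein_pos=protein_pos,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                )
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path} line {line_no}: {exc}") from exc
    return variants


def write_variant_table(variants: Iterable[SomaticVariant], path: str | os.PathLike) -> None:
    rows = [
        {
            "patient_id": v.patient_id,
            "gene": v.gene,
            "variant_class": v.variant_class.value,
            "ref_base": v.ref_base or "",
            "alt_base": v.alt_base or "",
            "protein_change": v.protein_change or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | os.PathLike) -> list[Patient]:
    """Read clinical covariates: ``patient_id``, ``sex``, ``age``, ``tnm``."""
    df = _read_tsv(path, ["patient_id", "sex", "age", "tnm"])
    patients = []
    for idx, row in df.iterrows():
        try:
            patients.append(
                Patient(
                    patient_id=row["patient_id"].strip(),
                    sex=row["sex"].strip().upper(),
                    age=int(row["age"]),
                    tnm=row["tnm"].strip(),
                )
            )
        except (RecordError, ValueError) as exc:
            raise RecordError(f"{path} line {idx + 2}: {exc}") from exc
    ids = [p.patient_id for p in patients]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate patient_id(s) {sorted(dupes)}")
    return patients


def write_clinical_table(patients: Iterable[Patient], path: str | os.PathLike) -> None:
    rows = [
        {"patient_id": p.patient_id, "sex": p.sex, "age": p.age, "tnm": p.tnm}
        for p in patients
    ]
    pd.DataFrame(rows, columns=["patient_id", "sex", "age", "tnm"]).to_csv(
        path, sep="\t", index=False
    )


def read_hla_table(path: str | os.PathLike) -> list[HLAGenotype]:
    """Read HLA class-I genotypes, one row per patient.

    Alleles may sit in a single delimited ``alleles`` column or be spread
    over any number of per-locus columns; all non-``patient_id`` columns are
    parsed and pooled into one normalised set.
    """
    df = _read_tsv(path, ["patient_id"])
    allele_cols = [c for c in df.columns if c != "patient_id"]
    if not allele_cols:
        raise FormatError(f"{path}: no allele columns found")
    genotypes = []
    for idx, row in df.iterrows():
        text = ";".join(v for c in allele_cols if (v := row[c].strip()))
        try:
            genotypes.append(
                HLAGenotype(patient_id=row["patient_id"].strip(), alleles=parse_hla_alleles(text))
            )
        except RecordError as exc:
            raise RecordError(f"{path} line {idx + 2}: {exc}") from exc
    return genotypes


def write_hla_table(genotypes: Iterable[HLAGenotype], path: str | os.PathLike) -> None:
    rows = [
        {"patient_id": g.patient_id, "alleles": ";".join(sorted(g.alleles))} for g in genotypes
    ]
    pd.DataFrame(rows, columns=["patient_id", "alleles"]).to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | os.PathLike) -> list[PatientSummary]:
    df = _read_tsv(path, ["patient_id", "n_missense", "n_indel", "n_neoantigen", "tmb"])
    try:
        return [
            PatientSummary(
                patient_id=row["patient_id"].strip(),
                n_missense=int(row["n_missense"]),
                n_indel=int(row["n_indel"]),
                n_neoantigen=int(row["n_neoantigen"]),
                tmb=float(row["tmb"]),
            )
            for _, row in df.iterrows()
        ]
    except (RecordError, ValueError) as exc:
        raise RecordError(f"{path}: {exc}") from exc


def write_summary_table(summaries: Iterable[PatientSummary], path: str | os.PathLike) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "n_missense": s.n_missense,
            "n_indel": s.n_indel,
            "n_neoantigen": s.n_neoantigen,
            "tmb": f"{s.tmb:.6g}",
        }
        for s in summaries
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "n_missense", "n_indel", "n_neoantigen", "tmb"]
    ).to_csv(path, sep="\t", index=False)


def read_census(path: str | os.PathLike) -> frozenset[str]:
    """Read a cancer gene list, one symbol per line; matching is case-insensitive."""
    with open(path, encoding="utf-8") as fh:
        symbols = {line.strip().upper() for line in fh if line.strip()}
    if not symbols:
        raise FormatError(f"{path}: cancer gene list is empty")
    return frozenset(symbols)


def read_affinity_records(path: str | os.PathLike) -> list[AffinityRecord]:
    df = _read_tsv(path, ["peptide", "allele", "ic50_nm"])
    try:
        return [
            AffinityRecord(
                peptide=row["peptide"].strip(),
                allele=row["allele"].strip(),
                ic50_nm=float(row["ic50_nm"]),
            )
            for _, row in df.iterrows()
        ]
    except (RecordError, ValueError) as exc:
        raise RecordError(f"{path}: {exc}") from exc


def read_protein_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read protein sequences keyed by record id (gene or transcript symbol)."""
    proteins: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        proteins[record.id] = str(record.seq).upper()
    if not proteins:
        raise FormatError(f"{path}: no FASTA records found")
    return proteins


def write_protein_fasta(proteins: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")
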