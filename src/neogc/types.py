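"""Domain types for somatic-variant and neoantigen cohort profiling.

All records are plain frozen dataclasses validated on construction.
Coordinates are 1-based residue indices; protein changes use the compact
``T96S`` notation (reference residue, position, alternate residue); HLA
class-I alleles are stored at two-field ("4-digit") resolution in the
starred form ``A*11:01``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A table or file does not conform to the expected layout."""


class RecordError(ValueError):
    """A single record violates a domain invariant."""


class VariantClass(str, Enum):
    MISSENSE = "missense"
    INDEL = "indel"


_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse compact protein-change notation, e.g. ``"T96S"`` -> ``("T", 96, "S")``."""
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if m is None:
        raise RecordError(f"malformed protein change {text!r}; expected e.g. 'T96S'")
    ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    for aa in (ref_aa, alt_aa):
        if aa not in AMINO_ACIDS:
            raise RecordError(f"protein change {text!r} uses non-canonical residue {aa!r}")
    if pos < 1:
        raise RecordError(f"protein change {text!r} has non-positive position")
    return ref_aa, pos, alt_aa


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated somatic mutation in one patient.

    Nucleotide fields (``ref_base``/``alt_base``) and protein fields
    (``protein_pos``/``ref_aa``/``alt_aa``) are each optional: some sources
    annotate only the protein change, and indels carry neither. Spectrum
    operations skip nucleotide-free records; counting operations do not.
    """

    patient_id: str
    gene: str
    variant_class: VariantClass
    ref_base: str | None = None
    alt_base: str | None = None
    protein_pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_class", VariantClass(self.variant_class))
        if not self.patient_id:
            raise RecordError("variant with empty patient_id")
        if not self.gene:
            raise RecordError("variant with empty gene symbol")
        if (self.ref_base is None) != (self.alt_base is None):
            raise RecordError(f"{self.gene}: ref_base and alt_base must be given together")
        if self.ref_base is not None:
            if self.ref_base not in BASES or self.alt_base not in BASES:
                raise RecordError(
                    f"{self.gene}: bases must be A/C/G/T, got {self.ref_base!r}>{self.alt_base!r}"
                )
            if self.variant_class is VariantClass.MISSENSE and self.ref_base == self.alt_base:
                raise RecordError(f"{self.gene}: missense with identical ref/alt base")
        protein_fields = (self.protein_pos, self.ref_aa, self.alt_aa)
        if any(f is not None for f in protein_fields):
            if any(f is None for f in protein_fields):
                raise RecordError(f"{self.gene}: partial protein annotation {protein_fields}")
            if self.protein_pos < 1:
                raise RecordError(f"{self.gene}: protein_pos must be >= 1")
            for aa in (self.ref_aa, self.alt_aa):
                if aa not in AMINO_ACIDS:
                    raise RecordError(f"{self.gene}: non-canonical residue {aa!r}")
            if self.variant_class is VariantClass.MISSENSE and self.ref_aa == self.alt_aa:
                raise RecordError(f"{self.gene}: missense with identical ref/alt residue")

    @property
    def protein_change(self) -> str | None:
        """Compact notation, e.g. ``"T96S"``, or None when unannotated."""
        if self.protein_pos is None:
            return None
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"

    @property
    def has_nucleotides(self) -> bool:
        return self.ref_base is not None

    @property
    def is_missense(self) -> bool:
        return self.variant_class is VariantClass.MISSENSE


_T_STAGE_RE = re.compile(r"T(\d+[A-Ba-b]?)", re.IGNORECASE)


def parse_t_stage(tnm: str) -> str:
    """Extract the tumour (T) component from a TNM string, case-insensitively.

    Clinical tables are inconsistent in case (``"T4Bn3aM0"`` occurs in the
    wild), so the stage token is normalised to e.g. ``"T4b"``.
    """
    m = _T_STAGE_RE.search(tnm)
    if m is None:
        raise RecordError(f"cannot find T stage in TNM string {tnm!r}")
    return "T" + m.group(1).lower()


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # "F" or "M"
    age: int
    tnm: str
    t_stage: str = field(default="")

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise RecordError(f"{self.patient_id}: sex must be 'F' or 'M', got {self.sex!r}")
        if self.age < 0:
            raise RecordError(f"{self.patient_id}: negative age")
        if not self.t_stage:
            object.__setattr__(self, "t_stage", parse_t_stage(self.tnm))


_HLA_TOKEN_RE = re.compile(r"([ABC])\s*\*?\s*(\d{1,3}):(\d{1,3})")


def normalize_hla_allele(token: str) -> str:
    """Normalise a class-I allele token to two-field starred form.

    Accepts ``"A*11:01"``, ``"A11:01"``, an ``HLA-`` prefix, and unpadded
    fields (``"A*2:1"`` -> ``"A*02:01"``).
    """
    t = token.strip()
    if t.upper().startswith("HLA-"):
        t = t[4:]
    m = _HLA_TOKEN_RE.fullmatch(t)
    if m is None:
        raise RecordError(f"unparseable HLA allele {token!r}")
    locus, group, protein = m.group(1).upper(), int(m.group(2)), int(m.group(3))
    return f"{locus}*{group:02d}:{protein:02d}"


def parse_hla_alleles(text: str) -> frozenset[str]:
    """Parse a string of one or more class-I alleles into a normalised set.

    Handles delimited lists (``;``, ``,``, ``/``, whitespace) as well as
    tables that concatenate alleles with no separator at all
    (``"B58:01C03:02C08:01"``). The whole string must be consumed by allele
    tokens; leftover characters raise, citing the offending text.
    """
    stripped = re.sub(r"HLA-", "", text, flags=re.IGNORECASE)
    leftovers = _HLA_TOKEN_RE.sub("", stripped)
    if re.sub(r"[;,/\s*]+", "", leftovers):
        raise RecordError(f"unparseable HLA allele text {text!r}")
    found = _HLA_TOKEN_RE.findall(stripped)
    if not found:
        raise RecordError(f"no HLA alleles found in {text!r}")
    return frozenset(
        f"{locus.upper()}*{int(group):02d}:{int(protein):02d}" for locus, group, protein in found
    )


@dataclass(frozen=True)
class HLAGenotype:
    """A patient's typed class-I alleles, with set semantics.

    Carrier-frequency analyses count patients, not chromosomes, so
    homozygous loci are stored once and collapsing duplicates is safe.
    """

    patient_id: str
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(self.alleles))
        if not 1 <= len(self.alleles) <= 6:
            raise RecordError(
                f"{self.patient_id}: expected 1-6 class-I alleles, got {len(self.alleles)}"
            )
        for allele in self.alleles:
            if normalize_hla_allele(allele) != allele:
                raise RecordError(f"{self.patient_id}: allele {allele!r} not in normalised form")


#: Megabases of coding sequence interrogated by a standard whole-exome capture;
#: the convention under which a median of 138 missense mutations corresponds
#: to a tumour mutation burden of 4.6 mutations/Mb.
DEFAULT_EXOME_MB = 30.0

#: TMB above which a patient is flagged as a hypermutator (mutations/Mb).
HYPERMUTATOR_TMB = 40.0


@dataclass(frozen=True)
class PatientSummary:
    """Per-patient mutation and neoantigen counts with tumour mutation burden.

    ``tmb`` is missense mutations per megabase of interrogated exome,
    n_missense / exome_mb exactly.
    """

    patient_id: str
    n_missense: int
    n_indel: int
    n_neoantigen: int
    tmb: float

    def __post_init__(self) -> None:
        for name in ("n_missense", "n_indel", "n_neoantigen"):
            if getattr(self, name) < 0:
                raise RecordError(f"{self.patient_id}: negative {name}")
        if self.tmb < 0:
            raise RecordError(f"{self.patient_id}: negative tmb")

    @classmethod
    def from_counts(
        cls,
        patient_id: str,
        n_missense: int,
        n_indel: int,
        n_neoantigen: int,
        exome_mb: float = DEFAULT_EXOME_MB,
    ) -> "PatientSummary":
        return cls(patient_id, n_missense, n_indel, n_neoantigen, n_missense / exome_mb)

    def is_hypermutator(self, threshold: float = HYPERMUTATOR_TMB) -> bool:
        return self.tmb > threshold


@dataclass(frozen=True)
class AffinityRecord:
    """Predicted binding affinity (IC50, nM) of one peptide-allele pair."""

    peptide: str
    allele: str
    ic50_nm: float

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 11:
            raise RecordError(f"peptide {self.peptide!r} length outside 8-11")
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise RecordError(f"peptide {self.peptide!r} has non-canonical residues {sorted(bad)}")
        object.__setattr__(self, "allele", normalize_hla_allele(self.allele))
        if not self.ic50_nm > 0:
            raise RecordError(f"ic50_nm must be positive, got {self.ic50_nm}")
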