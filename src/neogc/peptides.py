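"""Mutant-protein construction and 8-11-mer peptide enumeration.

MHC class-I ligands are short contiguous peptides of 8-11 residues. For a
missense mutation, every window of those lengths that lies fully within the
protein and covers the mutated residue is a candidate neoantigen precursor.
Windows truncated at the protein termini are dropped, not padded: padding
has no biological meaning for contiguous ligands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .types import AMINO_ACIDS, RecordError, SomaticVariant

DEFAULT_LENGTHS = (8, 9, 10, 11)


class ReferenceMismatchError(ValueError):
    """The protein sequence disagrees with the annotated reference residue.

    Guards against transcript or annotation drift between the variant table
    and the protein FASTA.
    """


@dataclass(frozen=True)
class PeptideCandidate:
    """An 8-11-mer mutant peptide window covering the mutated residue."""

    sequence: str
    mutation_offset: int  # 0-based index of the mutated residue in the peptide
    gene: str
    protein_change: str

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_offset < len(self.sequence):
            raise RecordError(
                f"mutation_offset {self.mutation_offset} outside peptide "
                f"{self.sequence!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def apply_missense(protein_seq: str, protein_pos: int, ref_aa: str, alt_aa: str) -> str:
    """Substitute one residue (1-based ``protein_pos``) after checking the reference."""
    if not 1 <= protein_pos <= len(protein_seq):
        raise RecordError(
            f"protein_pos {protein_pos} outside protein of length {len(protein_seq)}"
        )
    observed = protein_seq[protein_pos - 1]
    if observed != ref_aa:
        raise ReferenceMismatchError(
            f"reference mismatch at position {protein_pos}: "
            f"annotation says {ref_aa!r}, protein has {observed!r}"
        )
    if alt_aa not in AMINO_ACIDS:
        raise RecordError(f"non-canonical alternate residue {alt_aa!r}")
    return protein_seq[: protein_pos - 1] + alt_aa + protein_seq[protein_pos:]


def window_count(protein_len: int, protein_pos: int, length: int) -> int:
    """Number of length-``length`` windows inside the protein covering ``protein_pos``.

    Closed form: min(p, N-L+1) - max(1, p-L+1) + 1, clipped at zero.
    """
    lo = max(1, protein_pos - length + 1)
    hi = min(protein_pos, protein_len - length + 1)
    return max(0, hi - lo + 1)


def enumerate_mutant_peptides(
    mutant_seq: str,
    protein_pos: int,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    *,
    gene: str = "",
    protein_change: str = "",
    allow_nonstandard_lengths: bool = False,
) -> list[PeptideCandidate]:
    """Enumerate every mutation-covering window of the requested lengths.

    Ordering is deterministic: ascending length, then ascending start.
    Duplicate peptide sequences arising from repeats are collapsed per
    mutation (first occurrence kept); identical peptides from *distinct*
    mutations are deliberately kept apart by the caller.
    """
    if not 1 <= protein_pos <= len(mutant_seq):
        raise RecordError(
            f"protein_pos {protein_pos} outside protein of length {len(mutant_seq)}"
        )
    if not allow_nonstandard_lengths:
        bad = [L for L in lengths if not 8 <= L <= 11]
        if bad:
            raise RecordError(
                f"peptide lengths {bad} outside the class-I range 8-11 "
                "(pass allow_nonstandard_lengths=True to override)"
            )
    candidates: list[PeptideCandidate] = []
    seen: set[str] = set()
    p = protein_pos - 1  # 0-based
    for length in sorted(lengths):
        first = max(0, p - length + 1)
        last = min(p, len(mutant_seq) - length)
        for start in range(first, last + 1):
            seq = mutant_seq[start : start + length]
            if seq in seen:
                continue
            seen.add(seq)
            candidates.append(
                PeptideCandidate(
                    sequence=seq,
                    mutation_offset=p - start,
                    gene=gene,
                    protein_change=protein_change,
                )
            )
    return candidates


def candidates_for_variant(
    variant: SomaticVariant,
    proteins: Mapping[str, str],
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> list[PeptideCandidate]:
    """Build the candidate set for one missense variant.

    Indels and variants without protein annotation yield no candidates
    (neoantigen prediction here is missense-only).
    """
    if not variant.is_missense or variant.protein_pos is None:
        return []
    if variant.gene not in proteins:
        raise RecordError(f"no protein sequence for gene {variant.gene!r}")
    mutant = apply_missense(
        proteins[variant.gene], variant.protein_pos, variant.ref_aa, variant.alt_aa
    )
    return enumerate_mutant_peptides(
        mutant,
        variant.protein_pos,
        lengths,
        gene=variant.gene,
        protein_change=variant.protein_change,
    )


def candidates_by_patient(
    variants: Iterable[SomaticVariant],
    proteins: Mapping[str, str],
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> dict[str, list[PeptideCandidate]]:
    """Enumerate candidates for every patient's missense variants."""
    out: dict[str, list[PeptideCandidate]] = {}
    for v in variants:
        out.setdefault(v.patient_id, []).extend(candidates_for_variant(v, proteins, lengths))
    return out
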