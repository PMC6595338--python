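"""Six-class substitution spectrum and transition/transversion summary.

Single-base substitutions are collapsed onto the pyrimidine strand, the
standard convention: a change reported from a purine reference (G or A) is
complemented (G>T becomes C>A, A>G becomes T>C, ...), leaving six classes
{C>A, C>G, C>T, T>A, T>C, T>G}. Transitions are C>T and T>C; the other four
classes are transversions. No trinucleotide context is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .types import BASES, SomaticVariant

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITION_CLASSES = frozenset({"C>T", "T>C"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ClassificationError(ValueError):
    """The base pair cannot be classified (identical or non-ACGT bases)."""


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, bool]:
    """Map an ordered base pair onto its pyrimidine-strand class.

    Returns ``(class, is_transition)``. The 12 ordered pairs partition onto
    the 6 classes two-to-one.
    """
    if ref_base not in BASES or alt_base not in BASES:
        raise ClassificationError(f"non-ACGT base in {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ClassificationError(f"identical ref and alt base {ref_base!r}")
    if ref_base in ("G", "A"):  # purine reference: complement both strands
        ref_base, alt_base = _COMPLEMENT[ref_base], _COMPLEMENT[alt_base]
    cls = f"{ref_base}>{alt_base}"
    return cls, cls in TRANSITION_CLASSES


@dataclass(frozen=True)
class SpectrumSummary:
    """Spectrum fractions over classified missense substitutions.

    ``fractions`` is None when no record could be classified (all skipped);
    otherwise the six fractions sum to 1 and
    ``ti_fraction = fractions["C>T"] + fractions["T>C"]``.
    """

    counts: dict[str, int]
    n_classified: int
    n_skipped: int

    @property
    def fractions(self) -> dict[str, float] | None:
        if self.n_classified == 0:
            return None
        return {c: self.counts.get(c, 0) / self.n_classified for c in SIX_CLASSES}

    @property
    def ti_fraction(self) -> float | None:
        f = self.fractions
        if f is None:
            return None
        return f["C>T"] + f["T>C"]

    @property
    def tv_fraction(self) -> float | None:
        ti = self.ti_fraction
        return None if ti is None else 1.0 - ti


def spectrum_summary(variants: Iterable[SomaticVariant]) -> SpectrumSummary:
    """Summarise the substitution spectrum of the missense records.

    Indels and records lacking nucleotide annotation are skipped and
    reported in ``n_skipped`` — the spectrum is a statement about the
    classified subset only.
    """
    counts: Counter[str] = Counter()
    n_skipped = 0
    for v in variants:
        if not v.is_missense or not v.has_nucleotides:
            n_skipped += 1
            continue
        cls, _ = classify_substitution(v.ref_base, v.alt_base)
        counts[cls] += 1
    return SpectrumSummary(dict(counts), sum(counts.values()), n_skipped)


def spectrum_table(summary: SpectrumSummary) -> pd.DataFrame:
    """Class/count/fraction table, one row per class, suitable for TSV export."""
    fr = summary.fractions or {}
    return pd.DataFrame(
        {
            "class": SIX_CLASSES,
            "count": [summary.counts.get(c, 0) for c in SIX_CLASSES],
            "fraction": [fr.get(c, float("nan")) for c in SIX_CLASSES],
        }
    )


def per_patient_spectrum(variants: Iterable[SomaticVariant]) -> pd.DataFrame:
    """Patient x class count matrix for stacked-bar style displays."""
    rows: dict[str, Counter[str]] = {}
    for v in variants:
        if not v.is_missense or not v.has_nucleotides:
            continue
        cls, _ = classify_substitution(v.ref_base, v.alt_base)
        rows.setdefault(v.patient_id, Counter())[cls] += 1
    df = pd.DataFrame(
        [{"patient_id": p, **{c: cnt.get(c, 0) for c in SIX_CLASSES}} for p, cnt in sorted(rows.items())]
    )
    return df.set_index("patient_id") if len(df) else df
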