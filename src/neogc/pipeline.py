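"""End-to-end profiling: variants + HLA + proteins -> calls, summaries, stats.

This is the library core behind both the command-line ``profile`` command
and the analysis scripts. It strings the stages together without hiding
them: peptide enumeration, binding calls, per-patient summaries, spectrum,
recurrence (optionally intersected with a cancer gene census), HLA carrier
frequencies, and the association report.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .binding import BindingCall, PredictorContract, ScaledPredictor, call_neoantigens
from .cohort import (
    GeneRecurrence,
    hla_carrier_frequencies,
    intersect_census,
    neoantigen_gene_recurrence,
    recurrence_table,
    recurrent_genes,
    summarize_patients,
)
from .io import write_summary_table
from .peptides import DEFAULT_LENGTHS, candidates_by_patient
from .spectrum import SpectrumSummary, spectrum_summary, spectrum_table
from .stats import RegressionFit, TestResult, fit_linear, subgroup_report
from .types import DEFAULT_EXOME_MB, HLAGenotype, Patient, PatientSummary, SomaticVariant


@dataclass
class ProfileResult:
    summaries: list[PatientSummary]
    spectrum: SpectrumSummary
    recurrence: list[GeneRecurrence]
    census_recurrence: list[GeneRecurrence] | None
    hla_frequencies: dict[str, float]
    calls: list[BindingCall]
    association: list[TestResult] = field(default_factory=list)
    fit: RegressionFit | None = None
    neo_recurrence: pd.DataFrame | None = None


def run_association(
    summaries: Sequence[PatientSummary],
    clinical: Sequence[Patient],
    *,
    exact: bool = False,
    continuity: bool = False,
) -> tuple[list[TestResult], RegressionFit | None]:
    """Subgroup rank-sum comparisons plus the missense-vs-neoantigen OLS fit.

    The fit is None for cohorts too small to regress (< 3 patients).
    """
    results: list[TestResult] = []
    for grouping in ("age45", "sex", "t_stage"):
        results.extend(
            subgroup_report(summaries, clinical, grouping, exact=exact, continuity=continuity)
        )
    fit = None
    if len(summaries) >= 3:
        fit = fit_linear([s.n_missense for s in summaries], [s.n_neoantigen for s in summaries])
    return results, fit


def run_profile(
    variants: Sequence[SomaticVariant],
    clinical: Sequence[Patient],
    genotypes: Sequence[HLAGenotype],
    proteins: Mapping[str, str],
    predictor: PredictorContract,
    *,
    weak_nm: float = 500.0,
    strong_nm: float = 100.0,
    min_patients: int = 3,
    exome_mb: float = DEFAULT_EXOME_MB,
    census_path=None,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    patient_scale: Mapping[str, float] | None = None,
) -> ProfileResult:
    """Run the full downstream-of-calling pipeline.

    ``patient_scale`` optionally applies a per-patient factor to predicted
    affinities (the synthetic-cohort latent neoantigen rate); absent
    patients default to 1.
    """
    by_patient = candidates_by_patient(variants, proteins, lengths)
    geno_index = {g.patient_id: g for g in genotypes}
    calls: list[BindingCall] = []
    for pid in sorted(by_patient):
        if pid not in geno_index:
            continue
        pred = predictor
        if patient_scale is not None and patient_scale.get(pid, 1.0) != 1.0:
            pred = ScaledPredictor(predictor, patient_scale[pid])
        calls.extend(
            call_neoantigens(by_patient[pid], geno_index[pid], pred, weak_nm, strong_nm)
        )

    summaries = summarize_patients(variants, calls, clinical, exome_mb)
    spectrum = spectrum_summary(variants)
    recurrence = recurrent_genes(variants, min_patients, cohort_size=len(clinical))
    census_rec = intersect_census(recurrence, census_path) if census_path else None
    freqs = hla_carrier_frequencies(genotypes) if genotypes else {}
    association, fit = run_association(summaries, clinical)
    neo_rec = neoantigen_gene_recurrence(calls, min_patients) if calls else None
    return ProfileResult(
        summaries=summaries,
        spectrum=spectrum,
        recurrence=recurrence,
        census_recurrence=census_rec,
        hla_frequencies=freqs,
        calls=calls,
        association=association,
        fit=fit,
        neo_recurrence=neo_rec,
    )


def association_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.label_a,
                "group_b": r.label_b,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "median_a": r.median_a,
                "median_b": r.median_b,
                "u": r.u,
                "z": r.z,
                "p": r.p,
                "alternative": r.alternative,
                "method": r.method,
            }
            for r in results
        ],
        columns=[
            "group_a", "group_b", "n_a", "n_b", "median_a", "median_b",
            "u", "z", "p", "alternative", "method",
        ],
    )


def calls_frame(calls: Sequence[BindingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id or "",
                "gene": c.peptide.gene,
                "protein_change": c.peptide.protein_change,
                "peptide": c.peptide.sequence,
                "mutation_offset": c.peptide.mutation_offset,
                "allele": c.allele,
                "ic50_nm": c.ic50_nm,
                "is_strong": c.is_strong,
            }
            for c in calls
        ],
        columns=[
            "patient_id", "gene", "protein_change", "peptide",
            "mutation_offset", "allele", "ic50_nm", "is_strong",
        ],
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report_bundle(
    result: ProfileResult,
    out_dir: str | os.PathLike,
    *,
    params: Mapping[str, object],
    inputs: Mapping[str, str | os.PathLike] | None = None,
) -> dict:
    """Write every stage's table plus a manifest of parameters and checksums."""
    os.makedirs(out_dir, exist_ok=True)
    out = lambda name: os.path.join(out_dir, name)  # noqa: E731
    write_summary_table(result.summaries, out("patient_summaries.tsv"))
    spectrum_table(result.spectrum).to_csv(out("spectrum.tsv"), sep="\t", index=False)
    recurrence_table(result.recurrence).to_csv(out("recurrent_genes.tsv"), sep="\t", index=False)
    if result.census_recurrence is not None:
        recurrence_table(result.census_recurrence).to_csv(
            out("census_recurrent_genes.tsv"), sep="\t", index=False
        )
    pd.DataFrame(
        [{"allele": a, "carrier_fraction": f} for a, f in result.hla_frequencies.items()]
    ).to_csv(out("hla_frequencies.tsv"), sep="\t", index=False)
    calls_frame(result.calls).to_csv(
        out("neoantigen_calls.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    association_frame(result.association).to_csv(
        out("association.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    if result.neo_recurrence is not None:
        result.neo_recurrence.to_csv(out("neoantigen_gene_matrix.tsv"), sep="\t")
    manifest = {
        "package": {"name": "neogc", "version": __version__},
        "parameters": dict(params),
        "fit": None
        if result.fit is None
        else {
            "slope": result.fit.slope,
            "intercept": result.fit.intercept,
            "r_squared": result.fit.r_squared,
        },
        "inputs": {str(k): _sha256(v) for k, v in (inputs or {}).items()},
        "outputs": {},
    }
    for name in sorted(os.listdir(out_dir)):
        if name.endswith(".tsv"):
            manifest["outputs"][name] = _sha256(out(name))
    with open(out("manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
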