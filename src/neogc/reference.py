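"""The packaged 32-patient gastric-cancer reference cohort.

Two published tables travel with the package as plain TSV data:

* ``gc32_patients.tsv`` — clinical covariates plus per-patient counts of
  missense mutations, indels and predicted neoantigens for all 32 patients.
* ``gc32_driver_mutations.tsv`` — the 25 missense mutations observed in the
  six recurrently mutated driver genes (*PIK3CA*, *FAT4*, *BRCA2*, *GNAQ*,
  *LRP1B*, *PREX2*), with the carriers' HLA alleles, the number of predicted
  neoantigens per mutation, and the number of donors carrying the same
  mutation in the ICGC gastric-cancer datasets (12,198 donors; fixture data,
  not recomputed here).

These tables are the quantitative anchor of the analysis: summary statistics
and association tests on them are exactly reproducible, whereas the raw
variant calls behind them were never deposited.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .types import DEFAULT_EXOME_MB, Patient, PatientSummary, parse_hla_alleles

_PATIENTS_TSV = "gc32_patients.tsv"
_DRIVERS_TSV = "gc32_driver_mutations.tsv"


def _data_path(name: str):
    return resources.files("neogc.data").joinpath(name)


@dataclass(frozen=True)
class DriverMutation:
    """One row of the driver-gene mutation table."""

    gene: str
    protein_change: str
    n_patients: int
    hla_alleles: frozenset[str]
    n_neoantigens: int
    n_icgc: int


class ReferenceCohort(NamedTuple):
    patients: list[Patient]
    summaries: list[PatientSummary]
    driver_mutations: list[DriverMutation]


def load_patient_table() -> pd.DataFrame:
    """The per-patient table as a DataFrame (counts as integers)."""
    with resources.as_file(_data_path(_PATIENTS_TSV)) as path:
        df = pd.read_csv(path, sep="\t")
    return df


def load_driver_table() -> pd.DataFrame:
    with resources.as_file(_data_path(_DRIVERS_TSV)) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_cohort(exome_mb: float = DEFAULT_EXOME_MB) -> ReferenceCohort:
    """Load the packaged reference cohort.

    Returns the 32 clinical records, per-patient summaries (TMB computed at
    the given exome size), and the 25 driver-gene mutation records.
    """
    pdf = load_patient_table()
    patients = [
        Patient(patient_id=r.patient_id, sex=r.sex, age=int(r.age), tnm=r.tnm)
        for r in pdf.itertuples()
    ]
    summaries = [
        PatientSummary.from_counts(
            r.patient_id, int(r.n_missense), int(r.n_indel), int(r.n_neoantigen), exome_mb
        )
        for r in pdf.itertuples()
    ]
    ddf = load_driver_table()
    drivers = [
        DriverMutation(
            gene=r.gene,
            protein_change=r.protein_change,
            n_patients=int(r.n_patients),
            hla_alleles=parse_hla_alleles(r.hla_alleles),
            n_neoantigens=int(r.n_neoantigens),
            n_icgc=int(r.n_icgc),
        )
        for r in ddf.itertuples()
    ]
    return ReferenceCohort(patients, summaries, drivers)


def export_reference_tables(out_dir: str | os.PathLike) -> tuple[str, str]:
    """Materialise both reference tables as TSV files for inspection."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name in (_PATIENTS_TSV, _DRIVERS_TSV):
        dest = os.path.join(out_dir, name)
        with resources.as_file(_data_path(name)) as src:
            shutil.copyfile(src, dest)
        paths.append(dest)
    return tuple(paths)
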