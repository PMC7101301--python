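"""Cohort table container and the packaged 14-patient fixture.

The packaged fixture transcribes the published per-cycle dosimetry and
clinical characteristics of a 14-patient Lu-177-DOTATOC cohort: per
patient the kidney/spleen dose, lesion-category doses with lesion
counts, total tumor dose (TTD), grade, chromogranin A (CgA) before and
after therapy, cycle count, and the cohort-mean administered activity.
Per-patient injected activities and per-lesion volumes were not
published; the fixture stores the cohort mean activity for every
patient and leaves lesion volumes unset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

PATIENT_COLUMNS = [
    "patient", "age_y", "grade", "cga_pre_ug_l", "cga_post_ug_l",
    "cga_interval_months", "cycles", "activity_mbq",
    "kidney_dose_gy", "spleen_dose_gy", "ttd_gy",
]

LESION_COLUMNS = ["patient", "category", "dose_gy", "n_lesions"]


@dataclass
class CohortTable:
    """Per-patient clinical covariates and dose results.

    ``patients``: one row per patient (PATIENT_COLUMNS);
    ``lesions``: one row per (patient, lesion category) dose entry.
    """

    patients: pd.DataFrame
    lesions: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PATIENT_COLUMNS) - set(self.patients.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        missing = set(LESION_COLUMNS) - set(self.lesions.columns)
        if missing:
            raise ValueError(f"lesion table missing columns: {sorted(missing)}")
        if not self.patients["grade"].isin([1, 2, 3]).all():
            raise ValueError("grades must be 1, 2 or 3")
        for col in ("kidney_dose_gy", "spleen_dose_gy", "ttd_gy"):
            if (self.patients[col] < 0).any():
                raise ValueError(f"negative values in {col}")
        if (self.lesions["dose_gy"] < 0).any():
            raise ValueError("negative lesion doses")
        if (self.lesions["n_lesions"] < 1).any():
            raise ValueError("lesion counts must be >= 1")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def total_lesions(self) -> int:
        return int(self.lesions["n_lesions"].sum())

    def patient(self, pid: int) -> pd.Series:
        row = self.patients[self.patients["patient"] == pid]
        if row.empty:
            raise KeyError(f"no patient {pid}")
        return row.iloc[0]


def load_cohort_fixture() -> CohortTable:
    """Load the packaged 14-patient cohort fixture."""
    base = resources.files("voxdose.data")
    with base.joinpath("cohort_table.csv").open() as fh:
        patients = pd.read_csv(fh)
    with base.joinpath("lesion_table.csv").open() as fh:
        lesions = pd.read_csv(fh)
    return CohortTable(patients=patients, lesions=lesions)


def load_cohort(patients_csv: str | Path, lesions_csv: str | Path) -> CohortTable:
    """Load a user cohort in the fixture schema."""
    return CohortTable(patients=pd.read_csv(patients_csv),
                       lesions=pd.read_csv(lesions_csv))
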