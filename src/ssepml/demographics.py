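"""Reference cohort demographics.

The study cohort: ten adult thoracolumbar spine-surgery patients monitored
under sevoflurane anesthesia. The synthetic generator reuses these ages and
sexes so that simulated cohorts carry realistic patient metadata.
"""

from __future__ import annotations

import math
from typing import NamedTuple


class PatientRecord(NamedTuple):
    patient_id: str
    sex: str  # "M" / "F"
    age: int  # years
    procedure: str


REFERENCE_COHORT: tuple[PatientRecord, ...] = (
    PatientRecord("P01", "M", 62, "Lumbar Decompression and Fusion"),
    PatientRecord("P02", "M", 74, "Lumbar Decompression and Fusion"),
    PatientRecord("P03", "M", 60, "Lumbar Decompression and Fusion"),
    PatientRecord("P04", "F", 52, "Lumbar Decompression and Fusion"),
    PatientRecord("P05", "M", 51, "Lumbar Decompression and Fusion"),
    PatientRecord("P06", "M", 50, "Lumbar Decompression and Fusion"),
    PatientRecord("P07", "F", 63, "Lumbar Decompression and Fusion"),
    PatientRecord("P08", "F", 66, "Thoracic Decompression and Fusion"),
    PatientRecord("P09", "M", 49, "Lumbar Decompression and Fusion"),
    PatientRecord("P10", "M", 61, "Lumbar Extradural Tumor Excision and Fusion"),
)


def age_summary(cohort: tuple[PatientRecord, ...] = REFERENCE_COHORT) -> tuple[float, float]:
    """Mean and population standard deviation of cohort ages, in years."""
    ages = [p.age for p in cohort]
    mean = sum(ages) / len(ages)
    var = sum((a - mean) ** 2 for a in ages) / len(ages)
    return mean, math.sqrt(var)
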