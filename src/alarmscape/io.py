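"""CSV interchange for cohorts, alarms, windowed alarms and features.

All interchange is plain CSV with epoch-second timestamps; missing samples
are empty fields. One file per patient stream plus a cohort manifest.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import SyntheticPatient
from .series import VitalSeries

MANIFEST_NAME = "manifest.csv"


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> Path:
    """Write one stream CSV per patient and the cohort manifest; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        p.series.to_frame().to_csv(out / f"{p.patient_id}.csv", index=False)
        rows.append(
            {
                "patient_id": p.patient_id,
                "age_months": p.age_months,
                "sex": p.sex,
                "cie_type": p.cie_type,
                "cie_time": p.cie_time,
            }
        )
    manifest_path = out / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(cohort_dir: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(Path(cohort_dir) / MANIFEST_NAME)
    manifest["patient_id"] = manifest["patient_id"].astype(str)
    return manifest


def read_series(cohort_dir: str | Path, patient_id: str, interval: float = 1.0) -> VitalSeries:
    frame = pd.read_csv(Path(cohort_dir) / f"{patient_id}.csv")
    return VitalSeries.from_frame(frame, interval=interval)


def iter_series(cohort_dir: str | Path, interval: float = 1.0):
    """Yield (manifest row, VitalSeries) per patient, one at a time so a
    large cohort never needs to sit in memory at once."""
    manifest = read_manifest(cohort_dir)
    for _, row in manifest.iterrows():
        yield row, read_series(cohort_dir, row["patient_id"], interval=interval)


def events_from_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Events frame (patient_id, cie_type, event_time) for CIE patients."""
    ev = manifest[manifest["cie_type"] != "none"][
        ["patient_id", "cie_type", "cie_time"]
    ].copy()
    ev = ev.rename(columns={"cie_time": "event_time"})
    ev["event_time"] = ev["event_time"].astype("int64")
    return ev.reset_index(drop=True)


def spans_from_patients(patients: list[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "start": [p.series.start for p in patients],
            "end": [p.series.end for p in patients],
        }
    )
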