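"""NIfTI / CSV serialization helpers.

Volumes are written as NIfTI-1 with a diagonal affine built from the voxel
spacing (the synthetic cohort lives in a common space; no registration).
The AIF travels as a two-column CSV (time_s, concentration), the cohort as
one CSV row per patient.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .perfusion import AifCurve

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "nihss",
    "onset_to_drug_minutes",
    "arm",
    "recanalized",
    "lvo",
    "stroke_type",
    "affected_hemisphere",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(array: np.ndarray, spacing, path) -> None:
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_aif_csv(aif: AifCurve, path) -> None:
    pd.DataFrame({"time_s": aif.times, "concentration": aif.values}).to_csv(
        path, index=False
    )


def load_aif_csv(path) -> AifCurve:
    df = pd.read_csv(path)
    return AifCurve(
        times=df["time_s"].to_numpy(), values=df["concentration"].to_numpy()
    )


def save_cohort_csv(cases, path) -> None:
    rows = []
    for c in cases:
        r = c.record
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "nihss": r.nihss,
                "onset_to_drug_minutes": r.onset_to_drug_minutes,
                "arm": r.arm,
                "recanalized": r.recanalized,
                "lvo": r.large_vessel_occlusion,
                "stroke_type": r.stroke_type,
                "affected_hemisphere": c.affected_hemisphere,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def load_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def predictions_to_frame(predictions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "arm": p.arm,
                "vol_theophylline_ml": p.vol_theophylline_ml,
                "vol_placebo_ml": p.vol_placebo_ml,
                "vol_true_ml": p.vol_true_ml,
                "dice": p.dice,
                "dice_degenerate": p.dice_degenerate,
            }
            for p in predictions
        ]
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
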