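"""Voxel feature tables and stratified under-sampling.

Each patient contributes one row per valid ipsilateral brain voxel with
exactly 12 features: tissue-type probability, anatomical region label,
distance to the ischemic core (mm), ADC, rCBF, rCBV, dMTT, dTmax, and the
four clinical covariates (age, sex, NIHSS, onset-to-drug time).  The label
is the follow-up infarct indicator.  Rows carry (patient_id, voxel_index)
provenance so leave-one-patient-out removal is exact.

Voxels with any invalid feature are dropped (and counted), never imputed.
The training contribution of a patient is all lesion voxels plus an equal
number of non-lesion voxels sampled without replacement from the same
ipsilateral pool (stratified under-sampling); if the pool is smaller, all
of it is taken and the imbalance flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

FEATURE_COLUMNS = [
    "tissue_probability",
    "region",
    "distance_to_core_mm",
    "adc",
    "rcbf",
    "rcbv",
    "dmtt",
    "dtmax",
    "age",
    "sex",
    "nihss",
    "onset_to_drug_min",
]

META_COLUMNS = ["patient_id", "voxel_index", "label"]

__all__ = [
    "FEATURE_COLUMNS",
    "META_COLUMNS",
    "SampleInfo",
    "assemble_features",
    "stratified_undersample",
    "tissue_probability_map",
]


@dataclass(frozen=True)
class SampleInfo:
    """Bookkeeping for one patient's stratified under-sampled contribution."""

    patient_id: str
    n_lesion: int
    n_nonlesion: int
    imbalanced: bool
    seed: int


def tissue_probability_map(brain: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Brain-tissue probability: smoothed binary brain segmentation.

    1 deep inside brain, 0 in CSF/background, graded at interfaces — a
    stand-in for a template tissue-probability map.
    """
    return ndimage.gaussian_filter(brain.astype(float), sigma=sigma)


def assemble_features(case) -> pd.DataFrame:
    """Build the 12-feature voxel table for one processed patient case.

    Requires ``case.maps`` (normalized) and ``case.masks`` to be present.
    Rows are the valid brain voxels of the affected (ipsilateral)
    hemisphere, CSF excluded; the number of voxels dropped for invalid
    features is recorded in ``df.attrs["n_dropped"]``.
    """
    maps, masks = case.maps, case.masks
    missing = [
        name
        for name, obj in [("maps", maps), ("masks", masks)]
        if obj is None
    ]
    if not missing and maps.dtmax is None:
        missing.append("normalized maps (rcbf/rcbv/dmtt/dtmax)")
    if missing:
        raise ValueError(f"cannot assemble features, missing inputs: {missing}")

    ipsi = masks.brain & (
        case.phantom.hemisphere_labels == case.affected_hemisphere
    )
    idx = np.nonzero(ipsi.ravel())[0]

    tissue_prob = tissue_probability_map(masks.brain)
    rec = case.record
    df = pd.DataFrame(
        {
            "patient_id": rec.patient_id,
            "voxel_index": idx,
            "tissue_probability": tissue_prob.ravel()[idx],
            "region": case.phantom.region_atlas.ravel()[idx].astype(float),
            "distance_to_core_mm": masks.distance_to_core.ravel()[idx],
            "adc": maps.adc.values.ravel()[idx],
            "rcbf": maps.rcbf.ravel()[idx],
            "rcbv": maps.rcbv.ravel()[idx],
            "dmtt": maps.dmtt.ravel()[idx],
            "dtmax": maps.dtmax.ravel()[idx],
            "age": float(rec.age),
            "sex": float(rec.sex),
            "nihss": float(rec.nihss),
            "onset_to_drug_min": float(rec.onset_to_drug_minutes),
            "label": case.followup_lesion.ravel()[idx].astype(int),
        }
    )
    finite = np.isfinite(df[FEATURE_COLUMNS].to_numpy()).all(axis=1)
    out = df.loc[finite].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~finite).sum())
    return out


def stratified_undersample(
    table: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, SampleInfo]:
    """All lesion rows plus an equal random non-lesion sample (no replacement).

    Patients with zero lesion voxels contribute an empty frame (flagged via
    ``n_lesion == 0``); if non-lesion rows are exhausted, all are taken and
    ``imbalanced`` is set.
    """
    pid = str(table["patient_id"].iloc[0]) if len(table) else ""
    lesion = table[table["label"] == 1]
    nonlesion = table[table["label"] == 0]
    n_lesion = len(lesion)
    if n_lesion == 0:
        info = SampleInfo(pid, 0, 0, False, seed)
        return table.iloc[0:0].copy(), info

    rng = np.random.default_rng(seed)
    n_take = min(n_lesion, len(nonlesion))
    picked = rng.choice(len(nonlesion), size=n_take, replace=False)
    sampled = pd.concat(
        [lesion, nonlesion.iloc[np.sort(picked)]], ignore_index=True
    )
    info = SampleInfo(
        patient_id=pid,
        n_lesion=n_lesion,
        n_nonlesion=n_take,
        imbalanced=n_take < n_lesion,
        seed=seed,
    )
    return sampled, info
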