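"""Threshold-based lesion segmentation and geometry maps.

Conventions (documented, tested):

*   CSF: ADC strictly above ``csf_threshold`` (default 2000e-6 mm^2/s).
*   Ischemic core: 26-connected volume growing over brain voxels with ADC
    strictly below 550e-6 mm^2/s, from explicit seed voxels or an
    auto-seed at the ADC minimum of the affected hemisphere.
*   Hypoperfusion: normalized Tmax (contralateral-subtracted) strictly
    above 6 s.
*   Tissue-at-risk: exact set difference hypoperfusion minus core.
*   Distance-to-core: exact anisotropic Euclidean distance transform in
    mm; with an empty core every voxel gets the grid-diagonal sentinel
    distance (the feature stays defined for patients without a DWI lesion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .perfusion import AdcMap

__all__ = [
    "LesionMaskSet",
    "segment_brain_csf",
    "segment_core",
    "segment_hypoperfusion",
    "tissue_at_risk",
    "distance_to_core",
    "volume_ml",
    "CSF_THRESHOLD",
    "CORE_ADC_THRESHOLD",
    "TMAX_THRESHOLD_S",
]

CSF_THRESHOLD = 2000e-6  # mm^2/s
CORE_ADC_THRESHOLD = 550e-6  # mm^2/s
TMAX_THRESHOLD_S = 6.0  # s

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionMaskSet:
    brain: np.ndarray
    csf: np.ndarray
    core: np.ndarray
    hypoperfusion: np.ndarray
    tissue_at_risk: np.ndarray
    distance_to_core: np.ndarray  # mm
    followup_lesion: np.ndarray | None = None


def volume_ml(mask: np.ndarray, spacing) -> float:
    """Mask volume: voxel count x voxel volume / 1000 (ml)."""
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def segment_brain_csf(
    adc: AdcMap,
    csf_threshold: float = CSF_THRESHOLD,
    support: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split valid voxels into brain tissue and CSF by ADC thresholding.

    CSF = valid voxels with ADC > threshold; brain = the remaining valid
    voxels, restricted to ``support`` (e.g. the head mask) when given.
    """
    valid = adc.valid.copy()
    if support is not None:
        valid &= support
    if not valid.any():
        raise ValueError("no valid voxels to segment")
    csf = valid & (adc.values > csf_threshold)
    brain = valid & ~csf
    return brain, csf


def segment_core(
    adc: AdcMap,
    brain: np.ndarray,
    seeds: list[tuple[int, int, int]] | None = None,
    adc_threshold: float = CORE_ADC_THRESHOLD,
    affected_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Volume-growing ischemic core below the ADC threshold (strict).

    ``core`` is the union, over seeds, of the 26-connected components of
    {brain voxels with ADC < threshold} containing each seed.  Without
    explicit seeds the global ADC minimum inside ``affected_mask`` (or the
    whole brain) is used; if no voxel is below threshold the core is empty
    (no error: patients without a DWI lesion are legitimate).
    """
    below = brain & adc.valid & (adc.values < adc_threshold)
    if seeds is None:
        search = brain & adc.valid
        if affected_mask is not None:
            search &= affected_mask
        if not search.any():
            return np.zeros_like(brain)
        vals = np.where(search, adc.values, np.inf)
        seed = np.unravel_index(int(np.argmin(vals)), brain.shape)
        if not below[seed]:
            return np.zeros_like(brain)  # nothing below threshold
        seeds = [seed]
    else:
        for s in seeds:
            s = tuple(int(v) for v in s)
            if not brain[s]:
                raise ValueError(f"seed {s} lies outside the brain mask")
            if not below[s]:
                raise ValueError(f"seed {s} is not below the ADC threshold")

    labels, _ = ndimage.label(below, structure=_CONN26)
    wanted = {int(labels[tuple(int(v) for v in s)]) for s in seeds}
    wanted.discard(0)
    return np.isin(labels, sorted(wanted))


def segment_hypoperfusion(
    dtmax: np.ndarray | None,
    brain: np.ndarray,
    tmax_threshold_s: float = TMAX_THRESHOLD_S,
) -> np.ndarray:
    """Brain voxels with normalized Tmax strictly above the threshold."""
    if dtmax is None:
        raise ValueError("normalized Tmax map (dtmax) missing: run normalization first")
    return brain & (np.nan_to_num(dtmax, nan=-np.inf) > tmax_threshold_s)


def tissue_at_risk(hypoperfusion: np.ndarray, core: np.ndarray) -> np.ndarray:
    """Exact set difference: hypoperfused but not core (penumbra)."""
    if hypoperfusion.shape != core.shape:
        raise ValueError("mask geometries differ")
    return hypoperfusion & ~core


def sentinel_distance_mm(shape, spacing) -> float:
    """Grid diagonal in mm: the documented empty-core sentinel distance."""
    return float(np.sqrt(sum((n * s) ** 2 for n, s in zip(shape, spacing))))


def distance_to_core(core: np.ndarray, spacing) -> np.ndarray:
    """Exact Euclidean distance (mm) to the nearest core voxel.

    Anisotropic spacing is respected; core voxels get exactly 0.  For an
    empty core the whole map is set to the grid-diagonal sentinel.
    """
    if not core.any():
        return np.full(core.shape, sentinel_distance_mm(core.shape, spacing))
    return ndimage.distance_transform_edt(~core, sampling=spacing)
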