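"""ADC computation and DSC-perfusion analysis.

ADC comes from the monoexponential two-point DWI model.  The perfusion
parameters come from block-circulant SVD deconvolution of the voxel
concentration-time curves with the arterial input function (AIF):

*   the AIF convolution matrix is made circulant after zero-padding both
    signals to length ``2N`` (wrap-around protection, delay insensitivity);
*   singular values below ``lam * sigma_max`` are zeroed (truncated SVD
    pseudo-inverse, ``lam`` default 0.15);
*   per voxel: CBF = max of the deconvolved residue-scaled function k(t),
    Tmax = its argmax (earliest sample on ties), CBV = area(C)/area(AIF),
    MTT = CBV/CBF (central volume theorem).

Normalisation against the contralateral hemisphere follows clinical
convention: CBF and CBV as ratios to the contralateral brain-tissue mean
(CSF excluded), MTT and Tmax as differences from it.

Invalid voxels (non-positive DWI signal, vanishing CBF) are carried as NaN
plus explicit boolean masks, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AifCurve",
    "PerfusionStudy",
    "AdcMap",
    "ParameterMaps",
    "compute_adc",
    "gamma_variate_aif",
    "BlockCirculantDeconvolver",
    "deconvolve_blockcirculant",
    "compute_perfusion_maps",
    "normalize_maps",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AifCurve:
    """Arterial input function on a uniform time grid (seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("AIF needs matching 1-D times and values")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-10):
            raise ValueError("AIF time grid must be uniform")
        if np.any(v < 0) or not np.isfinite(v).all():
            raise ValueError("AIF values must be finite and non-negative")
        if v.sum() * dts[0] <= 0:
            raise ValueError("AIF area must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def area(self) -> float:
        return float(self.values.sum() * self.dt)


@dataclass(frozen=True)
class PerfusionStudy:
    """4-D concentration-time data (t last axis) plus its AIF."""

    data: np.ndarray
    dt: float
    aif: AifCurve

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError("perfusion data must be 4-D (x, y, z, t)")
        if abs(self.aif.dt - self.dt) > 1e-9:
            raise ValueError("study and AIF must share the sampling interval dt")
        if self.aif.values.size != self.data.shape[-1]:
            raise ValueError("AIF length must match the number of timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class AdcMap:
    """ADC in mm^2/s with an explicit validity mask (NaN where invalid)."""

    values: np.ndarray
    valid: np.ndarray


@dataclass
class ParameterMaps:
    """Per-patient parameter maps; normalized variants filled later.

    cbf/cbv are in arbitrary (deconvolution) units, mtt/tmax in seconds.
    ``mtt_valid`` flags voxels where CBF was large enough for the central
    volume ratio; elsewhere mtt is NaN.
    """

    adc: AdcMap
    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    tmax: np.ndarray
    mtt_valid: np.ndarray
    rcbf: np.ndarray | None = None
    rcbv: np.ndarray | None = None
    dmtt: np.ndarray | None = None
    dtmax: np.ndarray | None = None


# --------------------------------------------------------------------------
# ADC
# --------------------------------------------------------------------------


def compute_adc(
    b0_volume: np.ndarray,
    b1000_volume: np.ndarray,
    b_low: float = 0.0,
    b_high: float = 1000.0,
) -> AdcMap:
    """Two-point apparent diffusion coefficient map.

    adc = ln(S_low / S_high) / (b_high - b_low)   [mm^2/s]

    Voxels where either signal is non-positive (or non-finite) are flagged
    invalid and set to NaN rather than silently zeroed.
    """
    s_low = np.asarray(b0_volume, dtype=float)
    s_high = np.asarray(b1000_volume, dtype=float)
    if s_low.shape != s_high.shape:
        raise ValueError(
            f"DWI volumes differ in shape: {s_low.shape} vs {s_high.shape}"
        )
    if not b_high > b_low:
        raise ValueError("b_high must exceed b_low")

    valid = (
        (s_low > 0) & (s_high > 0) & np.isfinite(s_low) & np.isfinite(s_high)
    )
    if not valid.any():
        raise ValueError("no voxel has positive signal in both DWI volumes")

    adc = np.full(s_low.shape, np.nan)
    adc[valid] = np.log(s_low[valid] / s_high[valid]) / (b_high - b_low)
    return AdcMap(values=adc, valid=valid)


# --------------------------------------------------------------------------
# AIF model
# --------------------------------------------------------------------------


def gamma_variate_aif(
    times: np.ndarray,
    onset_s: float = 4.5,
    time_to_peak_s: float = 6.0,
    shape: float = 3.0,
    amplitude: float = 1.0,
) -> AifCurve:
    """Gamma-variate bolus curve, the standard DSC-MRI input model.

    a(t) = A * ((t-t0)/tp)^alpha * exp(alpha * (1 - (t-t0)/tp)) for t > t0,
    peaking at t0 + tp with value A.
    """
    t = np.asarray(times, dtype=float)
    u = (t - onset_s) / time_to_peak_s
    v = np.zeros_like(t)
    pos = u > 0
    v[pos] = amplitude * u[pos] ** shape * np.exp(shape * (1.0 - u[pos]))
    return AifCurve(times=t, values=v)


def aif_support_s(aif: AifCurve, rel_tol: float = 0.01) -> float:
    """Time after which the AIF stays below ``rel_tol`` of its peak."""
    thr = rel_tol * aif.values.max()
    above = np.nonzero(aif.values > thr)[0]
    if above.size == 0:
        return 0.0
    return float(aif.times[above[-1]])


# --------------------------------------------------------------------------
# block-circulant deconvolution
# --------------------------------------------------------------------------


class BlockCirculantDeconvolver:
    """Truncated-SVD pseudo-inverse of the zero-padded circulant AIF matrix.

    Built once per (AIF, lam); applying it to a stack of concentration
    curves is a single matrix product.
    """

    def __init__(self, aif: AifCurve, lam: float = 0.15):
        if not (0.0 <= lam < 1.0):
            raise ValueError("truncation fraction lam must be in [0, 1)")
        n = aif.values.size
        length = 2 * n  # zero-pad to >= 2N: wrap-around protection
        a_pad = np.zeros(length)
        a_pad[:n] = aif.values
        # circulant convolution matrix, column j is a_pad rolled by j
        idx = (np.arange(length)[:, None] - np.arange(length)[None, :]) % length
        matrix = a_pad[idx] * aif.dt

        u, s, vt = np.linalg.svd(matrix)
        keep = s >= lam * s[0]
        s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
        self._pinv = (vt.T * s_inv) @ u.T
        self.n_timepoints = n
        self.length = length
        self.dt = aif.dt
        self.lam = lam
        self.singular_values = s
        self.n_truncated = int((~keep).sum())

    def apply(self, curves: np.ndarray) -> np.ndarray:
        """Deconvolve curves (..., N) -> k(t) on the original N-grid."""
        curves = np.asarray(curves, dtype=float)
        if curves.shape[-1] != self.n_timepoints:
            raise ValueError("curve length does not match the deconvolver grid")
        flat = curves.reshape(-1, self.n_timepoints)
        padded = np.zeros((flat.shape[0], self.length))
        padded[:, : self.n_timepoints] = flat
        k = padded @ self._pinv.T
        return k[:, : self.n_timepoints].reshape(curves.shape)


def deconvolve_blockcirculant(
    study: PerfusionStudy, aif: AifCurve, lam: float = 0.15
) -> np.ndarray:
    """Per-voxel residue-scaled function k(t), shape (x, y, z, t)."""
    if abs(study.dt - aif.dt) > 1e-9:
        raise ValueError("study and AIF must share dt")
    return BlockCirculantDeconvolver(aif, lam).apply(study.data)


def compute_perfusion_maps(
    study: PerfusionStudy,
    aif: AifCurve | None = None,
    lam: float = 0.15,
    cbf_min: float = 1e-6,
    adc: AdcMap | None = None,
) -> ParameterMaps:
    """CBF/CBV/MTT/Tmax maps from a perfusion study.

    Per voxel: CBF = max_t k(t); Tmax = argmax_t k(t) * dt (earliest sample
    on ties); CBV = sum(C) dt / sum(AIF) dt; MTT = CBV/CBF where
    CBF > ``cbf_min``, else NaN with ``mtt_valid`` False.
    """
    aif = study.aif if aif is None else aif
    k = deconvolve_blockcirculant(study, aif, lam)
    cbf = k.max(axis=-1)
    tmax = np.argmax(k, axis=-1) * study.dt
    cbv = study.data.sum(axis=-1) * study.dt / aif.area
    cbv = np.clip(cbv, 0.0, None)  # noise can push tiny areas negative
    cbf = np.clip(cbf, 0.0, None)

    mtt_valid = cbf > cbf_min
    mtt = np.full(cbf.shape, np.nan)
    mtt[mtt_valid] = cbv[mtt_valid] / cbf[mtt_valid]
    mtt = np.clip(mtt, 0.0, None)

    if adc is None:
        adc = AdcMap(
            values=np.full(cbf.shape, np.nan), valid=np.zeros(cbf.shape, bool)
        )
    return ParameterMaps(
        adc=adc, cbf=cbf, cbv=cbv, mtt=mtt, tmax=tmax, mtt_valid=mtt_valid
    )


# --------------------------------------------------------------------------
# contralateral normalization
# --------------------------------------------------------------------------


def normalize_maps(
    maps: ParameterMaps,
    brain: np.ndarray,
    csf: np.ndarray,
    hemisphere_labels: np.ndarray,
    affected_hemisphere: int,
) -> ParameterMaps:
    """Fill rCBF, rCBV, dMTT, dTmax from contralateral brain-tissue means.

    The reference region is the brain mask of the hemisphere opposite
    ``affected_hemisphere``, with CSF voxels excluded.  Ratios for CBF/CBV,
    differences for MTT/Tmax.
    """
    contra = 3 - int(affected_hemisphere)  # LEFT=1 <-> RIGHT=2
    ref = brain & ~csf & (hemisphere_labels == contra)
    if not ref.any():
        raise ValueError("contralateral reference mask is empty")

    def _mean(arr, valid=None):
        sel = ref if valid is None else (ref & valid)
        vals = arr[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no valid contralateral voxels for normalization")
        return float(vals.mean())

    cbf_ref = _mean(maps.cbf)
    cbv_ref = _mean(maps.cbv)
    if cbf_ref == 0 or cbv_ref == 0:
        raise ZeroDivisionError("contralateral mean CBF/CBV is zero")
    mtt_ref = _mean(maps.mtt, maps.mtt_valid)
    tmax_ref = _mean(maps.tmax)

    maps.rcbf = maps.cbf / cbf_ref
    maps.rcbv = maps.cbv / cbv_ref
    maps.dmtt = maps.mtt - mtt_ref
    maps.dtmax = maps.tmax - tmax_ref
    return maps
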