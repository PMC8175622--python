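"""Two-arm synthetic stroke cohort with known ground truth.

This module emulates the data a two-arm neuroprotection trial would
collect per patient — a DWI pair (b=0/b=1000), a 4-D DSC-perfusion
concentration series with its AIF, a follow-up lesion mask and a clinical
record — on the ellipsoidal phantom, with a latent hemodynamic truth
(CBF/MTT/bolus delay, ischemic core nested in a hypoperfused shell) that
the analysis modules are supposed to recover.

Forward models
--------------
*   DWI: ``b1000 = s0 * exp(-b * ADC_true) + noise`` with piecewise ADC
    truth (normal tissue 900e-6, core 450e-6, CSF 2700e-6 mm^2/s).
*   Perfusion: per voxel ``C(t) = (CBF/KAPPA) * dt * (AIF (*) R(t-delay))
    + noise`` with a delayed-exponential (or boxcar) residue function R.
    The sampled R is rescaled so its *discrete* area equals MTT exactly;
    this makes the central-volume identity CBV = CBF*MTT/KAPPA hold on the
    grid rather than only in the continuum limit.
*   Tissue fate: a per-voxel logistic model on standardized truth
    covariates (ADC deficit, hypoperfusion severity, distance to core,
    recanalization), with core voxels infarcting with probability 1 and a
    log-odds protection ``tau`` applied to the theophylline arm only
    (tau = 0 is the null of no arm difference).

Every operation is a pure function of its inputs and a seed; per-patient
and per-stage sub-seeds are derived from the master seed (see `_seeds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from . import _seeds
from .phantom import LEFT, RIGHT, PhantomAnatomy, generate_phantom
from .perfusion import AifCurve, PerfusionStudy, gamma_variate_aif, aif_support_s

__all__ = [
    "KAPPA",
    "NORMAL_CBF",
    "NORMAL_MTT",
    "NORMAL_ADC",
    "CORE_ADC",
    "CSF_ADC",
    "LesionSpec",
    "AifSpec",
    "GroundTruthHemodynamics",
    "TissueFateParams",
    "ClinicalRecord",
    "CohortConfig",
    "PatientCase",
    "simulate_hemodynamics",
    "synthesize_perfusion_series",
    "synthesize_dwi",
    "adc_truth_field",
    "assign_tissue_fate",
    "generate_patient",
    "generate_truth",
    "TruthBundle",
    "generate_cohort",
]

# unit constant of the tracer-kinetic forward model: CBV = CBF * MTT / KAPPA
# (60 s/min, so CBF in ml/100g/min and MTT in s give CBV in ml/100g)
KAPPA = 60.0

NORMAL_CBF = 60.0  # ml/100g/min
NORMAL_MTT = 4.0  # s
NORMAL_ADC = 900e-6  # mm^2/s
CORE_ADC = 450e-6
CSF_ADC = 2700e-6


# --------------------------------------------------------------------------
# specs and truth containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and severity of one simulated occlusion."""

    centre_mm: tuple[float, float, float]
    hemisphere: int  # LEFT or RIGHT
    core_radius_mm: float
    hypo_radius_mm: float
    core_cbf_factor: float = 0.15
    shell_cbf_factor: float = 0.45
    core_mtt_s: float = 10.0
    shell_mtt_s: float = 8.0
    core_delay_s: float = 10.0
    shell_delay_s: float = 8.0
    field_jitter_sd: float = 0.0  # smooth multiplicative CBF/MTT jitter

    def __post_init__(self):
        if self.core_radius_mm < 0 or self.hypo_radius_mm < 0:
            raise ValueError("radii must be non-negative")
        if self.core_radius_mm > 0 and self.hypo_radius_mm <= self.core_radius_mm:
            raise ValueError("hypoperfusion radius must exceed core radius")


@dataclass(frozen=True)
class AifSpec:
    onset_s: float = 4.5
    time_to_peak_s: float = 6.0
    shape: float = 3.0
    amplitude: float = 1.0

    def curve(self, times: np.ndarray) -> AifCurve:
        return gamma_variate_aif(
            times, self.onset_s, self.time_to_peak_s, self.shape, self.amplitude
        )


@dataclass
class GroundTruthHemodynamics:
    """Latent truth the perfusion analysis estimates."""

    true_cbf: np.ndarray  # ml/100g/min
    true_mtt: np.ndarray  # s
    true_delay: np.ndarray  # s
    true_core: np.ndarray  # bool
    true_hypoperfusion: np.ndarray  # bool


@dataclass(frozen=True)
class TissueFateParams:
    """Logistic per-voxel infarction mechanism.

    logit p = intercept + b_adc*adc_deficit + b_severity*severity
              + b_distance*distance + b_recan*recanalized - tau*[theophylline]

    with adc_deficit = (900e-6 - ADC_true)/300e-6, severity = delay/6 s,
    distance = min(distance_to_core, 20 mm)/10 mm.  tau >= 0 encodes
    protection (expected lesion volume non-increasing in tau); tau = 0 is
    the exact null.  Core voxels infarct with probability 1.
    """

    intercept: float = -3.0
    b_adc: float = 2.0
    b_severity: float = 4.0
    b_distance: float = -4.0
    b_recan: float = -1.5
    tau: float = 0.0
    recanalization_probability: float = 0.43

    def __post_init__(self):
        if not (0.0 <= self.recanalization_probability <= 1.0):
            raise ValueError("recanalization_probability must be in [0, 1]")


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    age: int
    sex: int  # 1 = female
    nihss: int
    onset_to_drug_minutes: int
    arm: str  # "theophylline" | "placebo"
    recanalized: int
    large_vessel_occlusion: int
    stroke_type: str  # "cortical" | "lacunar"

    def __post_init__(self):
        if self.nihss < 4:
            raise ValueError("trial inclusion requires NIHSS >= 4")
        if self.arm not in ("theophylline", "placebo"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.stroke_type not in ("cortical", "lacunar"):
            raise ValueError(f"unknown stroke type {self.stroke_type!r}")


@dataclass
class PatientCase:
    """One synthetic patient: raw data, truth, and (later) derived products."""

    record: ClinicalRecord
    phantom: PhantomAnatomy
    gt: GroundTruthHemodynamics
    lesion_spec: LesionSpec
    affected_hemisphere: int
    b0: np.ndarray
    b1000: np.ndarray
    study: Optional[PerfusionStudy]
    followup_lesion: np.ndarray
    # filled by the processing pipeline
    maps: object = None
    masks: object = None
    features: object = None

    @property
    def patient_id(self) -> str:
        return self.record.patient_id

    def drop_raw(self) -> None:
        """Release the 4-D series after maps are computed (memory)."""
        self.study = None


# --------------------------------------------------------------------------
# hemodynamic truth
# --------------------------------------------------------------------------


def simulate_hemodynamics(
    phantom: PhantomAnatomy, lesion_spec: LesionSpec, seed: int = 0
) -> GroundTruthHemodynamics:
    """Piecewise hemodynamic truth: normal brain, hypoperfused shell, core.

    Normal tissue: CBF 60 ml/100g/min, MTT 4 s, delay 0.  Inside the
    hypoperfused shell CBF is reduced, MTT prolonged and the bolus delayed
    (default 8 s, i.e. above the 6 s Tmax threshold); the core is strictly
    inside the shell with a harsher reduction.  An optional smooth
    multiplicative jitter (``lesion_spec.field_jitter_sd``) perturbs CBF
    and MTT but never the masks.
    """
    x, y, z = phantom.coords_mm()
    c = lesion_spec.centre_mm
    idx = tuple(
        int(round(c[a] / phantom.spacing[a] + (phantom.shape[a] - 1) / 2.0))
        for a in range(3)
    )
    if any(i < 0 or i >= n for i, n in zip(idx, phantom.shape)) or not (
        phantom.brain_mask[idx]
    ):
        raise ValueError(f"lesion centre {c} mm is outside the brain")

    r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
    brain = phantom.brain_mask
    core = (r <= lesion_spec.core_radius_mm) & brain
    hypo = ((r <= lesion_spec.hypo_radius_mm) & brain) | core
    if lesion_spec.core_radius_mm == 0:
        core = np.zeros_like(brain)

    shell = hypo & ~core
    cbf = np.zeros(phantom.shape)
    mtt = np.zeros(phantom.shape)
    delay = np.zeros(phantom.shape)
    cbf[brain] = NORMAL_CBF
    mtt[brain] = NORMAL_MTT
    cbf[shell] = NORMAL_CBF * lesion_spec.shell_cbf_factor
    cbf[core] = NORMAL_CBF * lesion_spec.core_cbf_factor
    mtt[shell] = lesion_spec.shell_mtt_s
    mtt[core] = lesion_spec.core_mtt_s
    delay[shell] = lesion_spec.shell_delay_s
    delay[core] = lesion_spec.core_delay_s

    if lesion_spec.field_jitter_sd > 0:
        rng = _seeds.rng_for(seed, _seeds.HEMODYNAMICS)
        for arr in (cbf, mtt):
            noise = ndimage.gaussian_filter(
                rng.standard_normal(phantom.shape), sigma=1.5
            )
            sd = noise[brain].std()
            if sd > 0:
                arr[brain] *= 1.0 + lesion_spec.field_jitter_sd * (
                    noise[brain] / sd
                )
        np.clip(cbf, 1.0, None, out=cbf, where=brain)
        np.clip(mtt, 0.5, None, out=mtt, where=brain)
        cbf[~brain] = 0.0
        mtt[~brain] = 0.0

    return GroundTruthHemodynamics(
        true_cbf=cbf,
        true_mtt=mtt,
        true_delay=delay,
        true_core=core,
        true_hypoperfusion=hypo,
    )


# --------------------------------------------------------------------------
# perfusion forward model
# --------------------------------------------------------------------------


def _residue_kernels(
    times: np.ndarray, mtt: np.ndarray, delay: np.ndarray, model: str
) -> np.ndarray:
    """Sampled residue functions, one row per voxel, discrete area = MTT."""
    t = times[None, :]
    d = delay[:, None]
    m = mtt[:, None]
    if model == "exponential":
        r = np.where(t >= d, np.exp(-np.maximum(t - d, 0.0) / m), 0.0)
    elif model == "boxcar":
        r = ((t >= d) & (t < d + m)).astype(float)
        empty = r.sum(axis=1) == 0  # MTT shorter than dt: keep one sample
        if empty.any():
            j = np.clip(
                np.round(delay[empty] / (times[1] - times[0])).astype(int),
                0,
                times.size - 1,
            )
            r[np.nonzero(empty)[0], j] = 1.0
    else:
        raise ValueError(f"unknown residue model {model!r}")
    dt = times[1] - times[0]
    area = r.sum(axis=1) * dt
    r *= (mtt / area)[:, None]
    return r


def synthesize_perfusion_series(
    gt: GroundTruthHemodynamics,
    phantom: PhantomAnatomy,
    aif_spec: AifSpec = AifSpec(),
    dt: float = 1.5,
    n_timepoints: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue_model: str = "exponential",
) -> PerfusionStudy:
    """Forward DSC series: C = (CBF/KAPPA) * dt * (AIF (*) R(t-delay)) + noise.

    Raises if the series is too short to contain the AIF support plus the
    maximum delay and MTT (truncation would bias CBV downstream).
    Gaussian noise (sd in concentration units) is added inside the head
    only; air voxels stay identically zero, and ``noise_sd = 0`` yields
    noise-free curves.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(n_timepoints) * float(dt)
    aif = aif_spec.curve(times)

    head = phantom.brain_mask | phantom.csf_mask
    active = gt.true_cbf > 0
    span_needed = (
        aif_support_s(aif)
        + float(gt.true_delay[active].max(initial=0.0))
        + float(gt.true_mtt[active].max(initial=0.0))
    )
    if times[-1] < span_needed:
        raise ValueError(
            f"series length {times[-1]:.1f}s shorter than AIF support + max "
            f"delay + max MTT ({span_needed:.1f}s); curves would be truncated"
        )

    data = np.zeros(phantom.shape + (n_timepoints,))
    if active.any():
        r = _residue_kernels(
            times, gt.true_mtt[active], gt.true_delay[active], residue_model
        )
        k = (gt.true_cbf[active] / KAPPA)[:, None] * r
        length = 2 * n_timepoints
        conv = np.fft.irfft(
            np.fft.rfft(k, length) * np.fft.rfft(aif.values, length), length
        )[:, :n_timepoints]
        data[active] = dt * conv

    if noise_sd > 0:
        rng = _seeds.rng_for(seed, _seeds.PERFUSION)
        data[head] += rng.normal(0.0, noise_sd, size=(int(head.sum()), n_timepoints))

    return PerfusionStudy(data=data, dt=float(dt), aif=aif)


# --------------------------------------------------------------------------
# DWI forward model
# --------------------------------------------------------------------------


def adc_truth_field(
    gt: GroundTruthHemodynamics, phantom: PhantomAnatomy
) -> np.ndarray:
    """Piecewise ADC truth (mm^2/s): tissue 900e-6, core 450e-6, CSF 2700e-6."""
    adc = np.zeros(phantom.shape)
    adc[phantom.brain_mask] = NORMAL_ADC
    adc[gt.true_core] = CORE_ADC
    adc[phantom.csf_mask] = CSF_ADC
    return adc


def synthesize_dwi(
    gt: GroundTruthHemodynamics,
    phantom: PhantomAnatomy,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    b_value: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """DWI pair (b=0, b=1000): b1000 = s0*exp(-b*ADC_true) + noise.

    Noise is additive Gaussian inside the head; air stays exactly zero so
    downstream ADC computation flags it invalid rather than producing
    garbage values.
    """
    head = phantom.brain_mask | phantom.csf_mask
    adc = adc_truth_field(gt, phantom)
    b0 = np.where(head, float(s0), 0.0)
    b1000 = np.where(head, s0 * np.exp(-b_value * adc), 0.0)
    if noise_sd > 0:
        rng = _seeds.rng_for(seed, _seeds.DWI)
        n = int(head.sum())
        b0[head] += rng.normal(0.0, noise_sd, size=n)
        b1000[head] += rng.normal(0.0, noise_sd, size=n)
    return b0, b1000


# --------------------------------------------------------------------------
# tissue fate
# --------------------------------------------------------------------------

_DISTANCE_SCALE_MM = 10.0
_DISTANCE_CAP_MM = 20.0
_ADC_DEFICIT_SCALE = 300e-6
_SEVERITY_SCALE_S = 6.0


def fate_probability(
    gt: GroundTruthHemodynamics,
    phantom: PhantomAnatomy,
    record: ClinicalRecord,
    params: TissueFateParams,
) -> np.ndarray:
    """Per-voxel infarction probability field (1 on core, 0 outside brain)."""
    brain = phantom.brain_mask
    adc = adc_truth_field(gt, phantom)
    adc_deficit = (NORMAL_ADC - adc) / _ADC_DEFICIT_SCALE
    severity = gt.true_delay / _SEVERITY_SCALE_S

    if gt.true_core.any():
        dist = ndimage.distance_transform_edt(
            ~gt.true_core, sampling=phantom.spacing
        )
    else:
        dist = np.full(phantom.shape, _DISTANCE_CAP_MM)
    dist = np.minimum(dist, _DISTANCE_CAP_MM) / _DISTANCE_SCALE_MM

    logit = (
        params.intercept
        + params.b_adc * adc_deficit
        + params.b_severity * severity
        + params.b_distance * dist
        + params.b_recan * record.recanalized
    )
    if record.arm == "theophylline":
        logit = logit - params.tau
    p = np.zeros(phantom.shape)
    p[brain] = 1.0 / (1.0 + np.exp(-logit[brain]))
    p[gt.true_core] = 1.0
    return p


def assign_tissue_fate(
    gt: GroundTruthHemodynamics,
    phantom: PhantomAnatomy,
    record: ClinicalRecord,
    params: TissueFateParams,
    seed: int = 0,
) -> np.ndarray:
    """Sample the follow-up lesion mask from the logistic fate model.

    Guarantees ``true_core <= lesion <= brain_mask``.  With ``tau = 0`` the
    arm label has no effect: identical seeds give identical lesions
    regardless of arm.
    """
    p = fate_probability(gt, phantom, record, params)
    rng = _seeds.rng_for(seed, _seeds.FATE)
    draw = rng.random(phantom.shape)
    lesion = (draw < p) & phantom.brain_mask
    lesion |= gt.true_core
    return lesion


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort (defaults: trial-like)."""

    n_theophylline: int = 27
    n_placebo: int = 25
    shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    dt: float = 1.5
    n_timepoints: int = 40
    s0: float = 1000.0
    dwi_noise_sd: float = 5.0
    perfusion_noise_sd: float = 0.02
    residue_model: str = "exponential"
    field_jitter_sd: float = 0.05
    # right-skewed (log-normal) core radii so volume SD can exceed the mean;
    # parameters target the trial's core-volume scale (mean ~4-5 ml, SD > mean)
    log_core_radius_mean: float = 2.26  # ln(mm)
    log_core_radius_sd: float = 0.36
    lacunar_radius_scale: float = 0.45
    mismatch_probability: float = 0.55  # fraction with a real penumbral shell
    aif: AifSpec = field(default_factory=AifSpec)
    fate: TissueFateParams = field(default_factory=TissueFateParams)

    def __post_init__(self):
        if self.n_theophylline < 2 or self.n_placebo < 2:
            raise ValueError("need at least 2 patients per arm")

    @property
    def n_total(self) -> int:
        return self.n_theophylline + self.n_placebo


def _sample_clinical(
    rng: np.random.Generator, patient_id: str, arm: str, recan_prob: float
) -> ClinicalRecord:
    """Clinical covariates matching the trial's baseline table scale
    (median age ~70 y, median NIHSS 7-8, LVO ~44%, cortical ~65%)."""
    age = int(np.clip(round(rng.normal(70.0, 13.0)), 35, 92))
    sex = int(rng.random() < 0.40)
    nihss = int(4 + rng.poisson(3.5))
    onset = int(np.clip(round(rng.lognormal(np.log(130.0), 0.35)), 60, 300))
    lvo = int(rng.random() < 0.44)
    stroke_type = "cortical" if rng.random() < 0.65 else "lacunar"
    recan = int(bool(lvo) and rng.random() < recan_prob)
    return ClinicalRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        nihss=nihss,
        onset_to_drug_minutes=onset,
        arm=arm,
        recanalized=recan,
        large_vessel_occlusion=lvo,
        stroke_type=stroke_type,
    )


def _sample_lesion_spec(
    rng: np.random.Generator,
    phantom: PhantomAnatomy,
    config: CohortConfig,
    stroke_type: str,
) -> LesionSpec:
    hemisphere = LEFT if rng.random() < 0.5 else RIGHT
    sgn = -1.0 if hemisphere == LEFT else 1.0

    r_core = float(rng.lognormal(config.log_core_radius_mean, config.log_core_radius_sd))
    if stroke_type == "lacunar":
        r_core *= config.lacunar_radius_scale
    r_core = min(r_core, 25.0)
    if rng.random() < config.mismatch_probability:
        ratio = float(np.clip(rng.lognormal(np.log(1.6), 0.2), 1.2, 2.5))
    else:
        ratio = 1.05  # no real penumbral shell -> tissue-at-risk ~ absent
    r_hypo = min(max(r_core * ratio, r_core + 1.0), 32.0)
    if r_core == 0.0:
        r_hypo = max(r_hypo, 4.0)

    half_fov = [n * s / 2.0 for n, s in zip(phantom.shape, phantom.spacing)]
    semi = [0.82 * h for h in half_fov]
    centre = np.array(
        [
            sgn * 0.50 * semi[0],
            rng.uniform(-0.12, 0.12) * semi[1],
            rng.uniform(-0.12, 0.12) * semi[2],
        ]
    )
    # nudge outward until the centre voxel is brain (coarse grids can round
    # onto the ventricle boundary)
    for _ in range(6):
        idx = tuple(
            int(round(centre[a] / phantom.spacing[a] + (phantom.shape[a] - 1) / 2.0))
            for a in range(3)
        )
        inside = all(0 <= i < n for i, n in zip(idx, phantom.shape))
        if inside and phantom.brain_mask[idx]:
            break
        centre[0] += sgn * phantom.spacing[0]
    return LesionSpec(
        centre_mm=tuple(float(v) for v in centre),
        hemisphere=hemisphere,
        core_radius_mm=r_core,
        hypo_radius_mm=r_hypo,
        field_jitter_sd=config.field_jitter_sd,
    )


@dataclass(frozen=True)
class TruthBundle:
    """Clinical record plus latent truth, before any imaging synthesis."""

    record: ClinicalRecord
    phantom: PhantomAnatomy
    lesion_spec: LesionSpec
    gt: GroundTruthHemodynamics


def generate_truth(
    config: CohortConfig, master_seed: int, index: int, arm: str
) -> TruthBundle:
    """Sample one patient's clinical record, anatomy and hemodynamic truth.

    The cheap half of patient generation; Monte-Carlo distribution checks
    use it without paying for DWI/perfusion synthesis.
    """
    pid = f"S{index:03d}"
    clin_rng = _seeds.rng_for(master_seed, _seeds.CLINICAL, index)
    record = _sample_clinical(
        clin_rng, pid, arm, config.fate.recanalization_probability
    )
    phantom = generate_phantom(
        config.shape,
        config.spacing,
        seed=_seeds.int_seed(master_seed, _seeds.PHANTOM, index),
    )
    geo_rng = _seeds.rng_for(master_seed, _seeds.GEOMETRY, index)
    spec = _sample_lesion_spec(geo_rng, phantom, config, record.stroke_type)
    gt = simulate_hemodynamics(
        phantom, spec, seed=_seeds.int_seed(master_seed, _seeds.HEMODYNAMICS, index)
    )
    return TruthBundle(record=record, phantom=phantom, lesion_spec=spec, gt=gt)


def generate_patient(
    config: CohortConfig, master_seed: int, index: int, arm: str
) -> PatientCase:
    """Generate one patient; regenerable in isolation from (seed, index)."""
    truth = generate_truth(config, master_seed, index, arm)
    record, phantom, spec, gt = (
        truth.record,
        truth.phantom,
        truth.lesion_spec,
        truth.gt,
    )
    b0, b1000 = synthesize_dwi(
        gt,
        phantom,
        s0=config.s0,
        noise_sd=config.dwi_noise_sd,
        seed=_seeds.int_seed(master_seed, _seeds.DWI, index),
    )
    study = synthesize_perfusion_series(
        gt,
        phantom,
        aif_spec=config.aif,
        dt=config.dt,
        n_timepoints=config.n_timepoints,
        noise_sd=config.perfusion_noise_sd,
        seed=_seeds.int_seed(master_seed, _seeds.PERFUSION, index),
        residue_model=config.residue_model,
    )
    lesion = assign_tissue_fate(
        gt,
        phantom,
        record,
        config.fate,
        seed=_seeds.int_seed(master_seed, _seeds.FATE, index),
    )
    return PatientCase(
        record=record,
        phantom=phantom,
        gt=gt,
        lesion_spec=spec,
        affected_hemisphere=spec.hemisphere,
        b0=b0,
        b1000=b1000,
        study=study,
        followup_lesion=lesion,
    )


def generate_cohort(config: CohortConfig, seed: int = 0) -> list[PatientCase]:
    """Generate the full two-arm cohort (theophylline first, then placebo)."""
    arms = ["theophylline"] * config.n_theophylline + ["placebo"] * config.n_placebo
    return [
        generate_patient(config, seed, i, arm) for i, arm in enumerate(arms)
    ]
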