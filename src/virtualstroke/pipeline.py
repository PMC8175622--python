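"""End-to-end orchestration: generate -> maps -> segment -> features -> trial -> stats.

Two entry styles:

*   :func:`simulate_virtual_trial` runs the whole chain in memory for one
    cohort and returns a :class:`TrialResult`; the calibration harness and
    the tests use this.
*   :func:`run_pipeline` / the per-stage functions run from one
    :class:`RunConfig`, each stage reading its declared inputs from the
    previous stage's on-disk outputs (NIfTI / CSV / JSON), so any stage is
    re-runnable in isolation and a run is reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import _seeds, io
from .features import FEATURE_COLUMNS, assemble_features
from .perfusion import (
    AdcMap,
    PerfusionStudy,
    compute_adc,
    compute_perfusion_maps,
    normalize_maps,
)
from .prediction import TrialConfig, VirtualPrediction, run_virtual_trial
from .segmentation import (
    CORE_ADC_THRESHOLD,
    CSF_THRESHOLD,
    TMAX_THRESHOLD_S,
    LesionMaskSet,
    distance_to_core,
    segment_brain_csf,
    segment_core,
    segment_hypoperfusion,
    tissue_at_risk,
)
from .stats import (
    AgreementSummary,
    PairedComparison,
    SubgroupContrast,
    bland_altman,
    paired_volume_test,
    subgroup_tests,
)
from .synthetic import (
    ClinicalRecord,
    CohortConfig,
    PatientCase,
    AifSpec,
    TissueFateParams,
    generate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessingParams",
    "RunConfig",
    "TrialResult",
    "process_case",
    "process_cohort",
    "compute_trial_statistics",
    "simulate_virtual_trial",
    "run_pipeline",
]

MAP_NAMES = ("adc", "cbf", "cbv", "mtt", "tmax", "rcbf", "rcbv", "dmtt", "dtmax")
MASK_NAMES = ("brain", "csf", "core", "hypoperfusion", "tissue_at_risk")


@dataclass
class ProcessingParams:
    """Analysis-side parameters (trial-reported values as defaults)."""

    b_low: float = 0.0
    b_high: float = 1000.0  # s/mm^2
    svd_truncation: float = 0.15  # fraction of sigma_max
    csf_threshold: float = CSF_THRESHOLD
    adc_threshold: float = CORE_ADC_THRESHOLD
    tmax_threshold_s: float = TMAX_THRESHOLD_S
    cbf_min: float = 1e-6


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    trial: TrialConfig = field(default_factory=TrialConfig)
    seed: int = 0
    output_dir: str = "virtualstroke_run"

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        cohort = dict(d.get("cohort", {}))
        if "aif" in cohort:
            cohort["aif"] = AifSpec(**cohort["aif"])
        if "fate" in cohort:
            cohort["fate"] = TissueFateParams(**cohort["fate"])
        for key in ("shape", "spacing"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        return RunConfig(
            cohort=CohortConfig(**cohort),
            processing=ProcessingParams(**d.get("processing", {})),
            trial=TrialConfig(**d.get("trial", {})),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "virtualstroke_run")),
        )

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# in-memory processing
# --------------------------------------------------------------------------


def process_case(
    case: PatientCase,
    params: ProcessingParams = ProcessingParams(),
    drop_raw: bool = True,
) -> PatientCase:
    """Run the full image post-processing chain for one patient.

    ADC -> perfusion maps -> contralateral normalization -> brain/CSF,
    core, hypoperfusion, tissue-at-risk segmentation -> distance map ->
    feature table.  Results are attached to the case in place.
    """
    adc = compute_adc(case.b0, case.b1000, params.b_low, params.b_high)
    maps = compute_perfusion_maps(
        case.study, lam=params.svd_truncation, cbf_min=params.cbf_min, adc=adc
    )
    brain, csf = segment_brain_csf(adc, params.csf_threshold)
    normalize_maps(
        maps, brain, csf, case.phantom.hemisphere_labels, case.affected_hemisphere
    )
    affected = case.phantom.hemisphere_labels == case.affected_hemisphere
    core = segment_core(
        adc, brain, adc_threshold=params.adc_threshold, affected_mask=affected
    )
    hypo = segment_hypoperfusion(maps.dtmax, brain, params.tmax_threshold_s)
    masks = LesionMaskSet(
        brain=brain,
        csf=csf,
        core=core,
        hypoperfusion=hypo,
        tissue_at_risk=tissue_at_risk(hypo, core),
        distance_to_core=distance_to_core(core, case.phantom.spacing),
        followup_lesion=case.followup_lesion,
    )
    case.maps = maps
    case.masks = masks
    case.features = assemble_features(case)
    if drop_raw:
        case.drop_raw()
    return case


def process_cohort(
    cases, params: ProcessingParams = ProcessingParams(), drop_raw: bool = True
) -> list[PatientCase]:
    return [process_case(c, params, drop_raw) for c in cases]


# --------------------------------------------------------------------------
# trial-level statistics
# --------------------------------------------------------------------------


@dataclass
class TrialResult:
    predictions: list[VirtualPrediction]
    failures: list[str]
    paired: PairedComparison
    agreement: AgreementSummary
    subgroups: list[SubgroupContrast]
    mean_dice_theophylline: float
    mean_dice_placebo: float

    @property
    def volumes(self) -> pd.DataFrame:
        return io.predictions_to_frame(self.predictions)

    def report_dict(self) -> dict:
        return {
            "n_patients": self.paired.n,
            "failures": self.failures,
            "paired_test": dataclasses.asdict(self.paired),
            "bland_altman": {
                "mean_difference_ml": self.agreement.mean_difference,
                "sd_difference_ml": self.agreement.sd_difference,
                "lower_limit_ml": self.agreement.lower_limit,
                "upper_limit_ml": self.agreement.upper_limit,
            },
            "mean_dice_theophylline": self.mean_dice_theophylline,
            "mean_dice_placebo": self.mean_dice_placebo,
            "subgroups": [dataclasses.asdict(s) for s in self.subgroups],
        }

    def report_text(self) -> str:
        p = self.paired
        lines = [
            f"Virtual treatment comparison over {p.n} patients "
            f"({len(self.failures)} failed)",
            f"  predicted volume, virtual theophylline: "
            f"{p.mean_theophylline:.2f} ml (SD {p.sd_theophylline:.2f})",
            f"  predicted volume, virtual placebo:      "
            f"{p.mean_placebo:.2f} ml (SD {p.sd_placebo:.2f})",
            f"  paired t-test: t = {p.t_statistic:.3f}, p = {p.p_value:.3f}"
            + ("  [degenerate]" if p.degenerate else ""),
            f"  mean Dice vs truth: theophylline arm {self.mean_dice_theophylline:.3f}, "
            f"placebo arm {self.mean_dice_placebo:.3f}",
            f"  Bland-Altman: mean diff {self.agreement.mean_difference:.2f} ml, "
            f"limits [{self.agreement.lower_limit:.2f}, "
            f"{self.agreement.upper_limit:.2f}] ml",
        ]
        for s in self.subgroups:
            if s.flagged:
                lines.append(f"  subgroup {s.name}: flagged (group < 2)")
            else:
                lines.append(
                    f"  subgroup {s.name}: n = {s.n_in}/{s.n_out}, "
                    f"t = {s.t_statistic:.3f}, p = {s.p_value:.3f}"
                )
        return "\n".join(lines) + "\n"


def compute_trial_statistics(predictions, cases) -> TrialResult:
    if len(predictions) < 2:
        raise ValueError("need >= 2 successful patients for trial statistics")
    pairs = [
        (p.vol_theophylline_ml, p.vol_placebo_ml) for p in predictions
    ]
    by_arm = {
        arm: [p.dice for p in predictions if p.arm == arm]
        for arm in ("theophylline", "placebo")
    }
    return TrialResult(
        predictions=list(predictions),
        failures=[],
        paired=paired_volume_test(pairs),
        agreement=bland_altman(pairs),
        subgroups=subgroup_tests(predictions, cases),
        mean_dice_theophylline=float(np.mean(by_arm["theophylline"]))
        if by_arm["theophylline"]
        else float("nan"),
        mean_dice_placebo=float(np.mean(by_arm["placebo"]))
        if by_arm["placebo"]
        else float("nan"),
    )


def simulate_virtual_trial(
    cohort_config: CohortConfig,
    seed: int = 0,
    processing: ProcessingParams | None = None,
    trial_config: TrialConfig | None = None,
) -> TrialResult:
    """Generate, process and analyse one synthetic cohort in memory."""
    processing = processing or ProcessingParams()
    trial_config = trial_config or TrialConfig(seed=seed)
    cases = generate_cohort(cohort_config, seed=seed)
    process_cohort(cases, processing)
    predictions, failures = run_virtual_trial(cases, trial_config)
    result = compute_trial_statistics(predictions, cases)
    result.failures = failures
    return result


# --------------------------------------------------------------------------
# disk-based stages
# --------------------------------------------------------------------------


def _dirs(outdir):
    out = Path(outdir)
    return SimpleNamespace(
        root=out,
        raw=out / "raw",
        maps=out / "maps",
        masks=out / "masks",
        features=out / "features",
        trial=out / "trial",
        stats=out / "stats",
    )


def stage_generate(config: RunConfig) -> None:
    """Write the synthetic cohort: raw volumes, truth masks, cohort CSV."""
    d = _dirs(config.output_dir)
    io.ensure_dir(d.raw)
    cases = generate_cohort(config.cohort, seed=config.seed)
    io.save_cohort_csv(cases, d.root / "cohort.csv")
    sp = config.cohort.spacing
    for c in cases:
        pid = c.patient_id
        io.save_volume(c.b0, sp, d.raw / f"{pid}_b0.nii.gz")
        io.save_volume(c.b1000, sp, d.raw / f"{pid}_b1000.nii.gz")
        io.save_volume(
            c.study.data.astype(np.float32), sp, d.raw / f"{pid}_perfusion.nii.gz"
        )
        io.save_aif_csv(c.study.aif, d.raw / f"{pid}_aif.csv")
        io.save_volume(c.followup_lesion, sp, d.raw / f"{pid}_followup.nii.gz")
        io.save_volume(
            c.phantom.hemisphere_labels, sp, d.raw / f"{pid}_hemispheres.nii.gz"
        )
        io.save_volume(c.phantom.region_atlas, sp, d.raw / f"{pid}_atlas.nii.gz")
        io.save_volume(c.gt.true_core, sp, d.raw / f"{pid}_true_core.nii.gz")
        io.save_volume(
            c.gt.true_hypoperfusion, sp, d.raw / f"{pid}_true_hypoperfusion.nii.gz"
        )
    logger.info("generate: wrote %d patients to %s", len(cases), d.raw)


def _load_cases(config: RunConfig, need=("raw",)) -> list[SimpleNamespace]:
    """Rebuild lightweight cases from stage outputs on disk."""
    d = _dirs(config.output_dir)
    frame = io.load_cohort_csv(d.root / "cohort.csv")
    cases = []
    for _, row in frame.iterrows():
        pid = row["patient_id"]
        record = ClinicalRecord(
            patient_id=pid,
            age=int(row["age"]),
            sex=int(row["sex"]),
            nihss=int(row["nihss"]),
            onset_to_drug_minutes=int(row["onset_to_drug_minutes"]),
            arm=row["arm"],
            recanalized=int(row["recanalized"]),
            large_vessel_occlusion=int(row["lvo"]),
            stroke_type=row["stroke_type"],
        )
        hemis, spacing = io.load_volume(d.raw / f"{pid}_hemispheres.nii.gz")
        atlas, _ = io.load_volume(d.raw / f"{pid}_atlas.nii.gz")
        followup, _ = io.load_volume(d.raw / f"{pid}_followup.nii.gz")
        phantom = SimpleNamespace(
            hemisphere_labels=hemis.astype(np.int8),
            region_atlas=atlas.astype(np.int16),
            shape=hemis.shape,
            spacing=spacing,
        )
        case = SimpleNamespace(
            record=record,
            patient_id=pid,
            phantom=phantom,
            affected_hemisphere=int(row["affected_hemisphere"]),
            followup_lesion=followup.astype(bool),
            b0=None,
            b1000=None,
            study=None,
            maps=None,
            masks=None,
            features=None,
        )
        if "raw" in need:
            b0, _ = io.load_volume(d.raw / f"{pid}_b0.nii.gz")
            b1000, _ = io.load_volume(d.raw / f"{pid}_b1000.nii.gz")
            perf, _ = io.load_volume(d.raw / f"{pid}_perfusion.nii.gz")
            aif = io.load_aif_csv(d.raw / f"{pid}_aif.csv")
            case.b0, case.b1000 = b0, b1000
            case.study = PerfusionStudy(
                data=np.asarray(perf, dtype=float), dt=aif.dt, aif=aif
            )
        if "maps" in need:
            arrays = {}
            for name in MAP_NAMES:
                arr, _ = io.load_volume(d.maps / f"{pid}_{name}.nii.gz")
                arrays[name] = np.asarray(arr, dtype=float)
            valid, _ = io.load_volume(d.maps / f"{pid}_adc_valid.nii.gz")
            mtt_valid, _ = io.load_volume(d.maps / f"{pid}_mtt_valid.nii.gz")
            from .perfusion import ParameterMaps

            case.maps = ParameterMaps(
                adc=AdcMap(values=arrays["adc"], valid=valid.astype(bool)),
                cbf=arrays["cbf"],
                cbv=arrays["cbv"],
                mtt=arrays["mtt"],
                tmax=arrays["tmax"],
                mtt_valid=mtt_valid.astype(bool),
                rcbf=arrays["rcbf"],
                rcbv=arrays["rcbv"],
                dmtt=arrays["dmtt"],
                dtmax=arrays["dtmax"],
            )
        if "masks" in need:
            loaded = {}
            for name in MASK_NAMES:
                arr, _ = io.load_volume(d.masks / f"{pid}_{name}.nii.gz")
                loaded[name] = arr.astype(bool)
            dist, _ = io.load_volume(d.masks / f"{pid}_distance_to_core.nii.gz")
            case.masks = LesionMaskSet(
                brain=loaded["brain"],
                csf=loaded["csf"],
                core=loaded["core"],
                hypoperfusion=loaded["hypoperfusion"],
                tissue_at_risk=loaded["tissue_at_risk"],
                distance_to_core=np.asarray(dist, dtype=float),
                followup_lesion=case.followup_lesion,
            )
        if "features" in need:
            case.features = pd.read_csv(d.features / f"{pid}.csv")
        cases.append(case)
    return cases


def stage_maps(config: RunConfig) -> None:
    """ADC + deconvolution maps + contralateral normalization, from raw."""
    d = _dirs(config.output_dir)
    io.ensure_dir(d.maps)
    params = config.processing
    for case in _load_cases(config, need=("raw",)):
        pid = case.patient_id
        adc = compute_adc(case.b0, case.b1000, params.b_low, params.b_high)
        maps = compute_perfusion_maps(
            case.study, lam=params.svd_truncation, cbf_min=params.cbf_min, adc=adc
        )
        brain, csf = segment_brain_csf(adc, params.csf_threshold)
        normalize_maps(
            maps, brain, csf, case.phantom.hemisphere_labels, case.affected_hemisphere
        )
        sp = case.phantom.spacing
        for name in MAP_NAMES:
            arr = maps.adc.values if name == "adc" else getattr(maps, name)
            io.save_volume(arr, sp, d.maps / f"{pid}_{name}.nii.gz")
        io.save_volume(adc.valid, sp, d.maps / f"{pid}_adc_valid.nii.gz")
        io.save_volume(maps.mtt_valid, sp, d.maps / f"{pid}_mtt_valid.nii.gz")
    logger.info("maps: done")


def stage_segment(config: RunConfig) -> None:
    """Brain/CSF, core, hypoperfusion, tissue-at-risk, distance map."""
    d = _dirs(config.output_dir)
    io.ensure_dir(d.masks)
    params = config.processing
    for case in _load_cases(config, need=("maps",)):
        pid = case.patient_id
        adc = case.maps.adc
        brain, csf = segment_brain_csf(adc, params.csf_threshold)
        affected = case.phantom.hemisphere_labels == case.affected_hemisphere
        core = segment_core(
            adc, brain, adc_threshold=params.adc_threshold, affected_mask=affected
        )
        hypo = segment_hypoperfusion(case.maps.dtmax, brain, params.tmax_threshold_s)
        tar = tissue_at_risk(hypo, core)
        dist = distance_to_core(core, case.phantom.spacing)
        sp = case.phantom.spacing
        for name, arr in [
            ("brain", brain),
            ("csf", csf),
            ("core", core),
            ("hypoperfusion", hypo),
            ("tissue_at_risk", tar),
        ]:
            io.save_volume(arr, sp, d.masks / f"{pid}_{name}.nii.gz")
        io.save_volume(dist, sp, d.masks / f"{pid}_distance_to_core.nii.gz")
    logger.info("segment: done")


def stage_features(config: RunConfig) -> None:
    d = _dirs(config.output_dir)
    io.ensure_dir(d.features)
    for case in _load_cases(config, need=("maps", "masks")):
        table = assemble_features(case)
        table.to_csv(d.features / f"{case.patient_id}.csv", index=False)
    logger.info("features: done")


def stage_trial(config: RunConfig) -> None:
    d = _dirs(config.output_dir)
    io.ensure_dir(d.trial)
    cases = _load_cases(config, need=("masks", "features"))
    trial_cfg = dataclasses.replace(config.trial, seed=config.seed)
    predictions, failures = run_virtual_trial(cases, trial_cfg)
    io.predictions_to_frame(predictions).to_csv(
        d.trial / "volumes.csv", index=False
    )
    with open(d.trial / "failures.json", "w") as fh:
        json.dump(failures, fh)
    logger.info("trial: %d predictions, %d failures", len(predictions), len(failures))


def stage_stats(config: RunConfig) -> None:
    """Endpoint statistics from the cached per-patient volume table."""
    d = _dirs(config.output_dir)
    io.ensure_dir(d.stats)
    frame = pd.read_csv(d.trial / "volumes.csv")
    cases = _load_cases(config, need=("masks",))
    predictions = [
        VirtualPrediction(
            patient_id=row["patient_id"],
            arm=row["arm"],
            vol_theophylline_ml=float(row["vol_theophylline_ml"]),
            vol_placebo_ml=float(row["vol_placebo_ml"]),
            vol_true_ml=float(row["vol_true_ml"]),
            dice=float(row["dice"]),
            dice_degenerate=bool(row["dice_degenerate"]),
        )
        for _, row in frame.iterrows()
    ]
    present = {p.patient_id for p in predictions}
    result = compute_trial_statistics(
        predictions, [c for c in cases if c.patient_id in present]
    )
    with open(d.stats / "report.json", "w") as fh:
        json.dump(result.report_dict(), fh, indent=2, sort_keys=True)
    with open(d.stats / "report.txt", "w") as fh:
        fh.write(result.report_text())
    logger.info("stats: report written to %s", d.stats)


STAGES = {
    "generate": stage_generate,
    "maps": stage_maps,
    "segment": stage_segment,
    "features": stage_features,
    "trial": stage_trial,
    "stats": stage_stats,
}


def _write_manifest(config: RunConfig) -> None:
    import sklearn
    import scipy

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    with open(Path(config.output_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig, stages=None) -> None:
    """Run the requested stages (default: all) in order, with a manifest."""
    io.ensure_dir(config.output_dir)
    _write_manifest(config)
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        logger.info("running stage %s", name)
        try:
            STAGES[name](config)
        except Exception:
            logger.error("stage %s failed; partial outputs retained", name)
            raise
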