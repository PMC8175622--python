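"""Arm-specific random-forest outcome models and the virtual trial loop.

Two 100-tree random-forest classifiers are trained, one per treatment arm,
on the aggregated stratified under-sampled voxel rows of that arm.  For
each patient the own-arm model is retrained with that patient excluded
(leave-one-out) while the opposite-arm model — which can never contain the
patient — is trained once on its full arm.  Both models then predict the
patient's lesion, yielding a paired pair of virtual volumes (theophylline
and placebo) per patient, plus the Dice overlap of the actual-arm
prediction with the true follow-up lesion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import _seeds
from .features import FEATURE_COLUMNS, SampleInfo, assemble_features, stratified_undersample
from .segmentation import volume_ml
from .stats import dice

logger = logging.getLogger(__name__)

__all__ = [
    "ArmModel",
    "VirtualPrediction",
    "TrialConfig",
    "prepare_training_rows",
    "train_arm_model",
    "predict_lesion",
    "run_virtual_trial",
]

ARMS = ("theophylline", "placebo")


@dataclass
class ArmModel:
    arm: str
    classifier: RandomForestClassifier
    training_patient_ids: tuple[str, ...]
    n_trees: int
    seed: int


@dataclass
class VirtualPrediction:
    patient_id: str
    arm: str
    vol_theophylline_ml: float
    vol_placebo_ml: float
    vol_true_ml: float
    dice: float
    dice_degenerate: bool = False
    mask_theophylline: np.ndarray | None = None
    mask_placebo: np.ndarray | None = None


@dataclass
class TrialConfig:
    n_trees: int = 100
    probability_threshold: float = 0.5
    seed: int = 0
    store_masks: bool = False


def prepare_training_rows(
    cases, master_seed: int
) -> tuple[dict[str, pd.DataFrame], list[SampleInfo]]:
    """Per-patient stratified under-sampled contributions (computed once).

    Sampling seeds derive from the master seed and the patient's position
    in the cohort, never from the table contents, so one patient's data
    cannot perturb another's sample.
    """
    rows: dict[str, pd.DataFrame] = {}
    infos: list[SampleInfo] = []
    for i, case in enumerate(cases):
        if case.features is None:
            case.features = assemble_features(case)
        sampled, info = stratified_undersample(
            case.features, seed=_seeds.int_seed(master_seed, _seeds.SAMPLING, i)
        )
        rows[case.patient_id] = sampled
        infos.append(info)
        if info.n_lesion == 0:
            logger.info("patient %s has no lesion voxels; contributes no rows",
                        case.patient_id)
        elif info.imbalanced:
            logger.info("patient %s exhausted non-lesion pool (%d lesion / %d non)",
                        case.patient_id, info.n_lesion, info.n_nonlesion)
    return rows, infos


def train_arm_model(
    training_rows: dict[str, pd.DataFrame],
    arm_of: dict[str, str],
    arm: str,
    exclude_patient_id: str | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> ArmModel:
    """Fit the random forest for one arm, optionally excluding one patient.

    Hyperparameters beyond the tree count stay at library defaults.
    """
    ids = tuple(
        pid
        for pid, a in arm_of.items()
        if a == arm and pid != exclude_patient_id and len(training_rows[pid]) > 0
    )
    if len(ids) < 1:
        raise ValueError(
            f"arm {arm!r} has no contributing patients after exclusion"
        )
    data = pd.concat([training_rows[pid] for pid in ids], ignore_index=True)
    if data.empty:
        raise ValueError(f"empty training set for arm {arm!r}")
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    clf.fit(data[FEATURE_COLUMNS].to_numpy(), data["label"].to_numpy())
    return ArmModel(
        arm=arm,
        classifier=clf,
        training_patient_ids=ids,
        n_trees=n_trees,
        seed=seed,
    )


def _positive_proba(clf: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(x)
    classes = list(clf.classes_)
    if 1 not in classes:
        return np.zeros(len(x))
    return proba[:, classes.index(1)]


def predict_lesion(
    model: ArmModel,
    case,
    probability_threshold: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Predicted lesion mask (forest probability strictly > threshold) + volume."""
    table = case.features
    if table is None:
        raise ValueError("case features not assembled")
    proba = _positive_proba(
        model.classifier, table[FEATURE_COLUMNS].to_numpy()
    )
    mask = np.zeros(case.phantom.shape, dtype=bool)
    hit = table["voxel_index"].to_numpy()[proba > probability_threshold]
    mask.ravel()[hit] = True
    return mask, volume_ml(mask, case.phantom.spacing)


def run_virtual_trial(
    cases, config: TrialConfig = TrialConfig()
) -> tuple[list[VirtualPrediction], list[str]]:
    """Leave-one-out virtual trial: two predicted volumes per patient.

    Returns the per-patient predictions and the ids of patients whose
    own-arm training failed (the cohort continues without them).
    """
    rows, _ = prepare_training_rows(cases, config.seed)
    arm_of = {c.patient_id: c.record.arm for c in cases}

    full_models = {
        arm: train_arm_model(
            rows,
            arm_of,
            arm,
            exclude_patient_id=None,
            n_trees=config.n_trees,
            seed=_seeds.int_seed(config.seed, _seeds.FOREST, a_idx, -1 % (2**16)),
        )
        for a_idx, arm in enumerate(ARMS)
    }

    predictions: list[VirtualPrediction] = []
    failures: list[str] = []
    for i, case in enumerate(cases):
        own_arm = case.record.arm
        other_arm = ARMS[1 - ARMS.index(own_arm)]
        try:
            own_model = train_arm_model(
                rows,
                arm_of,
                own_arm,
                exclude_patient_id=case.patient_id,
                n_trees=config.n_trees,
                seed=_seeds.int_seed(config.seed, _seeds.FOREST, ARMS.index(own_arm), i),
            )
        except ValueError as exc:
            logger.warning("patient %s failed: %s", case.patient_id, exc)
            failures.append(case.patient_id)
            continue

        mask_own, vol_own = predict_lesion(
            own_model, case, config.probability_threshold
        )
        mask_other, vol_other = predict_lesion(
            full_models[other_arm], case, config.probability_threshold
        )
        if own_arm == "theophylline":
            vol_theo, vol_plac = vol_own, vol_other
            mask_theo, mask_plac = mask_own, mask_other
        else:
            vol_theo, vol_plac = vol_other, vol_own
            mask_theo, mask_plac = mask_other, mask_own

        truth = case.followup_lesion
        d, degenerate = dice(mask_own, truth)
        predictions.append(
            VirtualPrediction(
                patient_id=case.patient_id,
                arm=own_arm,
                vol_theophylline_ml=vol_theo,
                vol_placebo_ml=vol_plac,
                vol_true_ml=volume_ml(truth, case.phantom.spacing),
                dice=d,
                dice_degenerate=degenerate,
                mask_theophylline=mask_theo if config.store_masks else None,
                mask_placebo=mask_plac if config.store_masks else None,
            )
        )
    return predictions, failures
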