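"""Endpoint statistics for the virtual treatment comparison.

The primary endpoint is a paired t-test on the per-patient pair of
predicted follow-up lesion volumes (virtual theophylline vs. virtual
placebo).  Prediction accuracy is summarised by Dice coefficients against
the true lesion; agreement between the two predictions by a Bland-Altman
analysis with limits of agreement at mean +/- 2 SD of the differences
(2 SD, not 1.96, following the trial's own convention); exploratory
subgroup contrasts compare the per-patient volume difference between
groups with an unpaired t-test.  All tests are two-sided at alpha = 0.05
with no multiple-comparison correction, mirroring the trial analysis.

``calibrate_null`` is the simulation harness validating the design: under
tau = 0 the paired test's rejection rate over replicate synthetic cohorts
should sit near the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "AgreementSummary",
    "SubgroupContrast",
    "NullCalibration",
    "dice",
    "paired_volume_test",
    "bland_altman",
    "subgroup_tests",
    "rejection_rate",
    "calibrate_null",
]


# --------------------------------------------------------------------------
# Dice
# --------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, bool]:
    """Dice coefficient 2|A∩B|/(|A|+|B|) and a degenerate flag.

    Two empty masks overlap perfectly by convention: (1.0, True).
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(
            f"mask geometries differ: {mask_a.shape} vs {mask_b.shape}"
        )
    a = np.count_nonzero(mask_a)
    b = np.count_nonzero(mask_b)
    if a + b == 0:
        return 1.0, True
    inter = np.count_nonzero(mask_a & mask_b)
    return 2.0 * inter / (a + b), False


# --------------------------------------------------------------------------
# paired primary endpoint
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedComparison:
    n: int
    mean_theophylline: float
    sd_theophylline: float
    mean_placebo: float
    sd_placebo: float
    mean_difference: float
    t_statistic: float
    p_value: float
    degenerate: bool  # all differences identical (zero variance)


def paired_volume_test(pairs) -> PairedComparison:
    """Paired t-test on (theophylline, placebo) predicted volumes (ml).

    ``pairs`` is a sequence of 2-tuples or an (n, 2) array.  With zero
    variance of the differences the comparison is flagged degenerate and
    (t, p) are NaN rather than silently emitted.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("paired test needs at least 2 complete pairs")
    diffs = arr[:, 0] - arr[:, 1]
    degenerate = bool(np.ptp(diffs) == 0.0)
    if degenerate:
        t_stat, p = float("nan"), float("nan")
    else:
        t_stat, p = sps.ttest_rel(arr[:, 0], arr[:, 1])
    return PairedComparison(
        n=n,
        mean_theophylline=float(arr[:, 0].mean()),
        sd_theophylline=float(arr[:, 0].std(ddof=1)),
        mean_placebo=float(arr[:, 1].mean()),
        sd_placebo=float(arr[:, 1].std(ddof=1)),
        mean_difference=float(diffs.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# Bland-Altman agreement
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementSummary:
    differences: np.ndarray
    averages: np.ndarray
    mean_difference: float
    sd_difference: float
    lower_limit: float  # mean - 2 SD
    upper_limit: float  # mean + 2 SD


def bland_altman(pairs) -> AgreementSummary:
    """Differences vs. averages of the two predictions, limits mean +/- 2 SD."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need an (n>=2, 2) array of prediction pairs")
    diffs = arr[:, 0] - arr[:, 1]
    avgs = arr.mean(axis=1)
    mean_d = float(diffs.mean())
    sd_d = float(diffs.std(ddof=1))
    return AgreementSummary(
        differences=diffs,
        averages=avgs,
        mean_difference=mean_d,
        sd_difference=sd_d,
        lower_limit=mean_d - 2.0 * sd_d,
        upper_limit=mean_d + 2.0 * sd_d,
    )


# --------------------------------------------------------------------------
# subgroup contrasts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SubgroupContrast:
    name: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    t_statistic: float
    p_value: float
    flagged: bool  # a group had < 2 members; test not computed


def _contrast(name: str, diffs: np.ndarray, flags: np.ndarray, welch: bool) -> SubgroupContrast:
    g_in = diffs[flags]
    g_out = diffs[~flags]
    if len(g_in) < 2 or len(g_out) < 2:
        return SubgroupContrast(
            name, len(g_in), len(g_out),
            float(g_in.mean()) if len(g_in) else float("nan"),
            float(g_out.mean()) if len(g_out) else float("nan"),
            float("nan"), float("nan"), True,
        )
    t_stat, p = sps.ttest_ind(g_in, g_out, equal_var=not welch)
    return SubgroupContrast(
        name, len(g_in), len(g_out),
        float(g_in.mean()), float(g_out.mean()),
        float(t_stat), float(p), False,
    )


def subgroup_tests(predictions, cases, welch: bool = False) -> list[SubgroupContrast]:
    """The four exploratory contrasts on the per-patient volume difference.

    Groups: tissue-at-risk present at baseline, cortical vs. lacunar
    stroke, large vessel occlusion at baseline, recanalization at
    follow-up.  Student's unpaired t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    by_id = {c.patient_id: c for c in cases}
    diffs = np.array(
        [p.vol_theophylline_ml - p.vol_placebo_ml for p in predictions]
    )

    def flag(fn):
        return np.array([bool(fn(by_id[p.patient_id])) for p in predictions])

    tar = flag(
        lambda c: c.masks is not None and bool(c.masks.tissue_at_risk.any())
    )
    cortical = flag(lambda c: c.record.stroke_type == "cortical")
    lvo = flag(lambda c: c.record.large_vessel_occlusion)
    recan = flag(lambda c: c.record.recanalized)

    return [
        _contrast("tissue_at_risk_present", diffs, tar, welch),
        _contrast("cortical_vs_lacunar", diffs, cortical, welch),
        _contrast("large_vessel_occlusion", diffs, lvo, welch),
        _contrast("recanalization", diffs, recan, welch),
    ]


# --------------------------------------------------------------------------
# null / power calibration harness
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NullCalibration:
    n_replicates: int
    n_rejections: int
    rejection_rate: float
    ci_low: float
    ci_high: float
    alpha: float
    p_values: tuple[float, ...]
    mean_differences: tuple[float, ...]  # per-replicate mean (theo - placebo)
    mean_volume_difference: float


def rejection_rate(p_values, alpha: float = 0.05) -> float:
    """Fraction of replicates with p < alpha (strict)."""
    p = np.asarray(p_values, dtype=float)
    return float(np.mean(p < alpha))


def calibrate_null(
    cohort_config,
    n_replicates: int = 200,
    alpha: float = 0.05,
    master_seed: int = 0,
    trial_config=None,
) -> NullCalibration:
    """Replicate-cohort rejection rate of the paired test, with exact CI.

    Generates ``n_replicates`` independent cohorts from ``cohort_config``
    (typically with ``fate.tau = 0`` for the type-I-error check), runs the
    full analysis chain and paired test on each, and reports the fraction
    rejected at ``alpha`` with a Clopper-Pearson binomial CI.
    """
    from . import _seeds
    from .pipeline import simulate_virtual_trial  # lazy: avoids module cycle

    p_values = []
    mean_diffs = []
    for r in range(n_replicates):
        seed = _seeds.int_seed(master_seed, _seeds.REPLICATE, r)
        result = simulate_virtual_trial(
            cohort_config, seed=seed, trial_config=trial_config
        )
        p_values.append(result.paired.p_value)
        mean_diffs.append(result.paired.mean_difference)

    rejections = int(np.sum(np.asarray(p_values) < alpha))
    ci = sps.binomtest(rejections, n_replicates).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return NullCalibration(
        n_replicates=n_replicates,
        n_rejections=rejections,
        rejection_rate=rejections / n_replicates,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        alpha=alpha,
        p_values=tuple(float(p) for p in p_values),
        mean_differences=tuple(float(d) for d in mean_diffs),
        mean_volume_difference=float(np.mean(mean_diffs)),
    )
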