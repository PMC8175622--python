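"""Generator truth: nesting, forward-model oracles, fate mechanism, cohort."""

import numpy as np
import pytest

from virtualstroke.perfusion import compute_adc
from virtualstroke.phantom import LEFT, generate_phantom
from virtualstroke.segmentation import volume_ml
from virtualstroke.synthetic import (
    KAPPA,
    AifSpec,
    CohortConfig,
    LesionSpec,
    TissueFateParams,
    adc_truth_field,
    assign_tissue_fate,
    generate_cohort,
    generate_patient,
    generate_truth,
    simulate_hemodynamics,
    synthesize_dwi,
    synthesize_perfusion_series,
)


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom((24, 24, 16), (3.0, 3.0, 4.0), seed=1)


@pytest.fixture(scope="module")
def lesion(phantom):
    return LesionSpec(
        centre_mm=(-14.0, 0.0, 0.0),
        hemisphere=LEFT,
        core_radius_mm=8.0,
        hypo_radius_mm=14.0,
    )


@pytest.fixture(scope="module")
def gt(phantom, lesion):
    return simulate_hemodynamics(phantom, lesion, seed=0)


class TestHemodynamics:
    def test_core_nested_in_hypoperfusion(self, gt):
        assert gt.true_core.any()
        assert not (gt.true_core & ~gt.true_hypoperfusion).any()

    def test_normal_tissue_levels(self, phantom, gt):
        normal = phantom.brain_mask & ~gt.true_hypoperfusion
        assert np.allclose(gt.true_cbf[normal], 60.0, rtol=0.2)
        assert np.allclose(gt.true_mtt[normal], 4.0, rtol=0.2)
        assert (gt.true_delay[normal] == 0).all()
        assert (gt.true_cbf[phantom.brain_mask] > 0).all()
        assert (gt.true_delay >= 0).all()

    def test_zero_core_radius_gives_empty_core(self, phantom):
        spec = LesionSpec(
            centre_mm=(-14.0, 0.0, 0.0),
            hemisphere=LEFT,
            core_radius_mm=0.0,
            hypo_radius_mm=12.0,
        )
        gt = simulate_hemodynamics(phantom, spec, seed=0)
        assert not gt.true_core.any()
        assert gt.true_hypoperfusion.any()

    def test_masks_independent_of_seed(self, phantom, lesion):
        a = simulate_hemodynamics(phantom, lesion, seed=1)
        b = simulate_hemodynamics(phantom, lesion, seed=2)
        assert np.array_equal(a.true_core, b.true_core)
        assert np.array_equal(a.true_hypoperfusion, b.true_hypoperfusion)

    def test_centre_outside_brain_rejected(self, phantom):
        spec = LesionSpec(
            centre_mm=(200.0, 0.0, 0.0),
            hemisphere=LEFT,
            core_radius_mm=5.0,
            hypo_radius_mm=8.0,
        )
        with pytest.raises(ValueError, match="outside"):
            simulate_hemodynamics(phantom, spec, seed=0)


class TestPerfusionForwardModel:
    def test_zero_cbf_voxel_yields_zero_curve(self, phantom, gt):
        study = synthesize_perfusion_series(gt, phantom, noise_sd=0.0)
        outside = ~(phantom.brain_mask | phantom.csf_mask)
        assert np.all(study.data[outside] == 0.0)

    def test_matches_direct_convolution_oracle(self, phantom, gt):
        """Noise-free curves equal an independent O(N^2) convolution sum."""
        study = synthesize_perfusion_series(gt, phantom, noise_sd=0.0)
        aif = study.aif
        n = study.n_timepoints
        ix = np.argwhere(gt.true_core)[0]
        jx = np.argwhere(phantom.brain_mask & ~gt.true_hypoperfusion)[0]
        for vox in (tuple(ix), tuple(jx)):
            cbf = gt.true_cbf[vox]
            mtt = gt.true_mtt[vox]
            delay = gt.true_delay[vox]
            t = aif.times
            r = np.where(t >= delay, np.exp(-np.maximum(t - delay, 0) / mtt), 0.0)
            r *= mtt / (r.sum() * study.dt)  # discrete area = MTT
            expected = np.zeros(n)
            for i in range(n):  # brute-force convolution sum
                for j in range(i + 1):
                    expected[i] += aif.values[j] * r[i - j]
            expected *= study.dt * cbf / KAPPA
            assert np.allclose(study.data[vox], expected, atol=1e-12)

    def test_central_volume_identity(self, phantom, gt):
        """sum(C) dt / sum(AIF) dt = CBF * MTT / KAPPA for untruncated curves."""
        study = synthesize_perfusion_series(
            gt, phantom, noise_sd=0.0, n_timepoints=56
        )
        brain = phantom.brain_mask
        areas = study.data[brain].sum(axis=1) * study.dt
        expected = gt.true_cbf[brain] * gt.true_mtt[brain] / KAPPA * study.aif.area
        assert np.allclose(areas, expected, rtol=0.02)

    def test_truncated_series_rejected(self, phantom, gt):
        with pytest.raises(ValueError, match="truncat"):
            synthesize_perfusion_series(gt, phantom, n_timepoints=16)


class TestDwi:
    def test_noise_free_adc_inversion(self, phantom, gt):
        b0, b1000 = synthesize_dwi(gt, phantom, noise_sd=0.0)
        recovered = compute_adc(b0, b1000)
        truth = adc_truth_field(gt, phantom)
        head = phantom.brain_mask | phantom.csf_mask
        assert np.allclose(recovered.values[head], truth[head], atol=1e-15)

    def test_core_below_and_csf_above_thresholds(self, phantom, gt):
        b0, b1000 = synthesize_dwi(gt, phantom, noise_sd=2.0, seed=3)
        recovered = compute_adc(b0, b1000)
        assert (recovered.values[gt.true_core] < 550e-6).all()
        brain_vals = recovered.values[phantom.brain_mask & ~gt.true_core]
        assert (recovered.values[phantom.csf_mask] > brain_vals.max()).all()


class TestTissueFate:
    def _record(self, arm, recan=0):
        from virtualstroke.synthetic import ClinicalRecord

        return ClinicalRecord(
            patient_id="T000",
            age=70,
            sex=0,
            nihss=8,
            onset_to_drug_minutes=120,
            arm=arm,
            recanalized=recan,
            large_vessel_occlusion=1,
            stroke_type="cortical",
        )

    def test_null_tau_makes_arm_label_irrelevant(self, phantom, gt):
        params = TissueFateParams(tau=0.0)
        a = assign_tissue_fate(gt, phantom, self._record("theophylline"), params, seed=9)
        b = assign_tissue_fate(gt, phantom, self._record("placebo"), params, seed=9)
        assert np.array_equal(a, b)

    def test_lesion_nested_between_core_and_brain(self, phantom, gt):
        lesion = assign_tissue_fate(
            gt, phantom, self._record("placebo"), TissueFateParams(), seed=4
        )
        assert not (gt.true_core & ~lesion).any()
        assert not (lesion & ~phantom.brain_mask).any()

    def test_limiting_case_lesion_equals_core(self, phantom, gt):
        params = TissueFateParams(
            intercept=-50.0, b_adc=0.0, b_severity=0.0, b_distance=0.0, b_recan=0.0
        )
        lesion = assign_tissue_fate(
            gt, phantom, self._record("placebo"), params, seed=4
        )
        assert np.array_equal(lesion, gt.true_core)

    def test_protection_shrinks_mean_lesion_volume(self, phantom, gt):
        """Monte-Carlo: strongly protective tau reduces expected volume."""
        rec = self._record("theophylline")
        vols = {}
        for tau in (0.0, 3.0):
            params = TissueFateParams(tau=tau)
            vols[tau] = np.mean(
                [
                    volume_ml(
                        assign_tissue_fate(gt, phantom, rec, params, seed=s),
                        phantom.spacing,
                    )
                    for s in range(100)
                ]
            )
        assert vols[3.0] < vols[0.0]


class TestCohort:
    def test_default_arm_sizes_give_52_cases(self):
        cfg = CohortConfig(shape=(16, 16, 16), spacing=(4.0, 4.0, 4.0))
        assert cfg.n_theophylline == 27 and cfg.n_placebo == 25
        cases = generate_cohort(cfg, seed=0)
        assert len(cases) == 52
        arms = [c.record.arm for c in cases]
        assert arms.count("theophylline") == 27 and arms.count("placebo") == 25

    def test_same_master_seed_reproduces_cohort(self):
        cfg = CohortConfig(
            n_theophylline=2, n_placebo=2, shape=(16, 16, 16), spacing=(4, 4, 4)
        )
        a = generate_cohort(cfg, seed=11)
        b = generate_cohort(cfg, seed=11)
        for ca, cb in zip(a, b):
            assert ca.record == cb.record
            assert np.array_equal(ca.followup_lesion, cb.followup_lesion)
            assert np.array_equal(ca.b0, cb.b0)
            assert np.array_equal(ca.study.data, cb.study.data)

    def test_patient_regenerable_in_isolation(self):
        cfg = CohortConfig(
            n_theophylline=2, n_placebo=2, shape=(16, 16, 16), spacing=(4, 4, 4)
        )
        cohort = generate_cohort(cfg, seed=11)
        solo = generate_patient(cfg, 11, 2, "placebo")
        assert solo.record == cohort[2].record
        assert np.array_equal(solo.followup_lesion, cohort[2].followup_lesion)

    def test_core_volume_distribution_matches_trial_scale(self):
        """Mean core ~4-5 ml with SD > mean over >= 200 patients."""
        cfg = CohortConfig()  # default 48x48x24 geometry
        vols = []
        for i in range(220):
            truth = generate_truth(cfg, 321, i, "placebo" if i % 2 else "theophylline")
            vols.append(volume_ml(truth.gt.true_core, truth.phantom.spacing))
        vols = np.asarray(vols)
        assert 3.0 < vols.mean() < 6.0
        assert vols.std() > vols.mean()

    def test_clinical_invariants(self):
        cfg = CohortConfig(
            n_theophylline=8, n_placebo=8, shape=(16, 16, 16), spacing=(4, 4, 4)
        )
        for c in generate_cohort(cfg, seed=2):
            r = c.record
            assert r.nihss >= 4
            assert r.recanalized <= r.large_vessel_occlusion
            assert not (c.followup_lesion & ~c.phantom.brain_mask).any()
            assert not (c.gt.true_core & ~c.followup_lesion).any()

    def test_bad_arm_sizes_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_theophylline=1, n_placebo=5)
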