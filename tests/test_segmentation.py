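"""Segmentation thresholds, volume growing, distance transform oracle."""

import numpy as np
import pytest

from virtualstroke.perfusion import AdcMap
from virtualstroke.segmentation import (
    distance_to_core,
    segment_brain_csf,
    segment_core,
    segment_hypoperfusion,
    sentinel_distance_mm,
    tissue_at_risk,
    volume_ml,
)


def _adc(values):
    values = np.asarray(values, dtype=float)
    return AdcMap(values=values, valid=np.isfinite(values) & (values > 0))


class TestBrainCsf:
    def test_uniform_tissue_adc_gives_empty_csf(self):
        brain, csf = segment_brain_csf(_adc(np.full((4, 4, 2), 900e-6)))
        assert not csf.any() and brain.all()

    def test_high_adc_voxel_is_csf_not_brain(self):
        vals = np.full((4, 4, 2), 900e-6)
        vals[1, 1, 0] = 2500e-6
        brain, csf = segment_brain_csf(_adc(vals))
        assert csf[1, 1, 0] and not brain[1, 1, 0]

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            segment_brain_csf(_adc(np.zeros((2, 2, 2))))


class TestCore:
    def test_empty_core_when_nothing_below_threshold(self):
        vals = np.full((4, 4, 4), 900e-6)
        brain = np.ones((4, 4, 4), bool)
        core = segment_core(_adc(vals), brain)
        assert not core.any()

    def test_seeded_growth_selects_only_connected_blob(self):
        """Volume growing must match brute-force connected components."""
        vals = np.full((8, 8, 4), 900e-6)
        blob_a = [(1, 1, 1), (1, 2, 1), (2, 2, 2)]  # 26-connected chain
        blob_b = [(6, 6, 2), (6, 7, 2)]
        for v in blob_a + blob_b:
            vals[v] = 400e-6
        brain = np.ones(vals.shape, bool)
        core = segment_core(_adc(vals), brain, seeds=[blob_a[0]])
        expected = np.zeros(vals.shape, bool)
        for v in blob_a:
            expected[v] = True
        assert np.array_equal(core, expected)

    def test_threshold_boundary_is_strict(self):
        vals = np.full((4, 4, 4), 900e-6)
        vals[1, 1, 1] = 550e-6  # exactly at threshold: excluded
        vals[2, 2, 2] = 549e-6
        brain = np.ones(vals.shape, bool)
        core = segment_core(_adc(vals), brain)
        assert not core[1, 1, 1] and core[2, 2, 2]

    def test_bad_seed_rejected(self):
        vals = np.full((4, 4, 4), 900e-6)
        vals[1, 1, 1] = 400e-6
        brain = np.ones(vals.shape, bool)
        brain[0, 0, 0] = False
        with pytest.raises(ValueError, match="outside"):
            segment_core(_adc(vals), brain, seeds=[(0, 0, 0)])
        with pytest.raises(ValueError, match="threshold"):
            segment_core(_adc(vals), brain, seeds=[(3, 3, 3)])

    def test_lowering_threshold_never_enlarges_core(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(300e-6, 900e-6, size=(8, 8, 4))
        brain = np.ones(vals.shape, bool)
        seed = tuple(int(i) for i in np.unravel_index(np.argmin(vals), vals.shape))
        prev = None
        for thr in (700e-6, 600e-6, 500e-6, 400e-6):
            core = segment_core(_adc(vals), brain, seeds=[seed], adc_threshold=thr)
            if prev is not None:
                assert not (core & ~prev).any()
            prev = core


class TestHypoperfusion:
    def test_zero_dtmax_gives_empty_mask(self):
        brain = np.ones((3, 3, 2), bool)
        assert not segment_hypoperfusion(np.zeros((3, 3, 2)), brain).any()

    def test_threshold_boundary_is_strict(self):
        brain = np.ones((2, 2, 1), bool)
        dtmax = np.array([[[6.0], [6.5]], [[5.9], [np.nan]]])
        mask = segment_hypoperfusion(dtmax, brain)
        assert not mask[0, 0, 0] and mask[0, 1, 0]
        assert not mask[1, 0, 0] and not mask[1, 1, 0]

    def test_missing_map_rejected(self):
        with pytest.raises(ValueError, match="normaliz"):
            segment_hypoperfusion(None, np.ones((2, 2, 2), bool))

    def test_raising_threshold_never_enlarges_mask(self):
        rng = np.random.default_rng(1)
        dtmax = rng.uniform(0, 12, size=(6, 6, 3))
        brain = np.ones(dtmax.shape, bool)
        prev = None
        for thr in (2.0, 4.0, 6.0, 8.0):
            mask = segment_hypoperfusion(dtmax, brain, thr)
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask


class TestTissueAtRisk:
    def test_counting(self):
        hypo = np.zeros((10, 10, 1), bool)
        hypo.ravel()[:100] = True
        core = np.zeros_like(hypo)
        core.ravel()[:30] = True
        assert tissue_at_risk(hypo, core).sum() == 70

    def test_core_superset_gives_empty(self):
        hypo = np.zeros((4, 4, 1), bool)
        hypo[1, 1, 0] = True
        core = np.ones_like(hypo)
        assert not tissue_at_risk(hypo, core).any()

    def test_empty_core_returns_hypoperfusion(self):
        hypo = np.random.default_rng(2).random((4, 4, 2)) > 0.5
        core = np.zeros_like(hypo)
        assert np.array_equal(tissue_at_risk(hypo, core), hypo)


def _bruteforce_distance(core, spacing):
    out = np.zeros(core.shape)
    pts = np.argwhere(core) * np.asarray(spacing)
    for idx in np.ndindex(core.shape):
        p = np.asarray(idx) * np.asarray(spacing)
        out[idx] = np.sqrt(((pts - p) ** 2).sum(axis=1)).min()
    return out


class TestDistance:
    def test_core_voxel_zero_and_face_neighbour_spacing(self):
        core = np.zeros((4, 4, 4), bool)
        core[1, 1, 1] = True
        dist = distance_to_core(core, (2.0, 2.0, 4.0))
        assert dist[1, 1, 1] == 0.0
        assert dist[1, 1, 2] == pytest.approx(4.0)
        assert dist[2, 1, 1] == pytest.approx(2.0)

    def test_matches_bruteforce_oracle_on_random_masks(self):
        rng = np.random.default_rng(3)
        spacing = (1.0, 2.0, 3.5)
        for _ in range(5):
            core = rng.random((12, 12, 6)) > 0.97
            if not core.any():
                continue
            dist = distance_to_core(core, spacing)
            assert np.allclose(dist, _bruteforce_distance(core, spacing), atol=1e-9)

    def test_empty_core_sentinel(self):
        core = np.zeros((5, 5, 5), bool)
        dist = distance_to_core(core, (2.0, 2.0, 2.0))
        assert np.all(dist == sentinel_distance_mm(core.shape, (2.0, 2.0, 2.0)))

    def test_triangle_inequality_against_single_core_voxel(self):
        core = np.zeros((6, 6, 3), bool)
        core[0, 0, 0] = True
        core[5, 5, 2] = True
        spacing = (2.0, 2.0, 4.0)
        dist = distance_to_core(core, spacing)
        # distance to nearest core <= distance to the specific voxel (0,0,0)
        for idx in [(3, 4, 1), (5, 0, 2), (2, 2, 0)]:
            direct = np.sqrt(sum((i * s) ** 2 for i, s in zip(idx, spacing)))
            assert dist[idx] <= direct + 1e-9


def test_noise_free_shell_recovered_through_full_perfusion_chain(noisefree_case):
    """An 8 s-delay shell must be >= 95% covered by the recovered
    hypoperfusion mask when DWI and perfusion are noise-free."""
    from virtualstroke.pipeline import process_case

    case = process_case(noisefree_case, drop_raw=False)
    shell = case.gt.true_hypoperfusion & ~case.gt.true_core
    assert shell.any()
    covered = (case.masks.hypoperfusion & shell).sum() / shell.sum()
    assert covered >= 0.95


def test_volume_bookkeeping():
    mask = np.zeros((10, 10, 10), bool)
    mask.ravel()[:1000] = True
    assert volume_ml(mask, (1.0, 1.0, 1.0)) == pytest.approx(1.0)
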