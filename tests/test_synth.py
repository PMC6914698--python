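"""Generator: determinism, lesion-field structure, calibration, round trips."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from wmhfreq.dti import fa_from_eigenvalues, fa_map, fit_tensor_lls
from wmhfreq.synth import (BACKGROUND, CSF, GM, WM, CohortConfig,
                           LesionProbabilityField, eigenvalues_for_fa_md,
                           fibonacci_directions, generate_cohorts,
                           make_dwi, make_flair_image,
                           make_lesion_probability_field,
                           make_microstructure_field, make_phantom_anatomy,
                           sample_lesion_mask, simulate_cohort)


class TestPhantomAnatomy:
    def test_deterministic_given_shape_and_seed(self):
        a = make_phantom_anatomy((48, 48, 48), seed=7)
        b = make_phantom_anatomy((48, 48, 48), seed=7)
        np.testing.assert_array_equal(a.label_grid, b.label_grid)
        c = make_phantom_anatomy((48, 48, 48), seed=8)
        assert np.any(a.label_grid != c.label_grid)

    def test_label_census_all_four_labels(self):
        a = make_phantom_anatomy((48, 48, 48), seed=7)
        # exhaustive voxel scan
        counts = {lab: int(np.sum(a.label_grid == lab))
                  for lab in (BACKGROUND, CSF, WM, GM)}
        assert all(v > 0 for v in counts.values())
        assert sum(counts.values()) == 48 ** 3
        assert counts[WM] > counts[CSF]

    def test_ventricle_interior_to_white_matter(self, anatomy16):
        from scipy import ndimage
        vent = anatomy16.ventricle
        nlab, _ = ndimage.label(vent)
        assert nlab.max() == 1  # simply connected
        # every face-neighbor of the ventricle is ventricle or WM
        dil = ndimage.binary_dilation(vent)
        assert np.all(np.isin(anatomy16.label_grid[dil & ~vent], [WM]))

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_phantom_anatomy((8, 16, 16))


class TestLesionProbabilityField:
    def test_peak_normalization_and_bounds(self, anatomy16):
        f = make_lesion_probability_field(anatomy16, max_p=0.22)
        assert f.p.max() == pytest.approx(0.22, abs=1e-12)
        assert f.p.min() == 0.0
        assert np.all(f.p[~anatomy16.brain] == 0)

    def test_invalid_max_p_rejected(self, anatomy16):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                make_lesion_probability_field(anatomy16, max_p=bad)

    def test_monotone_decay_with_ventricle_distance(self, anatomy16):
        """At fixed anterior coordinate, p never increases with distance,
        where distance is recomputed by brute force over ventricle voxels."""
        f = make_lesion_probability_field(anatomy16, max_p=0.2)
        vent_xyz = np.argwhere(anatomy16.ventricle) * 2.0  # 2 mm voxels
        wm_idx = np.argwhere(anatomy16.white_matter)
        d = cdist(wm_idx * 2.0, vent_xyz).min(axis=1)
        p = f.p[tuple(wm_idx.T)]
        for y in np.unique(wm_idx[:, 1]):
            sel = wm_idx[:, 1] == y
            order = np.argsort(d[sel])
            diffs = np.diff(p[sel][order])
            assert np.all(diffs <= 1e-12)

    def test_anterior_weight_one_gives_mirror_symmetry(self, anatomy16):
        """Brute-force comparison of every voxel with its y-mirror."""
        f = make_lesion_probability_field(anatomy16, max_p=0.2, anterior_weight=1.0)
        np.testing.assert_allclose(f.p, f.p[:, ::-1, :], atol=1e-12)

    def test_anterior_exceeds_mirrored_posterior(self, anatomy16):
        f = make_lesion_probability_field(anatomy16, max_p=0.2, anterior_weight=2.0)
        mirrored = f.p[:, ::-1, :]
        both = (f.p > 0) & (mirrored > 0)
        ny = anatomy16.shape[1]
        anterior = np.zeros_like(both)
        anterior[:, ny // 2:, :] = True
        sel = both & anterior
        assert np.all(f.p[sel] >= mirrored[sel] - 1e-12)
        assert np.any(f.p[sel] > mirrored[sel] + 1e-6)


class TestSampleLesionMask:
    def test_zero_probability_gives_empty_mask(self, anatomy16):
        f = LesionProbabilityField(p=np.zeros(anatomy16.shape), max_p=1.0,
                                   voxel_size_mm=(2, 2, 2))
        assert not sample_lesion_mask(f, 3.0, seed=1).any()

    def test_certain_voxel_always_positive(self):
        p = np.zeros((8, 8, 8))
        p[4, 4, 4] = 1.0
        f = LesionProbabilityField(p=p, max_p=1.0, voxel_size_mm=(2, 2, 2))
        for s in range(20):
            assert sample_lesion_mask(f, 3.0, seed=s)[4, 4, 4]

    def test_seeded_reproducibility(self, field16):
        a = sample_lesion_mask(field16, 3.0, seed=9)
        b = sample_lesion_mask(field16, 3.0, seed=9)
        np.testing.assert_array_equal(a, b)
        assert a.any()

    def test_marginal_rate_calibration_at_peak(self, field16):
        """2000 seeded draws: empirical rate at the peak voxel within +-0.02
        of max_p = 0.2 (binomial SE ~ 0.009)."""
        peak = np.unravel_index(np.argmax(field16.p), field16.p.shape)
        hits = sum(sample_lesion_mask(field16, 3.0, seed=s)[peak]
                   for s in range(2000))
        assert hits / 2000 == pytest.approx(0.2, abs=0.02)


class TestFlair:
    def test_noiseless_piecewise_constant(self, anatomy16):
        tm = {BACKGROUND: 0.0, CSF: 10.0, WM: 100.0, GM: 92.0}
        img = make_flair_image(anatomy16, np.zeros(anatomy16.shape, bool),
                               tm, 30.0, 0.0, seed=0)
        for lab, mean in tm.items():
            assert np.all(img[anatomy16.label_grid == lab] == mean)

    def test_single_lesion_voxel_contrast(self, anatomy16):
        tm = {BACKGROUND: 0.0, CSF: 10.0, WM: 100.0, GM: 92.0}
        les = np.zeros(anatomy16.shape, bool)
        vox = tuple(np.argwhere(anatomy16.white_matter)[0])
        les[vox] = True
        img = make_flair_image(anatomy16, les, tm, 30.0, 0.0, seed=0)
        assert img[vox] == 130.0

    def test_noisy_image_bitwise_reproducible(self, anatomy16):
        tm = {BACKGROUND: 0.0, CSF: 10.0, WM: 100.0, GM: 92.0}
        les = np.zeros(anatomy16.shape, bool)
        a = make_flair_image(anatomy16, les, tm, 30.0, 5.0, seed=42)
        b = make_flair_image(anatomy16, les, tm, 30.0, 5.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_negative_noise_rejected(self, anatomy16):
        with pytest.raises(ValueError):
            make_flair_image(anatomy16, np.zeros(anatomy16.shape, bool),
                             {BACKGROUND: 0, CSF: 1, WM: 2, GM: 3}, 1.0, -1.0, 0)


class TestEigenvaluesForFaMd:
    def test_isotropic(self):
        l1, l2, l3 = eigenvalues_for_fa_md(0.0, 0.8e-3)
        assert l1 == l2 == l3 == pytest.approx(0.8e-3, abs=1e-18)

    @pytest.mark.parametrize("fa", [0.0, 0.1, 0.3, 0.45, 0.7, 0.9, 0.99])
    def test_round_trip_contract(self, fa):
        l1, l2, l3 = eigenvalues_for_fa_md(fa, 0.8e-3)
        assert l1 >= l2 == l3 > 0
        assert (l1 + l2 + l3) / 3 == pytest.approx(0.8e-3, abs=1e-18)
        assert fa_from_eigenvalues(l1, l2, l3) == pytest.approx(fa, abs=1e-10)

    def test_against_numeric_root_find(self):
        """Independent oracle: solve the axially symmetric FA equation for the
        anisotropy parameter numerically and compare eigenvalues."""
        fa, md = 0.7, 0.8e-3

        def fa_of_alpha(a):
            lam = np.array([1 + 2 * a, 1 - a, 1 - a]) * md
            return fa_from_eigenvalues(*lam) - fa

        a_star = brentq(fa_of_alpha, 0.0, 0.999999, xtol=1e-15)
        l1, l2, _ = eigenvalues_for_fa_md(fa, md)
        assert l1 == pytest.approx(md * (1 + 2 * a_star), rel=1e-8)
        assert l2 == pytest.approx(md * (1 - a_star), rel=1e-8)

    def test_unreachable_fa_rejected(self):
        for bad in (1.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                eigenvalues_for_fa_md(bad, 1e-3)
        with pytest.raises(ValueError):
            eigenvalues_for_fa_md(0.5, 0.0)


class TestMakeDwi:
    def test_isotropic_voxel_has_identical_dw_signals(self, anatomy16, field16):
        micro = make_microstructure_field(anatomy16, field16, fa0=0.0, beta=0.0)
        ds = make_dwi(micro, anatomy16, 800.0, 8, s0=1000.0, snr=np.inf, seed=0)
        wm_vox = tuple(np.argwhere(anatomy16.white_matter)[0])
        dw = ds.signal[wm_vox][ds.bvals > 0]
        np.testing.assert_allclose(dw, dw[0], rtol=1e-12)

    def test_b0_equals_s0_noiseless(self, small_cohort):
        cfg = small_cohort.config
        ds = make_dwi(small_cohort.micro, small_cohort.anatomy, cfg.b_value,
                      8, s0=cfg.s0, snr=np.inf, seed=0, axes=small_cohort.axes)
        b0 = ds.signal[..., ds.bvals == 0][small_cohort.anatomy.brain]
        np.testing.assert_allclose(b0, cfg.s0, rtol=1e-12)

    def test_noiseless_round_trip_recovers_fa(self, small_cohort):
        """Generator -> log-linear fit -> FA equals the ground truth."""
        a = small_cohort.anatomy
        ds = make_dwi(small_cohort.micro, a, 800.0, 16, s0=1000.0,
                      snr=np.inf, seed=0, axes=small_cohort.axes)
        fa = fa_map(fit_tensor_lls(ds))
        err = np.abs(fa[a.brain] - small_cohort.micro.fa_true[a.brain])
        assert err.max() < 1e-8

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError):
            fibonacci_directions(5)


class TestCohort:
    def test_severity_mean_near_one(self):
        cfg = CohortConfig(n_old=400, n_young=2, shape=(16, 16, 16), seed=5)
        c = simulate_cohort(cfg)
        assert c.severities.mean() == pytest.approx(1.0, abs=0.08)

    def test_wm_fa_is_affine_in_lesion_probability(self, small_cohort):
        wm = small_cohort.anatomy.white_matter
        cfg = small_cohort.config
        expected = cfg.fa0 - cfg.beta * small_cohort.lesion_field.p[wm]
        np.testing.assert_allclose(small_cohort.micro.fa_true[wm], expected,
                                   atol=1e-12)

    def test_subject_data_deterministic(self, small_cohort):
        np.testing.assert_array_equal(small_cohort.old_lesion_mask(2),
                                      small_cohort.old_lesion_mask(2))
        a = small_cohort.old_dwi(1)
        b = small_cohort.old_dwi(1)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_cohort_marginal_rate_matches_field(self):
        """Severity-scaled per-subject masks still average to p at the peak
        voxel (800 subjects; binomial + severity SE ~ 0.015)."""
        cfg = CohortConfig(n_old=800, n_young=2, shape=(16, 16, 16), seed=11,
                           max_p=0.2)
        c = simulate_cohort(cfg)
        peak = np.unravel_index(np.argmax(c.lesion_field.p), cfg.shape)
        hits = sum(c.old_lesion_mask(i)[peak] for i in range(cfg.n_old))
        assert hits / cfg.n_old == pytest.approx(0.2, abs=0.045)


class TestGenerateCohorts(object):
    def test_manifest_counts_and_reproducibility(self, tmp_path):
        cfg = CohortConfig(n_old=3, n_young=2, shape=(16, 16, 16),
                           n_directions_old=8, n_directions_young=8, seed=2)
        m1 = generate_cohorts(cfg, tmp_path / "a")
        assert (m1["modality"] == "flair").sum() == 3
        assert (m1["modality"] == "dwi").sum() == 5
        assert (m1["modality"] == "lesion_mask").sum() == 3
        m2 = generate_cohorts(cfg, tmp_path / "b")
        for (_, r1), (_, r2) in zip(m1.iterrows(), m2.iterrows()):
            if r1["modality"] in ("bvals", "bvecs"):
                continue
            b1 = open(r1["path"], "rb").read()
            b2 = open(r2["path"], "rb").read()
            assert b1 == b2, f"payload differs for {r1['modality']}"

    def test_generated_dataset_passes_validation(self, tmp_path):
        from wmhfreq.pipeline import validate_inputs
        cfg = CohortConfig(n_old=2, n_young=2, shape=(16, 16, 16),
                           n_directions_old=8, n_directions_young=8, seed=2)
        generate_cohorts(cfg, tmp_path)
        assert validate_inputs(tmp_path / "manifest.tsv") == []
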