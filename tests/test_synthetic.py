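"""Synthetic cohort generator: determinism, HU statistics, fixtures."""

import numpy as np
import pytest

from fatph import (
    ConfigurationError,
    UsageError,
    fat_config,
    generate_cohort,
    generate_patch,
    make_fixture,
    mask_hu,
    nonfat_config,
)
from fatph.synthetic import GeneratorConfig, write_cohort


class TestGeneratePatch:
    def test_degenerate_noise_gives_constant_patch(self):
        cfg = fat_config(sd_hu=0.0, smoothing_sigma=0.0, mean_hu=-110.0)
        patch = generate_patch(cfg, 0, 0)
        assert patch.shape == (32, 32)
        np.testing.assert_array_equal(patch, -110.0)

    def test_same_config_and_seed_is_bit_identical(self):
        cfg = fat_config(seed=42)
        a = generate_patch(cfg, 3, 17)
        b = generate_patch(cfg, 3, 17)
        np.testing.assert_array_equal(a, b)

    def test_distinct_patches_differ(self):
        cfg = fat_config(seed=42)
        assert not np.array_equal(generate_patch(cfg, 0, 0), generate_patch(cfg, 0, 1))
        assert not np.array_equal(generate_patch(cfg, 0, 0), generate_patch(cfg, 1, 0))

    def test_fat_defaults_concentrate_in_adipose_window(self):
        # normal(-110, 25) puts ~99.8% of its mass in [-190, -30]
        patch = generate_patch(fat_config(seed=1), 0, 0)
        frac = mask_hu(patch).mean()
        assert frac >= 0.9

    def test_values_stay_in_valid_ct_range(self):
        cfg = nonfat_config(seed=5, sd_hu=2000.0)
        patch = generate_patch(cfg, 0, 0)
        assert patch.min() >= -1024.0 and patch.max() <= 3071.0

    def test_smoothing_preserves_marginal_sd(self):
        cfg = fat_config(patch_size=64)
        samples = np.concatenate(
            [generate_patch(cfg, 0, i).ravel() for i in range(20)]
        )
        assert np.std(samples) == pytest.approx(cfg.sd_hu, rel=0.05)

    @pytest.mark.parametrize(
        "bad",
        [
            {"mean_hu": float("nan")},
            {"sd_hu": -1.0},
            {"smoothing_sigma": float("inf")},
            {"patch_size": 3},
            {"n_subjects": 0},
        ],
    )
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ConfigurationError):
            generate_patch(fat_config(**bad), 0, 0)

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(group_label="muscle").validate()


class TestGenerateCohort:
    def test_default_counts(self):
        cf, cn = generate_cohort(
            fat_config(n_subjects=8, patches_per_subject=36, patch_size=8),
            nonfat_config(n_subjects=8, patches_per_subject=36, patch_size=8),
        )
        assert len(cf) == len(cn) == 288

    def test_single_patch_cohort(self):
        cf, cn = generate_cohort(
            fat_config(n_subjects=1, patches_per_subject=1),
            nonfat_config(n_subjects=1, patches_per_subject=1),
        )
        assert len(cf) == len(cn) == 1

    def test_subject_ids_disjoint_by_default(self):
        cf, cn = generate_cohort(fat_config(patch_size=4, patches_per_subject=1),
                                 nonfat_config(patch_size=4, patches_per_subject=1))
        assert not set(cf.subject_ids) & set(cn.subject_ids)

    def test_overlapping_subject_ids_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(
                fat_config(n_subjects=2, patches_per_subject=1, patch_size=4),
                nonfat_config(n_subjects=2, patches_per_subject=1, patch_size=4),
                subject_ids_fat=[0, 1],
                subject_ids_nonfat=[1, 2],
            )

    def test_identical_group_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(fat_config(), fat_config())

    def test_masked_pixel_count_higher_in_fat_group(self):
        # direct counting: fat mean sits mid-window, nonfat mean outside it
        cf, cn = generate_cohort(fat_config(seed=0), nonfat_config(seed=0))
        med_fat = np.median([mask_hu(p).sum() for _, _, p in cf.patches])
        med_non = np.median([mask_hu(p).sum() for _, _, p in cn.patches])
        assert med_fat > med_non

    def test_full_regeneration_is_bit_identical(self):
        kw = dict(n_subjects=2, patches_per_subject=3, patch_size=8)
        a, _ = generate_cohort(fat_config(seed=9, **kw), nonfat_config(seed=9, **kw))
        b, _ = generate_cohort(fat_config(seed=9, **kw), nonfat_config(seed=9, **kw))
        for (s1, p1, x1), (s2, p2, x2) in zip(a.patches, b.patches):
            assert (s1, p1) == (s2, p2)
            np.testing.assert_array_equal(x1, x2)


class TestFixtures:
    def test_circle_is_20_unit_radius_points(self):
        pts = make_fixture("circle")
        assert pts.shape == (20, 2)
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), 1.0)

    def test_annulus_mask_is_single_connected_ring(self):
        from scipy.ndimage import label

        img = make_fixture("annulus_image")
        m = mask_hu(img)
        n_fg = label(m)[1]
        n_bg = label(~m)[1]  # hole + outside
        assert (n_fg, n_bg) == (1, 2)  # beta0 = 1, beta1 = 1 by construction

    def test_two_clusters_geometry(self):
        pts = make_fixture("two_clusters")
        assert pts.shape == (10, 2)
        d = np.linalg.norm(pts[:5].mean(0) - pts[5:].mean(0))
        assert d == pytest.approx(10.0)

    def test_grid_is_unit_square_corners(self):
        pts = make_fixture("grid")
        assert sorted(map(tuple, pts)) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_unknown_fixture_raises(self):
        with pytest.raises(UsageError):
            make_fixture("torus")


def test_write_cohort_roundtrip(tmp_path):
    cohort, _ = generate_cohort(
        fat_config(seed=3, n_subjects=1, patches_per_subject=2, patch_size=6),
        nonfat_config(seed=3, n_subjects=1, patches_per_subject=2, patch_size=6),
    )
    manifest = write_cohort(cohort, tmp_path)
    lines = manifest.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["group", "subject", "patch", "path", "seed"]
    assert len(lines) == 3
    path = tmp_path / lines[1].split("\t")[3]
    back = np.loadtxt(path, delimiter=",")
    np.testing.assert_allclose(back, cohort.patches[0][2], rtol=1e-9)
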