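"""Feature engine: discretization, first-order, shape, texture, filters."""

import numpy as np
import pytest

from rectomics.features import (
    DIRECTIONS,
    ExtractionConfig,
    N_FEATURES_PER_SEGMENT,
    discretize,
    extract_all,
    feature_names,
    filter_bank,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    glszm_features,
    glszm_matrix,
    glrlm_features,
    gldm_features,
    ngtdm_features,
    shape_features,
    texture_features,
)
from rectomics.features.texture import present_levels
from rectomics.volumes import resample_isotropic

# documented two-level toy slice used by the brute-force oracles
TOY_SLICE = np.array(
    [[1, 1, 2, 2],
     [1, 1, 2, 2],
     [2, 2, 1, 1],
     [2, 2, 1, 1]]
)


class TestDiscretize:
    def test_constant_region_single_bin(self):
        vals = np.full((3, 3, 3), 42.0)
        labels = discretize(vals, np.ones_like(vals, bool), 10.0, warn_bin_count=False)
        assert set(np.unique(labels)) == {1}

    def test_stated_formula_on_listed_values(self):
        vals = np.array([0.0, 5.0, 10.0, 15.0, 25.0]).reshape(5, 1, 1)
        labels = discretize(vals, np.ones_like(vals, bool), 10.0, warn_bin_count=False)
        assert labels.ravel().tolist() == [1, 1, 2, 2, 3]

    def test_bin_count_arithmetic(self):
        vals = np.linspace(0, 150, 64).reshape(4, 4, 4)
        labels = discretize(vals, np.ones_like(vals, bool), 10.0)
        assert labels.max() == 16

    def test_out_of_range_bin_count_warns(self):
        vals = np.linspace(0, 20, 27).reshape(3, 3, 3)
        with pytest.warns(UserWarning, match="bins"):
            discretize(vals, np.ones_like(vals, bool), 10.0)


class TestFirstOrder:
    def test_constant_region_degenerate(self):
        vals = np.full((3, 3, 3), 7.0)
        f = firstorder_features(vals, np.ones_like(vals, bool))
        assert f["Mean"] == 7.0
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_hand_arithmetic_on_four_voxels(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        f = firstorder_features(vals, np.ones_like(vals, bool), bin_width=1.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert f["Range"] == 3.0

    def test_two_bin_histogram_entropy(self):
        vals = np.array([0.0, 0.0, 10.0, 10.0]).reshape(4, 1, 1)
        f = firstorder_features(vals, np.ones_like(vals, bool), bin_width=10.0)
        assert f["Entropy"] == pytest.approx(1.0)  # 1 bit
        assert f["Uniformity"] == pytest.approx(0.5)


class TestShape:
    def test_ball_voxel_volume(self, ball_mask):
        mask, sp = ball_mask
        f = shape_features(mask, sp)
        assert f["VoxelVolume"] == pytest.approx(4188.8, rel=0.05)

    def test_sphere_maximizes_sphericity(self, ball_mask):
        mask, sp = ball_mask
        ball = shape_features(mask, sp)
        box = np.zeros((22, 12, 7), bool)
        box[1:21, 1:11, 1:6] = True
        slab = shape_features(box, sp)
        assert ball["Sphericity"] == pytest.approx(1.0, abs=0.06)
        assert ball["Sphericity"] > slab["Sphericity"]

    def test_box_axis_length_ordering(self):
        box = np.zeros((22, 12, 7), bool)
        box[1:21, 1:11, 1:6] = True  # 20 x 10 x 5 mm on a 1 mm grid
        f = shape_features(box, (1.0, 1.0, 1.0))
        assert f["MajorAxisLength"] >= f["MinorAxisLength"] >= f["LeastAxisLength"]
        assert f["Elongation"] <= 1.0 and f["Flatness"] <= f["Elongation"]


def _brute_glcm(labels, d):
    levels = present_levels(labels)
    idx = {g: i for i, g in enumerate(levels)}
    m = np.zeros((len(levels), len(levels)))
    for p in np.ndindex(labels.shape):
        q = tuple(np.add(p, d))
        if all(0 <= q[i] < labels.shape[i] for i in range(3)):
            if labels[p] > 0 and labels[q] > 0:
                m[idx[labels[p]], idx[labels[q]]] += 1
    return m + m.T


def _brute_zones(labels):
    """Connected iso-level zones by explicit flood fill, 26-connectivity."""
    seen = np.zeros(labels.shape, bool)
    zones = []
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for p in np.ndindex(labels.shape):
        if labels[p] > 0 and not seen[p]:
            g = labels[p]
            stack, size = [p], 0
            seen[p] = True
            while stack:
                q = stack.pop()
                size += 1
                for d in offs:
                    r = tuple(np.add(q, d))
                    if all(0 <= r[i] < labels.shape[i] for i in range(3)):
                        if labels[r] == g and not seen[r]:
                            seen[r] = True
                            stack.append(r)
            zones.append((int(g), size))
    return sorted(zones)


class TestTextureMatrices:
    def test_glcm_normalizes_to_one_and_is_symmetric(self, rng):
        labels = rng.integers(1, 5, size=(6, 6, 6))
        for d in DIRECTIONS[:4]:
            m = glcm_matrix(labels, d)
            p = m / m.sum()
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(m, m.T)

    def test_constant_region_degenerates(self):
        labels = np.ones((4, 4, 4), dtype=int)
        f = glcm_features(labels)
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0  # zero-variance convention
        g = glrlm_features(labels)
        # one run spanning the whole line in every direction
        assert g["LongRunEmphasis"] > 1.0
        assert ngtdm_features(labels)["Contrast"] == 0.0

    def test_toy_slice_glcm_matches_brute_force(self):
        labels = TOY_SLICE[:, :, None]
        for d in DIRECTIONS:
            np.testing.assert_allclose(
                glcm_matrix(labels, d), _brute_glcm(labels, d)
            )

    def test_toy_slice_glcm_contrast_value(self):
        # direction (0,1,0): 12 horizontal pairs, 4 cross-level -> sym
        labels = TOY_SLICE[:, :, None]
        m = glcm_matrix(labels, (0, 1, 0))
        p = m / m.sum()
        lv = present_levels(labels)
        contrast = sum(
            p[i, j] * (lv[i] - lv[j]) ** 2
            for i in range(len(lv)) for j in range(len(lv))
        )
        assert contrast == pytest.approx(1 / 3)

    def test_toy_slice_glszm_matches_flood_fill(self, rng):
        labels = rng.integers(1, 4, size=(5, 5, 3))
        m, levels = glszm_matrix(labels)
        zones = _brute_zones(labels)
        # rebuild the matrix from the brute-force zone list
        ref = np.zeros_like(m)
        idx = {g: i for i, g in enumerate(levels)}
        for g, s in zones:
            ref[idx[g], s - 1] += 1
        np.testing.assert_allclose(m, ref)

    def test_glszm_zone_sizes_sum_to_voxels(self, rng):
        labels = rng.integers(1, 6, size=(7, 7, 5))
        m, _ = glszm_matrix(labels)
        sizes = np.arange(1, m.shape[1] + 1)
        assert (m * sizes).sum() == labels.size

    def test_gldm_dependence_counts_small_example(self):
        # 2x2x1 all same level: each voxel has 3 dependent neighbours -> d=4
        labels = np.ones((2, 2, 1), dtype=int)
        from rectomics.features.texture import gldm_matrix

        m, levels = gldm_matrix(labels)
        assert levels.tolist() == [1]
        assert m[0].tolist() == [0, 0, 0, 4]

    def test_shift_by_bin_width_multiple_leaves_texture_unchanged(self, rng):
        vals = rng.normal(50, 30, size=(6, 6, 6))
        mask = np.ones_like(vals, bool)
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            f1 = texture_features(vals, mask, 10.0, family)
            f2 = texture_features(vals + 30.0, mask, 10.0, family)
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], rel=1e-9), (family, k)


class TestFilterBank:
    def test_output_count_is_twelve(self, rng):
        out = filter_bank(rng.normal(size=(10, 10, 10)), (1, 1, 1))
        assert len(out) == 12

    def test_log_of_constant_is_zero(self):
        out = filter_bank(np.full((10, 10, 10), 5.0), (1, 1, 1))
        for s in (1, 2, 3):
            np.testing.assert_allclose(out[f"log-sigma-{s}"], 0.0, atol=1e-9)

    def test_lowpass_of_constant_is_constant(self):
        out = filter_bank(np.full((10, 10, 10), 5.0), (1, 1, 1))
        np.testing.assert_allclose(out["wavelet-LLL"], 5.0, atol=1e-9)

    def test_highpass_of_constant_is_zero(self):
        out = filter_bank(np.full((10, 10, 10), 5.0), (1, 1, 1))
        np.testing.assert_allclose(out["wavelet-HHH"], 0.0, atol=1e-9)

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError, match="support"):
            filter_bank(np.zeros((2, 2, 2)), (1, 1, 1))


@pytest.fixture(scope="module")
def extracted(tiny_cohort):
    (vol, gtv, ctv), *_ = tiny_cohort[0]
    rvol, (rg, rc) = resample_isotropic(vol, [gtv, ctv])
    return extract_all(rvol, rg, rc, subject_id="S0"), (rvol, rg, rc)


class TestExtractAll:
    def test_feature_count_per_segment(self, extracted):
        feats, _ = extracted
        assert N_FEATURES_PER_SEGMENT == 1130
        gtv_names = [k for k in feats if not k.endswith("_ctv")]
        ctv_names = [k for k in feats if k.endswith("_ctv")]
        assert len(gtv_names) == 1130
        assert len(ctv_names) == 1130

    def test_all_values_finite_and_name_order_stable(self, extracted):
        feats, _ = extracted
        assert np.isfinite(list(feats.values())).all()
        assert list(feats) == feature_names("") + feature_names("_ctv")

    def test_determinism(self, extracted):
        feats, (rvol, rg, rc) = extracted
        again = extract_all(rvol, rg, rc, subject_id="S0")
        assert feats == again
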