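"""SSM/PCA pattern derivation and topographic profile rating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from petdx.metrics import roc_auc_one_vs_all
from petdx.preprocess import Volume
from petdx.ssmpca import (
    PatternConfig,
    derive_pattern,
    double_center,
    log_transform,
    pattern_feature_matrix,
    tpr_score,
)
from petdx.synth import make_toy_atlas


def _volume(data, mask):
    return Volume(data=data, spacing_mm=(2.0, 2.0, 2.0), mask=mask)


@pytest.fixture(scope="module")
def derivation(small_cohort_module):
    """AD-vs-NC pattern from the leakage subjects of the small cohort."""
    volumes, table, atlas = small_cohort_module
    leak = table["leakage"].to_numpy()
    cls = table["class"].to_numpy()
    ad = [v for v, l, c in zip(volumes, leak, cls) if l and c == "AD"]
    nc = [v for v, l, c in zip(volumes, leak, cls) if l and c == "NC"]
    pattern = derive_pattern(ad, nc, name="ADRP")
    return pattern, volumes, table, atlas


@pytest.fixture(scope="module")
def small_cohort_module(request):
    return request.getfixturevalue("small_cohort")


class TestLogTransform:
    def test_constant_e_gives_ones(self):
        mask = np.ones((4, 4, 4), bool)
        vec = log_transform(_volume(np.full((4, 4, 4), np.e), mask))
        np.testing.assert_allclose(vec, 1.0)

    def test_unit_volume_gives_zeros(self):
        mask = np.ones((4, 4, 4), bool)
        vec = log_transform(_volume(np.ones((4, 4, 4)), mask))
        np.testing.assert_allclose(vec, 0.0)

    def test_nonpositive_voxel_rejected(self):
        mask = np.ones((4, 4, 4), bool)
        data = np.ones((4, 4, 4))
        data[1, 2, 3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            log_transform(_volume(data, mask))


class TestDoubleCenter:
    def test_hand_computed_example(self):
        srp, gmp = double_center(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        np.testing.assert_allclose(gmp, [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(srp, 0.0, atol=1e-12)

    def test_constant_matrix_gives_zero_srp(self):
        srp, _ = double_center(np.full((3, 5), 7.0))
        np.testing.assert_allclose(srp, 0.0, atol=1e-12)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            double_center(np.ones((1, 5)))

    def test_permuting_subjects_permutes_rows(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(5, 7))
        srp, gmp = double_center(mat)
        perm = [3, 0, 4, 1, 2]
        srp_p, gmp_p = double_center(mat[perm])
        np.testing.assert_allclose(srp_p, srp[perm])
        np.testing.assert_allclose(gmp_p, gmp)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        mat=arrays(
            float,
            st.tuples(st.integers(2, 8), st.integers(2, 12)),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    def test_rows_and_columns_sum_to_zero(self, mat):
        srp, _ = double_center(mat)
        n = max(mat.shape)
        assert np.all(np.abs(srp.sum(axis=1)) <= 1e-8 * n)
        assert np.all(np.abs(srp.sum(axis=0)) <= 1e-8 * n)


@pytest.fixture(scope="module")
def dlb_pattern(small_cohort_module):
    """Pattern for the class with small planted parcels (DLB: ROIs 3, 4)."""
    volumes, table, atlas = small_cohort_module
    leak = table["leakage"].to_numpy()
    cls = table["class"].to_numpy()
    dlb = [v for v, l, c in zip(volumes, leak, cls) if l and c == "DLB"]
    nc = [v for v, l, c in zip(volumes, leak, cls) if l and c == "NC"]
    return derive_pattern(dlb, nc, name="DLBRP"), atlas


class TestDerivePattern:
    def test_weights_concentrate_on_planted_rois(self, dlb_pattern):
        """The planted ROIs carry the extreme (negative) loadings."""
        pattern, atlas = dlb_pattern
        roi_of_voxel = atlas.labels[atlas.mask]
        in_planted = (roi_of_voxel == 3) | (roi_of_voxel == 4)
        mean_in = pattern.weights[in_planted].mean()
        mean_out = pattern.weights[~in_planted].mean()
        assert mean_in < 0  # hypometabolic: disease loads negatively
        assert abs(mean_in) > abs(mean_out)

    def test_weights_correlate_with_planted_topography(self, dlb_pattern):
        """|r| >= 0.8 against the planted topography seen by the derivation
        (the indicator put through the same smoothing kernel as the data)."""
        from petdx.preprocess import smooth

        pattern, atlas = dlb_pattern
        indicator = np.zeros(atlas.labels.shape)
        indicator[(atlas.labels == 3) | (atlas.labels == 4)] = 1.0
        blurred = smooth(_volume(indicator, atlas.mask), 10.0)
        r = np.corrcoef(pattern.weights, blurred.data[atlas.mask])[0, 1]
        assert abs(r) >= 0.8

    def test_nc_derivation_scores_standardized(self, derivation):
        """Scoring the NC derivation subjects gives Z mean 0, SD 1."""
        pattern, volumes, table, _ = derivation
        leak = table["leakage"].to_numpy()
        cls = table["class"].to_numpy()
        z = [
            tpr_score(v, pattern).z_score
            for v, l, c in zip(volumes, leak, cls)
            if l and c == "NC"
        ]
        assert np.mean(z) == pytest.approx(0.0, abs=1e-8)
        assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-8)

    def test_disease_group_mean_z_positive(self, derivation):
        pattern, volumes, table, _ = derivation
        leak = table["leakage"].to_numpy()
        cls = table["class"].to_numpy()
        z = [
            tpr_score(v, pattern).z_score
            for v, l, c in zip(volumes, leak, cls)
            if l and c == "AD"
        ]
        assert np.mean(z) > 0

    def test_pca_reconstruction_when_all_components_kept(self, derivation):
        from petdx.ssmpca import _log_matrix

        _, volumes, table, _ = derivation
        srp, _ = double_center(_log_matrix(volumes[:6]))
        u, s, vt = np.linalg.svd(srp, full_matrices=False)
        np.testing.assert_allclose((u * s) @ vt, srp, atol=1e-6)

    def test_too_few_subjects_rejected(self, derivation):
        _, volumes, _, _ = derivation
        with pytest.raises(ValueError, match="at least 3"):
            derive_pattern(volumes[:2], volumes[8:12])

    def test_logistic_mode_also_separates(self, derivation):
        _, volumes, table, _ = derivation
        leak = table["leakage"].to_numpy()
        cls = table["class"].to_numpy()
        ad = [v for v, l, c in zip(volumes, leak, cls) if l and c == "AD"]
        nc = [v for v, l, c in zip(volumes, leak, cls) if l and c == "NC"]
        pattern = derive_pattern(ad, nc, PatternConfig(mode="logistic"))
        z_ad = [tpr_score(v, pattern).z_score for v in ad]
        assert np.mean(z_ad) > 0


class TestTprScore:
    def test_gmp_plus_constant_scores_zero(self, derivation):
        pattern, _, _, _ = derivation
        data = np.zeros(pattern.mask.shape)
        data[pattern.mask] = np.exp(pattern.gmp + 0.7)
        data[~pattern.mask] = 0.0
        score = tpr_score(_volume(data, pattern.mask), pattern)
        assert score.raw_score == pytest.approx(0.0, abs=1e-8)
        expected_z = -pattern.nc_score_mean / pattern.nc_score_sd
        assert score.z_score == pytest.approx(expected_z, abs=1e-8)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(k=st.floats(0.05, 20.0))
    def test_invariant_to_global_intensity_scaling(self, derivation, k):
        pattern, volumes, _, _ = derivation
        vol = volumes[10]
        scaled = vol.with_data(np.where(vol.mask, vol.data * k, vol.data))
        s1 = tpr_score(vol, pattern)
        s2 = tpr_score(scaled, pattern)
        assert s2.z_score == pytest.approx(s1.z_score, abs=1e-8)

    def test_mask_mismatch_rejected(self, derivation):
        pattern, _, _, _ = derivation
        other = make_toy_atlas(pattern.mask.shape, 4, seed=99)
        bad_mask = other.labels == 1
        data = np.where(bad_mask, 1.0, 0.0)
        with pytest.raises(ValueError, match="mask"):
            tpr_score(_volume(data, bad_mask), pattern)

    def test_held_out_disease_vs_nc_auc(self, derivation):
        """Prospective scores separate unseen AD from unseen NC (AUC >= 0.95)."""
        pattern, volumes, table, _ = derivation
        leak = table["leakage"].to_numpy()
        cls = table["class"].to_numpy()
        held = [
            (tpr_score(v, pattern).z_score, c)
            for v, l, c in zip(volumes, leak, cls)
            if not l and c in ("AD", "NC")
        ]
        scores, labels = zip(*held)
        assert roc_auc_one_vs_all(scores, labels, "AD") >= 0.95


class TestPatternFeatureMatrix:
    def test_shape_and_column_order(self, derivation):
        pattern, volumes, table, _ = derivation
        pattern_b = derive_pattern(volumes[8:12], volumes[24:28], name="DLBRP")
        fm = pattern_feature_matrix(volumes, [pattern, pattern_b], table)
        assert fm.values.shape == (len(volumes), 2)
        assert fm.feature_names == ["ADRP", "DLBRP"]
        assert fm.class_labels == table["class"].tolist()

    def test_nc_derivation_column_mean_zero(self, derivation):
        pattern, volumes, table, _ = derivation
        fm = pattern_feature_matrix(volumes, [pattern], table)
        sel = (table["leakage"] & (table["class"] == "NC")).to_numpy()
        assert fm.values[sel, 0].mean() == pytest.approx(0.0, abs=1e-8)

    def test_empty_pattern_list_rejected(self, derivation):
        _, volumes, table, _ = derivation
        with pytest.raises(ValueError):
            pattern_feature_matrix(volumes, [], table)
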