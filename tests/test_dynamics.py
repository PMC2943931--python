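"""Voxelwise z-transform, IC matching, group components, back-projection."""

import numpy as np
import pytest

from covmap.dynamics import (
    SpatialMap,
    backproject,
    group_component,
    match_ics_to_templates,
    normalize_across_rsns,
    threshold_map,
    ztransform_voxelwise,
)
from covmap.synthetic import generate_subject_ic_maps, generate_templates


class TestZTransform:
    def test_hand_computed_row(self):
        out = ztransform_voxelwise(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])

    def test_constant_row_maps_to_zero(self):
        out = ztransform_voxelwise(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(out[0], 0.0)

    def test_idempotent_on_standardized_rows(self, rng):
        x = ztransform_voxelwise(rng.standard_normal((10, 50)))
        np.testing.assert_allclose(ztransform_voxelwise(x), x, atol=1e-12)

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError):
            ztransform_voxelwise(np.ones((3, 1)))


class TestMatching:
    def test_identical_map_matches_with_similarity_one(self, rng):
        t = SpatialMap(rng.standard_normal(100), (100,))
        a = match_ics_to_templates([t], [t])
        assert a.matches == {0: 0}
        assert a.similarity[0] == pytest.approx(1.0)
        assert a.sign[0] == 1

    def test_sign_flipped_map_matches_and_is_flagged(self, rng):
        v = rng.standard_normal(100)
        a = match_ics_to_templates(
            [SpatialMap(-v, (100,))], [SpatialMap(v, (100,))]
        )
        assert a.similarity[0] == pytest.approx(1.0)
        assert a.sign[0] == -1

    def test_independent_random_maps_stay_unassigned(self, rng):
        # at 10^4 voxels, |corr| between independent maps is < 0.1
        ics = [SpatialMap(rng.standard_normal(10_000), (10_000,)) for _ in range(3)]
        tms = [SpatialMap(rng.standard_normal(10_000), (10_000,)) for _ in range(3)]
        a = match_ics_to_templates(ics, tms, min_similarity=0.25)
        assert a.matches == {}

    def test_permutation_invariance_of_pairing(self, rng):
        templates = generate_templates(4, (8, 8, 4), seed=3)
        ics = generate_subject_ic_maps(templates, 0.05, 0.5, seed=4)[0]
        a1 = match_ics_to_templates(ics, templates)
        shuffled_idx = [2, 0, 3, 1] + list(range(4, len(ics)))
        a2 = match_ics_to_templates([ics[i] for i in shuffled_idx], templates)
        pairs1 = {(t, i) for t, i in a1.matches.items()}
        pairs2 = {(t, shuffled_idx[i]) for t, i in a2.matches.items()}
        assert pairs1 == pairs2

    def test_noiseless_recovery_is_identity(self):
        templates = generate_templates(5, (8, 8, 4), seed=0)
        ics = generate_subject_ic_maps(templates, 0.0, 0.0, seed=1)[0]
        a = match_ics_to_templates(ics, templates)
        assert len(a.matches) == 5
        for t, i in a.matches.items():
            assert a.similarity[t] == pytest.approx(1.0)

    def test_all_flipped_recovery_with_sign_invariance(self):
        templates = generate_templates(5, (8, 8, 4), seed=0)
        ics = generate_subject_ic_maps(templates, 0.0, 1.0, seed=1)[0]
        a = match_ics_to_templates(ics, templates)
        assert len(a.matches) == 5
        assert all(s == -1 for s in a.sign.values())

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            match_ics_to_templates(
                [SpatialMap(np.zeros(8), (8,))], [SpatialMap(np.zeros(9), (9,))]
            )


class TestGroupComponent:
    def test_hand_computed_t(self):
        vals = [0.5, 0.7, 0.9, 1.1, 1.3]
        maps = [SpatialMap([v], (1,)) for v in vals]
        gc = group_component(maps)
        assert gc.tmap.values[0] == pytest.approx(6.3640, abs=1e-4)

    def test_symmetric_values_give_zero_t(self):
        maps = [SpatialMap([v], (1,)) for v in [-1.0, 1.0]]
        assert group_component(maps).tmap.values[0] == 0.0

    def test_degenerate_zero_voxel(self):
        maps = [SpatialMap([0.0], (1,)) for _ in range(4)]
        gc = group_component(maps)
        assert gc.tmap.values[0] == 0.0

    def test_fewer_than_two_contributors_rejected(self):
        with pytest.raises(ValueError):
            group_component([SpatialMap([1.0], (1,))])

    def test_largest_t_on_template_support_without_noise(self):
        # compact-support template with exactly representable values: without
        # spatial noise, t is largest (sentinel) on support and 0 elsewhere
        v = np.zeros(64)
        support = np.array([10, 11, 12, 20])
        v[support] = 1.0
        template = SpatialMap(v, (8, 8, 1))
        subj = generate_subject_ic_maps([template], 0.0, 0.0, seed=8, n_subjects=5)
        gc = group_component([ics[0] for ics in subj])
        on = np.abs(gc.tmap.values[support])
        off = np.abs(np.delete(gc.tmap.values, support))
        assert on.min() > off.max()
        assert np.all(off == 0.0)

    def test_threshold_map_is_display_only(self, rng):
        templates = generate_templates(2, (8, 8, 4), seed=1)
        subj = generate_subject_ic_maps(templates, 0.05, 0.0, seed=2, n_subjects=6)
        aligned = []
        for ics in subj:
            a = match_ics_to_templates(ics, templates)
            aligned.append(
                SpatialMap(a.sign[0] * ics[a.matches[0]].values, templates[0].shape)
            )
        gc = group_component(aligned)
        disp = threshold_map(gc, p=0.005, min_cluster=5)
        # thresholding zeroes some voxels but never alters surviving values
        kept = disp.values != 0
        np.testing.assert_array_equal(disp.values[kept], gc.tmap.values[kept])
        assert kept.sum() < gc.tmap.n_voxels


class TestBackprojection:
    def test_one_hot_weights_select_voxel_timecourse(self, rng):
        bold = rng.standard_normal((5, 7))
        w = np.zeros(5)
        w[3] = 1.0
        out = backproject(SpatialMap(w, (5,)), bold)
        np.testing.assert_array_equal(out, bold[3])

    def test_zero_map_gives_zero_timecourse(self, rng):
        out = backproject(SpatialMap(np.zeros(5), (5,)), rng.standard_normal((5, 7)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_explicit_double_loop(self, rng):
        w = rng.standard_normal(4)
        bold = rng.standard_normal((4, 3))
        expected = np.array(
            [sum(w[v] * bold[v, t] for v in range(4)) for t in range(3)]
        )
        np.testing.assert_allclose(
            backproject(SpatialMap(w, (4,)), bold), expected, rtol=1e-12
        )

    def test_linearity(self, rng):
        w = SpatialMap(rng.standard_normal(6), (6,))
        x, y = rng.standard_normal((2, 6, 9))
        lhs = backproject(w, 2.5 * x - 1.5 * y)
        rhs = 2.5 * backproject(w, x) - 1.5 * backproject(w, y)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            backproject(SpatialMap(np.zeros(5), (5,)), rng.standard_normal((6, 7)))


class TestNormalizeAcrossRsns:
    def test_hand_computed_column(self):
        out = normalize_across_rsns(np.array([[3.0], [-3.0]]))
        np.testing.assert_allclose(
            out.activity, [[0.70711], [-0.70711]], atol=1e-5
        )

    def test_unit_variance_column_unchanged(self, rng):
        x = rng.standard_normal((4, 20))
        x /= x.std(axis=0, ddof=1, keepdims=True)
        out = normalize_across_rsns(x)
        np.testing.assert_allclose(out.activity, x, atol=1e-12)

    def test_constant_column_becomes_zero(self):
        x = np.array([[1.0, 2.0], [1.0, -2.0], [1.0, 0.0]])
        out = normalize_across_rsns(x)
        np.testing.assert_array_equal(out.activity[:, 0], 0.0)

    def test_single_rsn_rejected(self):
        with pytest.raises(ValueError):
            normalize_across_rsns(np.ones((1, 10)))
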