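"""Connectivity hyperalignment: Procrustes fits, common model, invariants."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from fgconn.cohort import (
    CohortConfig,
    SubjectTimeSeries,
    make_parcellation,
    random_orthogonal,
    simulate_cohort,
)
from fgconn.hyperalign import (
    Transform,
    apply_cha,
    apply_transform,
    build_common_model,
    cha_seed_profiles,
    fit_cha,
    fit_procrustes,
    identity_transforms,
    region_mean_timeseries,
)
from fgconn.preprocess import preprocess_subject


class TestRegionMeanTimeseries:
    def test_single_vertex_region_returns_its_series(self, rng):
        parc = make_parcellation(1, 1, seed=0)
        ts = SubjectTimeSeries(values=rng.standard_normal((1, 20)))
        assert np.allclose(region_mean_timeseries(ts, parc), ts.values)

    def test_identical_vertices_give_same_series(self, rng):
        parc = make_parcellation(2, 1, seed=0)
        row = rng.standard_normal(15)
        ts = SubjectTimeSeries(values=np.vstack([row, row]))
        assert np.allclose(region_mean_timeseries(ts, parc)[0], row)

    def test_matches_loop_and_average_oracle(self, rng):
        parc = make_parcellation(5, 2, seed=3)
        ts = SubjectTimeSeries(values=rng.standard_normal((5, 12)))
        got = region_mean_timeseries(ts, parc)
        for r in range(2):
            idx = parc.vertices_of(r)
            expected = sum(ts.values[v] for v in idx) / len(idx)
            assert np.allclose(got[r], expected)


class TestSeedProfiles:
    def test_vertex_equal_to_target_has_correlation_one(self, rng):
        series = rng.standard_normal(30)
        ts = SubjectTimeSeries(values=series[None, :])
        prof = cha_seed_profiles(ts, np.vstack([series, -series]))
        assert prof[0, 0] == pytest.approx(1.0)
        assert prof[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_oracle(self, rng):
        values = rng.standard_normal((3, 6))
        targets = rng.standard_normal((2, 6))
        got = cha_seed_profiles(SubjectTimeSeries(values=values), targets)
        for v in range(3):
            for t in range(2):
                x, y = values[v], targets[t]
                expected = (
                    np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2))
                )
                assert got[v, t] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_vertex_rejected(self):
        ts = SubjectTimeSeries(values=np.ones((1, 10)))
        with pytest.raises(ValueError, match="zero-variance"):
            cha_seed_profiles(ts, np.random.default_rng(0).standard_normal((1, 10)))


class TestFitProcrustes:
    def test_identity_when_source_equals_template(self, rng):
        source = rng.standard_normal((6, 10))
        t = fit_procrustes(source, source)
        assert np.allclose(t, np.eye(6), atol=1e-10)

    def test_exact_recovery_of_known_rotation(self, rng):
        template = rng.standard_normal((8, 12))
        q = random_orthogonal(8, rng)
        source = q @ template
        t = fit_procrustes(source, template)
        assert np.linalg.norm(t.T @ source - template) < 1e-10

    def test_fitted_transform_is_orthogonal(self, rng):
        t = fit_procrustes(rng.standard_normal((7, 9)),
                           rng.standard_normal((7, 9)))
        assert np.allclose(t.T @ t, np.eye(7), atol=1e-10)
        assert abs(abs(np.linalg.det(t)) - 1.0) < 1e-8

    def test_monte_carlo_minimality(self, rng):
        source = rng.standard_normal((6, 10))
        template = rng.standard_normal((6, 10))
        t = fit_procrustes(source, template)
        best = np.linalg.norm(t.T @ source - template)
        for _ in range(1000):
            q = random_orthogonal(6, rng)
            assert best <= np.linalg.norm(q.T @ source - template) + 1e-12

    def test_agrees_with_scipy_oracle(self, rng):
        source = rng.standard_normal((5, 11))
        template = rng.standard_normal((5, 11))
        t = fit_procrustes(source, template)
        t_scipy, _ = orthogonal_procrustes(source.T, template.T)
        assert np.allclose(t, t_scipy, atol=1e-10)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_procrustes(np.zeros((3, 5)), np.zeros((3, 5)))


class TestApplyTransform:
    def test_identity_transform_is_noop(self, rng):
        block = rng.standard_normal((4, 9))
        t = Transform(matrix=np.eye(4), subject_id=0, region_id=0)
        assert np.allclose(apply_transform(block, t), block)

    def test_preserves_frobenius_norm_and_timepoint_geometry(self, rng):
        block = rng.standard_normal((6, 20))
        q = random_orthogonal(6, rng)
        out = apply_transform(block, q)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(block),
                                                    abs=1e-10)
        # pairwise distances between timepoints, computed across vertices
        def dists(x):
            diff = x.T[:, None, :] - x.T[None, :, :]
            return np.sqrt(np.sum(diff**2, axis=2))
        assert np.allclose(dists(out), dists(block), atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_transform(rng.standard_normal((4, 9)), np.eye(5))


class TestCommonModel:
    def test_identical_profiles_give_identity_family(self, rng):
        profile = rng.standard_normal((5, 8))
        template, transforms = build_common_model(
            [profile.copy() for _ in range(4)], region_id=0, normalize=False
        )
        assert np.allclose(template, profile, atol=1e-8)
        for t in transforms:
            assert np.allclose(t.matrix.T @ profile, profile, atol=1e-8)

    def test_rotated_copies_align_exactly(self, rng):
        base = rng.standard_normal((6, 10))
        profiles = [random_orthogonal(6, rng) @ base for _ in range(5)]
        _, transforms = build_common_model(profiles, region_id=0,
                                           normalize=False)
        aligned = [t.matrix.T @ p for t, p in zip(transforms, profiles)]
        for a in aligned[1:]:
            assert np.allclose(a, aligned[0], atol=1e-8)

    def test_alignment_raises_intersubject_correlation_under_noise(self, rng):
        base = rng.standard_normal((8, 15))
        profiles = [
            random_orthogonal(8, rng) @ (base + 0.3 * rng.standard_normal(base.shape))
            for _ in range(20)
        ]
        _, transforms = build_common_model(profiles, region_id=0)
        aligned = [t.matrix.T @ p for t, p in zip(transforms, profiles)]

        def mean_pairwise_corr(mats):
            flat = np.array([m.ravel() for m in mats])
            c = np.corrcoef(flat)
            return c[np.triu_indices_from(c, k=1)].mean()

        assert mean_pairwise_corr(aligned) > mean_pairwise_corr(profiles)

    def test_requires_two_subjects(self, rng):
        with pytest.raises(ValueError):
            build_common_model([rng.standard_normal((3, 5))], region_id=0)


class TestCohortLevel:
    def test_alignment_improves_profile_isc_in_most_regions(self):
        """CHA strictly increases inter-subject correlation of regional
        fine-grained connectivity profiles in >= 90% of regions."""
        config = CohortConfig(
            family_histogram={1: 16},
            n_vertices=96,
            n_regions=8,
            n_timepoints_per_run=150,
            rotation_dispersion=0.6,
            seed=5,
        )
        parc = make_parcellation(config.n_vertices, config.n_regions, seed=6)
        subjects, _, _ = simulate_cohort(config, parcellation=parc)
        pre = [preprocess_subject(s) for s in subjects]
        _, transforms = fit_cha(pre, parc)
        aligned = [apply_cha(ts, parc, transforms, i)
                   for i, ts in enumerate(pre)]

        def profile_isc(ts_list, region):
            idx = parc.vertices_of(region)
            flats = []
            for ts in ts_list:
                x = ts.values - ts.values.mean(axis=1, keepdims=True)
                x /= np.linalg.norm(x, axis=1, keepdims=True)
                flats.append((x[idx] @ x.T).ravel())
            c = np.corrcoef(np.array(flats))
            return c[np.triu_indices_from(c, k=1)].mean()

        improved = [
            profile_isc(aligned, r) > profile_isc(pre, r)
            for r in range(config.n_regions)
        ]
        assert np.mean(improved) >= 0.9

    def test_no_rotation_no_noise_transforms_act_as_identity(self):
        config = CohortConfig(
            family_histogram={1: 6},
            n_vertices=36,
            n_regions=3,
            n_timepoints_per_run=100,
            fine_effect=0.0,
            coarse_effect=0.0,
            weight_noise=0.0,
            coupling_noise=0.0,
            rotation_dispersion=0.0,
            noise_sd=0.0,
            seed=9,
        )
        parc = make_parcellation(config.n_vertices, config.n_regions, seed=1)
        subjects, _, _ = simulate_cohort(config, parcellation=parc)
        pre = [preprocess_subject(s) for s in subjects]
        _, transforms = fit_cha(pre, parc)
        aligned = [apply_cha(ts, parc, transforms, i)
                   for i, ts in enumerate(pre)]
        for ts_a, ts_u in zip(aligned, pre):
            assert np.allclose(ts_a.values, ts_u.values, atol=1e-8)

    def test_identity_transforms_are_identity(self, tiny_cohort):
        parc = tiny_cohort["parcellation"]
        transforms = identity_transforms(tiny_cohort["subjects"], parc)
        ts = tiny_cohort["subjects"][0]
        out = apply_cha(ts, parc, transforms, 0)
        assert np.array_equal(out.values, ts.values)

    def test_fitted_transforms_are_orthogonal(self, tiny_cohort):
        pre = [preprocess_subject(s) for s in tiny_cohort["subjects"][:6]]
        parc = tiny_cohort["parcellation"]
        _, transforms = fit_cha(pre, parc)
        for t in transforms.values():
            n = t.matrix.shape[0]
            assert np.allclose(t.matrix.T @ t.matrix, np.eye(n), atol=1e-8)
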