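"""Block permutation, bootstrap contrasts, idiosyncrasy, Dice, overlap."""

import itertools

import numpy as np
import pytest

from fgconn.cohort import make_family_structure, make_parcellation, random_orthogonal
from fgconn.stats import (
    block_permutation,
    bootstrap_contrast,
    dice,
    dominant_system,
    idiosyncrasy_index,
    pearson_r,
    permutation_pvalue,
    system_overlap,
    top_k_regions,
)


class TestIdiosyncrasy:
    def test_identical_transforms_give_zero_dissimilarity(self):
        transforms = {r: [np.eye(5)] * 4 for r in range(4)}
        res = idiosyncrasy_index(transforms)
        assert np.allclose(res.raw, 0.0)

    def test_raw_index_tracks_sqrt_region_size(self, rng):
        """For uniformly random orthogonal transforms the mean pairwise
        Frobenius distance is essentially proportional to sqrt(region size)."""
        sizes = np.arange(10, 81, 5)
        transforms = {
            k: [random_orthogonal(n, rng) for _ in range(20)]
            for k, n in enumerate(sizes)
        }
        res = idiosyncrasy_index(transforms)
        assert pearson_r(res.raw, res.sqrt_region_size) > 0.99

    def test_residual_ranks_dispersion_levels(self, rng):
        """Regions whose subjects have more dispersed transforms receive a
        higher size-corrected idiosyncrasy index."""
        from fgconn.cohort import dispersed_orthogonal

        transforms = {}
        dispersions = {}
        sizes = [12, 20, 28, 36, 44, 52]
        for k, n in enumerate(sizes):
            disp = 0.25 if k % 2 == 0 else 0.9
            dispersions[k] = disp
            transforms[k] = [dispersed_orthogonal(n, disp, rng)
                             for _ in range(15)]
        res = idiosyncrasy_index(transforms)
        low = [res.residual[k] for k in transforms if dispersions[k] == 0.25]
        high = [res.residual[k] for k in transforms if dispersions[k] == 0.9]
        assert min(high) > max(low)

    def test_residual_uncorrelated_with_size_under_uniform_dispersion(self, rng):
        sizes = np.arange(10, 90, 4)
        transforms = {
            k: [random_orthogonal(n, rng) for _ in range(12)]
            for k, n in enumerate(sizes)
        }
        res = idiosyncrasy_index(transforms)
        assert abs(pearson_r(res.residual, res.sqrt_region_size)) < 0.1

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            idiosyncrasy_index({r: [np.eye(3)] for r in range(3)})


class TestBlockPermutation:
    def test_singleton_families_permute_freely(self):
        families = make_family_structure({1: 8}, seed=0)
        scores = np.arange(8.0)
        perms = block_permutation(scores, families, n_perm=50, seed=1)
        assert perms.shape == (50, 8)
        for p in perms:
            assert sorted(p) == sorted(scores)
        # permutations actually move values around
        assert not all(np.array_equal(p, scores) for p in perms)

    def test_size_stratum_multisets_invariant(self):
        families = make_family_structure({1: 4, 2: 3, 3: 2}, seed=2)
        scores = np.random.default_rng(0).standard_normal(families.n_subjects)
        perms = block_permutation(scores, families, n_perm=30, seed=3)
        sizes = families.family_sizes()
        for size in (1, 2, 3):
            pos = np.concatenate([
                families.members_of(f)
                for f in range(families.n_families) if sizes[f] == size
            ])
            original = np.sort(scores[pos])
            for p in perms:
                assert np.allclose(np.sort(p[pos]), original)

    def test_family_of_three_confined_by_enumeration(self):
        """One family of 3 among singletons: its three scores can only be
        shuffled among the family's own positions."""
        families = make_family_structure({1: 3, 3: 1}, seed=4)
        scores = np.array([10.0, 20.0, 30.0, 1.0, 2.0, 3.0])
        fam3 = np.argmax(families.family_sizes())
        pos3 = families.members_of(fam3)
        trio = set(scores[pos3])
        allowed = set(itertools.permutations(sorted(trio)))
        perms = block_permutation(scores, families, n_perm=200, seed=5)
        for p in perms:
            assert set(p[pos3]) == trio  # never leaves the family positions
        # and every within-family arrangement is eventually visited
        seen = {tuple(p[pos3]) for p in perms}
        assert seen == allowed


class TestPermutationPvalue:
    def test_observed_above_all_hundred(self):
        p = permutation_pvalue(10.0, np.linspace(-5, 5, 100))
        assert p == pytest.approx(1 / 101)
        assert p < 0.01

    def test_observed_below_all(self):
        assert permutation_pvalue(-10.0, np.linspace(-5, 5, 100)) == 1.0

    def test_uniform_under_null(self, rng):
        """p-values of a null statistic against its own distribution are
        approximately uniform."""
        pvals = [
            permutation_pvalue(rng.standard_normal(),
                               rng.standard_normal(19))
            for _ in range(500)
        ]
        # mean of uniform on the achievable grid is ~0.525 for n_perm=19
        assert abs(np.mean(pvals) - 0.525) < 0.05


class TestBootstrapContrast:
    def test_identical_predictions_collapse_to_point(self, rng):
        y = rng.standard_normal(40)
        pred = y + 0.3 * rng.standard_normal(40)
        tm = np.zeros(40)
        diff, ratio = bootstrap_contrast(y, pred, pred, tm, n_boot=500, seed=0)
        assert diff.lower == diff.upper == diff.point == 0.0
        assert ratio.lower == ratio.upper == ratio.point == 1.0

    def test_reproducible_given_seed(self, rng):
        y = rng.standard_normal(30)
        a = y + 0.5 * rng.standard_normal(30)
        b = y + 0.9 * rng.standard_normal(30)
        tm = np.zeros(30)
        ci1 = bootstrap_contrast(y, a, b, tm, n_boot=300, seed=7)
        ci2 = bootstrap_contrast(y, a, b, tm, n_boot=300, seed=7)
        assert ci1[0] == ci2[0] and ci1[1] == ci2[1]

    def test_interval_orders_and_brackets_point(self, rng):
        y = rng.standard_normal(60)
        a = y + 0.4 * rng.standard_normal(60)
        b = y + 1.2 * rng.standard_normal(60)
        diff, _ = bootstrap_contrast(y, a, b, np.zeros(60), n_boot=1000, seed=1)
        assert diff.lower <= diff.point <= diff.upper

    def test_nominal_coverage_of_true_vaf_difference(self):
        """95% CI covers the population VAF difference within ±3% over 200
        simulated evaluation cohorts."""
        noise_a, noise_b = 0.5, 0.9
        # population VAF of prediction y + noise e: 100*(1 - var(e))
        true_diff = 100.0 * (noise_b**2 - noise_a**2)
        n = 80
        covered = 0
        for sim in range(200):
            rng = np.random.default_rng(1000 + sim)
            y = rng.standard_normal(n)
            a = y + noise_a * rng.standard_normal(n)
            b = y + noise_b * rng.standard_normal(n)
            diff, _ = bootstrap_contrast(y, a, b, np.zeros(n), n_boot=2000,
                                         seed=sim)
            if diff.lower <= true_diff <= diff.upper:
                covered += 1
        assert abs(covered / 200 - 0.95) <= 0.03


class TestDiceAndTopK:
    def test_dice_identical_and_disjoint(self):
        assert dice({1, 2, 3}, {1, 2, 3}) == 1.0
        assert dice({1, 2}, {3, 4}) == 0.0

    def test_dice_hand_computed(self):
        a = set(range(40))
        b = set(range(20, 60))
        assert dice(a, b) == pytest.approx(0.5)

    def test_dice_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = set(rng.integers(0, 50, 15).tolist())
            b = set(rng.integers(0, 50, 15).tolist())
            if not a and not b:
                continue
            d = dice(a, b)
            assert 0.0 <= d <= 1.0
            assert d == dice(b, a)

    def test_dice_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            dice(set(), set())

    def test_top_k_matches_sort_oracle(self, rng):
        r2 = rng.standard_normal(50)
        got = top_k_regions(r2, k=12)
        expected = np.sort(np.argsort(-r2)[:12])
        assert np.array_equal(got, expected)

    def test_top_k_tie_goes_to_lower_region_id(self):
        r2 = np.array([1.0, 5.0, 5.0, 5.0, 0.0])
        assert np.array_equal(top_k_regions(r2, k=2), [1, 2])

    def test_top_k_equal_to_n_regions(self):
        r2 = np.arange(6.0)
        assert np.array_equal(top_k_regions(r2, k=6), np.arange(6))

    def test_top_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_k_regions(np.zeros(5), k=6)


class TestSystemOverlap:
    def test_region_wholly_inside_one_system(self):
        parc = make_parcellation(20, 2, seed=0)
        systems = np.zeros(20, dtype=int)
        systems[parc.vertices_of(1)] = 3
        out = system_overlap(np.array([0]), systems, parc)
        assert out == {0: 100.0}

    def test_two_equal_regions_in_two_systems(self):
        parc = make_parcellation(20, 2, seed=0)
        # force equal region sizes
        if len(parc.vertices_of(0)) != len(parc.vertices_of(1)):
            labels = np.repeat([0, 1], 10)
            from fgconn.cohort import Parcellation

            parc = Parcellation(region_label=labels)
        systems = parc.region_label.copy()
        out = system_overlap(np.array([0, 1]), systems, parc)
        assert out[0] == pytest.approx(50.0)
        assert out[1] == pytest.approx(50.0)

    def test_matches_counting_oracle_and_sums_to_100(self, rng):
        parc = make_parcellation(50, 5, seed=1)
        systems = rng.integers(0, 3, 50)
        region_set = np.array([0, 2, 3])
        out = system_overlap(region_set, systems, parc)
        vertices = np.concatenate([parc.vertices_of(r) for r in region_set])
        for s, pct in out.items():
            count = sum(1 for v in vertices if systems[v] == s)
            assert pct == pytest.approx(100.0 * count / len(vertices))
        assert sum(out.values()) == pytest.approx(100.0)

    def test_dominant_system(self):
        parc = make_parcellation(10, 1, seed=0)
        systems = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2])
        assert dominant_system(0, systems, parc) == 1


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_five_point_toy_matches_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))
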