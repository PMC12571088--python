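"""Scenario engine: APPD, Procrustes variance, nulls, classifications."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphx.extinction import (
    ExtinctionScenario,
    appd,
    apply_scenario,
    canonical_scenarios,
    procrustes_variance,
    random_extinction_null,
    targeted_vs_null,
)
from morphx.morphospace import ordinate, species_mean_shapes


@pytest.fixture(scope="module")
def species_space(aligned_species):
    ids, means = species_mean_shapes(aligned_species)
    return ids, means, ordinate(means, ids=ids)


class TestAppd:
    def test_two_configurations(self, rng):
        a, b = rng.normal(size=(2, 6, 2))
        d = np.linalg.norm((a - b).ravel())
        assert np.isclose(appd(np.stack([a, b])), d)

    def test_identical_set_is_zero(self):
        X = np.tile(np.arange(8.0).reshape(4, 2), (5, 1, 1))
        assert appd(X) == 0.0

    def test_matches_exhaustive_pair_mean(self, rng):
        X = rng.normal(size=(7, 5, 2))
        pairs = [
            np.linalg.norm((X[i] - X[j]).ravel())
            for i, j in itertools.combinations(range(7), 2)
        ]
        assert abs(appd(X) - np.mean(pairs)) <= 1e-12

    def test_undefined_below_two(self, rng):
        with pytest.raises(ValueError):
            appd(rng.normal(size=(1, 4, 2)))

    def test_removing_most_distant_member_never_increases(self, rng):
        """Dropping the specimen with maximal mean pairwise distance cannot
        raise the average pairwise distance (checked against brute force)."""
        for n in range(4, 13):
            X = rng.normal(size=(n, 3, 2))
            flat = X.reshape(n, -1)
            D = np.linalg.norm(flat[:, None] - flat[None], axis=-1)
            worst = int(np.argmax(D.mean(axis=1)))
            keep = [i for i in range(n) if i != worst]
            assert appd(X[keep]) <= appd(X) + 1e-12


class TestProcrustesVariance:
    def test_identical_group_is_zero(self):
        X = np.tile(np.arange(6.0), (4, 1))
        out = procrustes_variance(X, ["a"] * 4)
        assert out["a"] == 0.0

    def test_matches_direct_recomputation(self, rng):
        X = rng.normal(size=(20, 8))
        g = np.array(["a", "b"] * 10)
        out = procrustes_variance(X, g)
        for lvl in "ab":
            sub = X[g == lvl]
            direct = np.mean([np.linalg.norm(r - sub.mean(0)) ** 2 for r in sub])
            assert abs(out[lvl] - direct) <= 1e-12

    def test_member_order_invariance(self, rng):
        X = rng.normal(size=(12, 4))
        g = np.array(list("aaabbbcccddd"))
        perm = rng.permutation(12)
        a = procrustes_variance(X, g)
        b = procrustes_variance(X[perm], g[perm])
        for k in a:
            assert np.isclose(a[k], b[k])

    def test_singleton_group_is_nan_with_warning(self, rng):
        X = rng.normal(size=(4, 4))
        with pytest.warns(UserWarning, match="single member"):
            out = procrustes_variance(X, ["a", "a", "a", "b"])
        assert np.isnan(out["b"])


class TestScenarios:
    def test_canonical_scenarios_are_nested_partitions(self, species_bundle):
        statuses = species_bundle.traits["iucn"]
        scenarios = canonical_scenarios(statuses)
        prev = set()
        for sc in scenarios:
            removed = set(sc.removed)
            assert prev <= removed
            assert removed | set(sc.survivors) == set(statuses.index)
            assert not removed & set(sc.survivors)
            prev = removed

    def test_canonical_status_counts_give_printed_intensities(self, species_bundle):
        scenarios = canonical_scenarios(species_bundle.traits["iucn"])
        assert [len(sc.removed) for sc in scenarios] == [4, 12, 22, 26]

    def test_empty_removal_preserves_baseline(self, species_space):
        ids, means, ordn = species_space
        sc = ExtinctionScenario("none", (), [], list(ids))
        res = apply_scenario(ordn.pc12, means, ids, sc)
        assert res.pct_area_loss == 0.0
        assert res.shift.magnitude == 0.0
        assert np.isclose(res.appd, appd(means))

    def test_removing_everything_is_error(self, species_space):
        ids, means, ordn = species_space
        sc = ExtinctionScenario("all", ("CR",), list(ids), [])
        with pytest.raises(ValueError):
            apply_scenario(ordn.pc12, means, ids, sc)

    def test_peripheral_threat_gives_monotone_hull_loss(self):
        """When threat targets morphologically extreme species, the nested
        scenarios erode hull area monotonically."""
        from morphx.shape_core import superimpose
        from morphx.synthetic import GeneratorConfig, generate_bundle

        b = generate_bundle(GeneratorConfig(beta=8.0), seed=3, include_specimens=False)
        al = superimpose(b.configurations, slide=True)
        ids, means = species_mean_shapes(al)
        ordn = ordinate(means, ids=ids)
        areas = [
            apply_scenario(ordn.pc12, means, ids, sc).hull.area
            for sc in canonical_scenarios(b.traits["iucn"])
        ]
        assert all(a >= b_ - 1e-12 for a, b_ in zip(areas, areas[1:]))

    def test_depth_range_covers_survivors_only(self, species_space, species_bundle):
        ids, means, ordn = species_space
        sc = canonical_scenarios(species_bundle.traits["iucn"])[2]
        res = apply_scenario(
            ordn.pc12, means, ids, sc, depths=species_bundle.traits["max_depth_m"]
        )
        d = species_bundle.traits.loc[sc.survivors, "max_depth_m"]
        assert res.depth_range == (d.min(), d.max())


class TestRandomExtinctionNull:
    def test_same_seed_reproduces_replicates(self, species_space):
        ids, means, ordn = species_space
        n1 = random_extinction_null(ordn.pc12, means, 5, n_reps=20, seed=9)
        n2 = random_extinction_null(ordn.pc12, means, 5, n_reps=20, seed=9)
        for k in n1:
            assert np.array_equal(n1[k].values, n2[k].values)

    def test_intensity_bounds(self, species_space):
        ids, means, ordn = species_space
        n = len(ids)
        with pytest.raises(ValueError):
            random_extinction_null(ordn.pc12, means, n, n_reps=5, seed=0)
        with pytest.raises(ValueError):
            random_extinction_null(ordn.pc12, means, n - 1, n_reps=5, seed=0)
        # n - 2 leaves two survivors: APPD still defined
        null = random_extinction_null(ordn.pc12, means, n - 2, n_reps=5, seed=0)
        assert np.isfinite(null["appd"].values).all()

    def test_uniform_removal_is_unbiased_for_mean_pc1(self, species_space):
        ids, means, ordn = species_space
        null = random_extinction_null(ordn.pc12, means, 8, n_reps=400, seed=4)
        base = ordn.pc12[:, 0].mean()
        se = null["mean_pc1"].values.std(ddof=1) / np.sqrt(400)
        assert abs(null["mean_pc1"].mean - base) <= 3 * se

    def test_envelopes_widen_with_intensity_on_isotropic_scores(self, rng):
        scores = rng.normal(size=(30, 2))
        widths = []
        for k in (4, 12, 22, 26):
            null = random_extinction_null(scores, scores, k, n_reps=200, seed=1)
            widths.append(null["mean_pc1"].upper - null["mean_pc1"].lower)
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))


class TestTargetedVsNull:
    def test_classification_bands(self, species_space):
        ids, means, ordn = species_space
        null = random_extinction_null(ordn.pc12, means, 4, n_reps=50, seed=2)["appd"]
        assert targeted_vs_null(null.mean, null) == "within"
        assert targeted_vs_null(null.lower - 1.0, null) == "below"
        assert targeted_vs_null(null.upper + 1.0, null) == "above"

    def test_intensity_mismatch_is_error(self, species_space):
        ids, means, ordn = species_space
        null = random_extinction_null(ordn.pc12, means, 4, n_reps=20, seed=2)["appd"]
        with pytest.raises(ValueError, match="intensity"):
            targeted_vs_null(null.mean, null, k=12)
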