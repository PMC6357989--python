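"""Moran's I, Gi* hot spots, SD layers — checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from needscape.spatial import (
    IslandWarning,
    benjamini_hochberg,
    classify_z,
    cumulative_need,
    distance_band_weights,
    hotspot_z,
    incremental_moran,
    morans_i,
    region_aggregate,
    sd_classes,
)

from conftest import rook_lattice


def moran_bruteforce(x, W):
    """Double-loop Moran's I (independent of the package implementation)."""
    n = len(x)
    z = x - x.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / (z @ z)


def gi_star_bruteforce(x, W):
    """Per-unit Gi* z-scores by direct evaluation."""
    n = len(x)
    xbar = x.mean()
    S = np.sqrt((x**2).mean() - xbar**2)
    out = np.zeros(n)
    for i in range(n):
        wi = W[i].sum()
        denom = S * np.sqrt((n * (W[i] ** 2).sum() - wi**2) / (n - 1))
        if denom > 0:
            out[i] = (W[i] @ x - xbar * wi) / denom
    return out


class TestDistanceBandWeights:
    def test_two_points_within_band(self):
        w = distance_band_weights(np.array([[0.0, 0.0], [1.0, 0.0]]), 1.5)
        assert w.s0 == 2.0

    def test_3x3_lattice_is_rook_adjacency(self):
        w = distance_band_weights(rook_lattice(3, 3), 1.0)
        assert w.s0 == 24.0  # 12 undirected neighbor pairs
        assert (w.W.toarray() == w.W.toarray().T).all()

    def test_all_islands_warn(self):
        with pytest.warns(IslandWarning):
            distance_band_weights(np.array([[0.0, 0.0], [5.0, 0.0]]), 1.0)

    def test_include_self_sets_diagonal(self):
        w = distance_band_weights(rook_lattice(2, 2), 1.0, include_self=True)
        assert (w.W.diagonal() == 1.0).all()

    def test_cached_sums_match_definitions(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, size=(30, 2))
        w = distance_band_weights(pts, 2.0)
        W = w.W.toarray()
        assert w.s0 == pytest.approx(W.sum())
        assert w.s1 == pytest.approx(0.5 * ((W + W.T) ** 2).sum())
        assert w.s2 == pytest.approx(((W.sum(1) + W.sum(0)) ** 2).sum())


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        pts = rook_lattice(4, 4)
        w = distance_band_weights(pts, 1.0)
        vals = np.array([(int(x) + int(y)) % 2 for x, y in pts], dtype=float)
        res = morans_i(vals, w)
        assert res.I == pytest.approx(-1.0)

    def test_expected_value_for_n10(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        w = distance_band_weights(pts, 1.0)
        res = morans_i(np.arange(10.0) ** 2, w)
        assert round(res.expected, 4) == -0.1111

    def test_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            pts = rng.uniform(0, 10, size=(n, 2))
            w = distance_band_weights(pts, 3.0)
            x = rng.normal(size=n)
            assert morans_i(x, w).I == pytest.approx(
                moran_bruteforce(x, w.W.toarray()), abs=1e-12
            )

    def test_permutation_mean_matches_expectation(self):
        rng = np.random.default_rng(5)
        pts = rook_lattice(6, 6)
        w = distance_band_weights(pts, 1.0)
        x = rng.normal(size=36)
        Is = [morans_i(rng.permutation(x), w).I for _ in range(1000)]
        assert np.mean(Is) == pytest.approx(-1 / 35, abs=3 * np.std(Is) / np.sqrt(1000))

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 5, size=(40, 2))
        w = distance_band_weights(pts, 2.0)
        x = rng.normal(size=40)
        r1, r2 = morans_i(x, w), morans_i(-3.0 * x + 7.0, w)
        assert r1.I == pytest.approx(r2.I) and r1.z == pytest.approx(r2.z)

    def test_constant_field_rejected(self):
        w = distance_band_weights(rook_lattice(3, 3), 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(9), w)

    def test_self_including_weights_rejected(self):
        w = distance_band_weights(rook_lattice(3, 3), 1.0, include_self=True)
        with pytest.raises(ValueError, match="self"):
            morans_i(np.arange(9.0), w)


class TestIncrementalMoran:
    def test_planted_cluster_peak_near_cluster_radius(self):
        rng = np.random.default_rng(2)
        pts = rook_lattice(10, 10)
        center = np.array([4.5, 4.5])
        radius = 2.0
        vals = rng.normal(0, 0.3, size=100)
        vals[np.linalg.norm(pts - center, axis=1) <= radius] += 2.0
        res = incremental_moran(vals, pts, np.array([1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]))
        assert radius / 2 <= res.peak_distance <= radius * 2

    def test_shuffled_values_rarely_significant(self):
        rng = np.random.default_rng(4)
        pts = rook_lattice(8, 8)
        base = rng.normal(size=64)
        hits = 0
        for _ in range(20):
            res = incremental_moran(
                rng.permutation(base), pts, np.array([1.0, 2.0, 3.0])
            )
            hits += (res.z > 1.96).any()
        assert hits <= 2  # >= 90% of seeds show no significant distance

    def test_single_distance_grid(self):
        pts = rook_lattice(5, 5)
        res = incremental_moran(np.arange(25.0), pts, np.array([1.0]))
        assert len(res.distances) == 1 and res.peak_distance == 1.0

    def test_island_distances_skipped(self):
        pts = rook_lattice(5, 5)
        res = incremental_moran(np.arange(25.0), pts, np.array([0.5, 1.0]))
        assert res.skipped == [0.5] and list(res.distances) == [1.0]

    def test_all_distances_skipped_is_error(self):
        pts = rook_lattice(4, 4)
        with pytest.raises(ValueError, match="islands"):
            incremental_moran(np.arange(16.0), pts, np.array([0.2, 0.5]))


class TestHotSpots:
    def test_constant_field_all_not_significant(self):
        w = distance_band_weights(rook_lattice(3, 3), 1.0, include_self=True)
        layer = hotspot_z(np.full(9, 2.5), w)
        assert (layer.z == 0).all() and (layer.classes == "ns").all()

    def test_isolated_spike_has_maximum_z(self):
        # one far-away unit with value 1 in a zero field, self-only neighborhood
        pts = np.vstack([rook_lattice(3, 3), [[10.0, 10.0]]])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IslandWarning)
            w = distance_band_weights(pts, 1.0, include_self=True)
        vals = np.zeros(10)
        vals[-1] = 1.0
        layer = hotspot_z(vals, w)
        assert layer.z.argmax() == 9

    def test_matches_bruteforce_on_random_fields(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            pts = rng.uniform(0, 10, size=(n, 2))
            w = distance_band_weights(pts, 3.0, include_self=True)
            x = rng.normal(size=n)
            np.testing.assert_allclose(
                hotspot_z(x, w).z, gi_star_bruteforce(x, w.W.toarray()), atol=1e-12
            )

    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 5, size=(30, 2))
        w = distance_band_weights(pts, 2.0, include_self=True)
        x = rng.normal(size=30)
        np.testing.assert_allclose(hotspot_z(x, w).z, hotspot_z(2.0 * x - 1.0, w).z)

    def test_class_ladder(self):
        z = np.array([-3.0, -2.0, -1.7, 0.0, 1.7, 2.0, 3.0])
        assert list(classify_z(z)) == [
            "cold99",
            "cold95",
            "cold90",
            "ns",
            "hot90",
            "hot95",
            "hot99",
        ]


class TestRegionLayers:
    def _households(self):
        rng = np.random.default_rng(6)
        communes = np.repeat([f"c{i}" for i in range(10)], 50)
        counties = np.repeat(["j0"] * 5 + ["j1"] * 5, 50)
        return pd.DataFrame(
            {
                "commune_id": communes,
                "county_id": counties,
                "need": rng.integers(0, 2, size=500),
            }
        )

    def test_weighted_prevalence_equals_overall(self):
        hh = self._households()
        agg = region_aggregate(hh, "commune", "need")
        weighted = (agg["prevalence"] * agg["n_households"]).sum() / agg["n_households"].sum()
        assert weighted == pytest.approx(hh["need"].mean())

    def test_equal_regions_fall_in_central_class(self):
        hh = pd.DataFrame(
            {
                "commune_id": np.repeat(["a", "b", "c"], 10),
                "county_id": "j0",
                "need": np.tile([0, 1], 15),
            }
        )
        agg = region_aggregate(hh, "commune", "need")
        assert (agg["sd_class"] == "m0.5_p0.5sd").all()

    def test_extreme_region_hits_top_class(self):
        vals = np.array([0.2] * 30 + [0.9])
        vals[:30] += np.linspace(-0.01, 0.01, 30)  # small spread
        classes = sd_classes(vals)
        assert classes[-1] == "gt_p2.5sd"

    def test_county_level_aggregates(self):
        agg = region_aggregate(self._households(), "county", "need")
        assert set(agg.index) == {"j0", "j1"}


class TestCumulativeNeed:
    def test_counts_included_flags(self):
        flags = pd.DataFrame(
            {"a": [1, 0, 1], "b": [1, 0, 0], "c": [1, 0, 1]}
        )
        assert list(cumulative_need(flags, ["a", "b", "c"])) == [3, 0, 2]

    def test_empty_include_set_rejected(self):
        with pytest.raises(ValueError):
            cumulative_need(pd.DataFrame({"a": [1]}), [])


def test_benjamini_hochberg_monotone():
    p = np.array([0.001, 0.01, 0.02, 0.04, 0.2, 0.9])
    mask = benjamini_hochberg(p, alpha=0.05)
    # 0.02 <= 0.05*3/6 rejects the first three; 0.04 > 0.05*4/6 stops there
    assert mask[:3].all() and not mask[3:].any()
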