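"""T cell/Treg proximity statistics against a brute-force oracle."""

import numpy as np
import pytest

from neocorr.errors import ParameterError
from neocorr.mif_quantification import assign_phenotypes
from neocorr.spatial_proximity import (
    ProximityConfig,
    ProximityResult,
    distance_distribution,
    mean_distance_by_class,
    proximity_by_class,
    proximity_pairs,
    proximity_shift,
)


def brute_force(tcells, tregs, radius, mode):
    """Exhaustive O(n*m) oracle sharing only the distance expression."""
    tcells = np.asarray(tcells, float).reshape(-1, 2)
    tregs = np.asarray(tregs, float).reshape(-1, 2)
    out = []
    for tx, ty in tcells:
        ds = np.sqrt((tx - tregs[:, 0]) ** 2 + (ty - tregs[:, 1]) ** 2)
        if mode == "pairwise":
            out.extend(ds[ds <= radius])
        elif len(ds):
            d = ds.min()
            if d <= radius:
                out.append(d)
    return np.sort(np.asarray(out))


class TestProximityPairs:
    def test_hand_example_3_4_5(self):
        # Treg at (30,40) is 50 um away; the one at (200,0) is out of radius
        res = proximity_pairs(np.array([[0.0, 0.0]]), np.array([[30.0, 40.0], [200.0, 0.0]]))
        assert res.n_pairs == 1
        assert res.mean_distance_um == pytest.approx(50.0)

    def test_coincident_cells_contribute_zero_distance(self):
        res = proximity_pairs(np.array([[5.0, 5.0]]), np.array([[5.0, 5.0]]))
        assert res.n_pairs == 1 and res.distances[0] == 0.0

    def test_all_tregs_beyond_radius(self):
        res = proximity_pairs(np.array([[0.0, 0.0]]), np.array([[500.0, 0.0]]))
        assert res.n_pairs == 0 and np.isnan(res.mean_distance_um)

    def test_no_tregs_is_sentinel_not_error(self):
        res = proximity_pairs(np.array([[0.0, 0.0]]), np.empty((0, 2)))
        assert res.n_pairs == 0 and np.isnan(res.mean_distance_um)

    @pytest.mark.parametrize("mode", ["pairwise", "nearest"])
    def test_matches_bruteforce_bit_exactly(self, mode):
        rng = np.random.default_rng(42)
        cfg = ProximityConfig(distribution_mode=mode)
        for _ in range(50):
            n, m = rng.integers(1, 60, size=2)
            t = rng.uniform(0, 400, size=(n, 2))
            g = rng.uniform(0, 400, size=(m, 2))
            ours = proximity_pairs(t, g, cfg)
            oracle = brute_force(t, g, cfg.radius_um, mode)
            assert ours.n_pairs == len(oracle)
            assert np.array_equal(ours.distances, oracle)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 300, size=(40, 2))
        g = rng.uniform(0, 300, size=(25, 2))
        base = proximity_pairs(t, g)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t2, g2 = t @ rot.T + 50.0, g @ rot.T + 50.0
        moved = proximity_pairs(t2, g2)
        assert moved.n_pairs == base.n_pairs
        np.testing.assert_allclose(moved.distances, base.distances, rtol=1e-9)

    def test_nearest_mean_le_pairwise_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = rng.uniform(0, 300, size=(50, 2))
            g = rng.uniform(0, 300, size=(30, 2))
            pw = proximity_pairs(t, g, ProximityConfig(distribution_mode="pairwise"))
            nn = proximity_pairs(t, g, ProximityConfig(distribution_mode="nearest"))
            if pw.n_pairs and nn.n_pairs:
                assert nn.mean_distance_um <= pw.mean_distance_um + 1e-12

    def test_edge_exclusion_drops_border_cells(self):
        cfg = ProximityConfig(edge_exclusion=True)
        t = np.array([[10.0, 200.0], [200.0, 200.0]])  # first is within 100 of border
        g = np.array([[210.0, 200.0]])
        res = proximity_pairs(t, g, cfg, bounds=(0, 0, 400, 400))
        assert res.n_pairs == 1 and res.distances[0] == pytest.approx(10.0)


class TestDistribution:
    def test_point_mass(self):
        centers, probs = distance_distribution([42.0] * 10, bin_width_um=5, radius_um=100)
        assert probs.sum() == pytest.approx(1.0)
        assert probs[np.argwhere((centers > 40) & (centers < 45))[0, 0]] == 1.0

    def test_uniform_distances_give_flat_curve(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 100, size=20000)
        _, probs = distance_distribution(d, bin_width_um=10, radius_um=100)
        np.testing.assert_allclose(probs, 0.1, atol=0.01)

    def test_normalization_for_any_input(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            d = rng.exponential(30, size=rng.integers(1, 200))
            _, probs = distance_distribution(d, bin_width_um=7, radius_um=120)
            assert probs.sum() == pytest.approx(1.0)

    def test_empty_sentinel(self):
        centers, probs = distance_distribution([], bin_width_um=5)
        assert centers.size == 0 and probs.size == 0

    def test_smoothing_preserves_mass(self):
        d = np.linspace(10, 90, 50)
        _, probs = distance_distribution(d, 5, 100, smooth_bandwidth_um=10)
        assert probs.sum() == pytest.approx(1.0)


class TestShift:
    def mk(self, distances):
        d = np.asarray(distances, float)
        return ProximityResult("x", len(d), d)

    def test_identity(self):
        r = self.mk([30, 50, 70])
        assert proximity_shift(r, r) == 0.0

    def test_halving_is_minus_one(self):
        assert proximity_shift(self.mk([80.0]), self.mk([40.0])) == pytest.approx(-1.0)

    def test_empty_sentinel(self):
        assert np.isnan(proximity_shift(self.mk([]), self.mk([40.0])))
        assert np.isnan(proximity_shift(self.mk([40.0]), self.mk([])))


class TestByClass:
    def test_planted_exclusion_recovered_and_permutation_null(self, tiny_cohort):
        """Ki67+ T cells sit farther from Tregs than Ki67- cells when the
        generator plants a 40 um exclusion; shuffling Ki67 labels erases it."""
        patient = next(p for p in tiny_cohort.patients if p.planted_responder)
        cells = assign_phenotypes(patient.cells_pre)
        res = proximity_by_class(cells)
        table = mean_distance_by_class(res).set_index("tcell_class")
        for lineage in ("CD8", "CD4"):
            assert (
                table.loc[f"Ki67+{lineage}", "mean_distance_um"]
                > table.loc[f"Ki67-{lineage}", "mean_distance_um"]
            )
        # permutation null: randomize Ki67 within the CD8 population
        rng = np.random.default_rng(0)
        gaps = []
        for _ in range(30):
            shuffled = cells.copy()
            is_cd8 = shuffled["phenotype"] == "CD8 T cell"
            vals = shuffled.loc[is_cd8, "ki67"].to_numpy()
            shuffled.loc[is_cd8, "ki67"] = rng.permutation(vals)
            r = proximity_by_class(shuffled)
            gaps.append(r["Ki67+CD8"].mean_distance_um - r["Ki67-CD8"].mean_distance_um)
        # after shuffling, the class means are equal within resampling error:
        # the mean shuffled gap is statistically indistinguishable from zero
        gaps = np.asarray(gaps)
        assert abs(gaps.mean()) < 3 * gaps.std(ddof=1) / np.sqrt(len(gaps))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"radius_um": 0}, {"bin_width_um": -1}, {"distribution_mode": "knn"}]
    )
    def test_bad_config(self, kwargs):
        with pytest.raises(ParameterError):
            ProximityConfig(**kwargs)
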