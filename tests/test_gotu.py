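"""gOTU clustering, adjusted Rand index, Chao1 and rarefaction."""

import numpy as np
import pandas as pd
import pytest

from evgtools.gotu import (
    adjusted_rand_index,
    average_linkage_cluster,
    chao1,
    cluster_sizes,
    composition,
    expected_richness,
    rarefaction,
    scan_cutoffs,
)


def _sg(ids, values):
    return pd.DataFrame(values, index=ids, columns=ids, dtype=float)


class TestClustering:
    def test_pair_above_cutoff_merges(self):
        sg = _sg(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        part = average_linkage_cluster(sg, 0.15)
        assert part["a"] == part["b"]

    def test_pair_below_cutoff_stays_split(self):
        sg = _sg(["a", "b"], [[1.0, 0.10], [0.10, 1.0]])
        part = average_linkage_cluster(sg, 0.15)
        assert part["a"] != part["b"]

    def test_average_linkage_blocks_weak_third(self):
        # S_G(a,b)=0.9; c at 0.1 to both: average linkage to {a,b} is 0.1,
        # below the 0.15 cutoff, so c stays a singleton
        sg = _sg(["a", "b", "c"], [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        part = average_linkage_cluster(sg, 0.15)
        assert part["a"] == part["b"] != part["c"]

    def test_cutoff_range_validated(self):
        sg = _sg(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError):
            average_linkage_cluster(sg, 0.0)

    def test_partition_nesting_in_cutoff(self, small_sg):
        """Raising the cutoff only splits, never merges."""
        parts = {c: average_linkage_cluster(small_sg, c) for c in (0.1, 0.3, 0.6)}
        ids = list(small_sg.index)
        for lo, hi in ((0.1, 0.3), (0.3, 0.6)):
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    if parts[hi][a] == parts[hi][b]:
                        assert parts[lo][a] == parts[lo][b]


class TestARI:
    def test_identical_partitions(self):
        p = {"a": 1, "b": 1, "c": 2}
        assert adjusted_rand_index(p, p) == 1.0

    def test_crossed_pairs_hand_value(self):
        p1 = {"a": 0, "b": 0, "c": 1, "d": 1}
        p2 = {"a": 0, "b": 1, "c": 0, "d": 1}
        assert adjusted_rand_index(p1, p2) == pytest.approx(-0.5)

    def test_symmetry(self, rng):
        items = [f"x{i}" for i in range(30)]
        p1 = {x: int(rng.integers(0, 4)) for x in items}
        p2 = {x: int(rng.integers(0, 4)) for x in items}
        assert adjusted_rand_index(p1, p2) == pytest.approx(adjusted_rand_index(p2, p1))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score

        items = [f"x{i}" for i in range(50)]
        for _ in range(20):
            p1 = {x: int(rng.integers(0, 6)) for x in items}
            p2 = {x: int(rng.integers(0, 6)) for x in items}
            ours = adjusted_rand_index(p1, p2)
            ref = adjusted_rand_score([p1[x] for x in items], [p2[x] for x in items])
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_random_relabeling_near_zero_mean(self, rng):
        items = [f"x{i}" for i in range(40)]
        p1 = {x: i % 5 for i, x in enumerate(items)}
        vals = []
        for _ in range(1000):
            perm = rng.permutation(5)
            p2 = {x: int(perm[rng.integers(0, 5)]) for x in items}
            vals.append(adjusted_rand_index(p1, p2))
        assert abs(np.mean(vals)) < 0.02

    def test_mismatched_items_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({"a": 1}, {"b": 1})


class TestScan:
    def test_grid_has_99_points(self):
        grid = np.arange(0.01, 1.0, 0.01)
        assert len(grid) == 99

    def test_planted_genera_recovered(self, small_community, small_sg):
        _, _, truth = small_community
        ev = scan_cutoffs(small_sg, truth.genus_of)
        assert ev.best_ari >= 0.9
        assert adjusted_rand_index(ev.best_partition, truth.genus_of) == ev.best_ari

    def test_requires_two_genera(self, small_sg):
        labels = {g: "only" for g in small_sg.index}
        with pytest.raises(ValueError):
            scan_cutoffs(small_sg, labels)

    def test_singleton_truth_edge(self):
        # all below the grid: every cutoff isolates singletons, ARI 1
        ids = ["a", "b", "c"]
        sg = _sg(ids, (np.eye(3) * 1.0).tolist())
        truth = {g: g for g in ids}
        ev = scan_cutoffs(sg, truth)
        assert np.allclose(ev.ari, 1.0)


class TestChao1:
    def test_no_singletons_collapses_to_sobs(self):
        assert chao1([3, 2, 2]) == 3

    def test_formula_arithmetic(self):
        # S_obs 10, f1=4, f2=2 -> 10 + 4*3/6 = 12
        sizes = [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]
        assert chao1(sizes) == pytest.approx(12.0)

    def test_all_singletons(self):
        n = 7
        assert chao1([1] * n) == pytest.approx(n + n * (n - 1) / 2)

    def test_classical_form_option(self):
        sizes = [1, 1, 1, 1, 2, 2, 3]
        assert chao1(sizes, bias_corrected=False) == pytest.approx(7 + 16 / 4)

    def test_matches_skbio(self, rng):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        for _ in range(20):
            sizes = [int(x) for x in rng.integers(1, 6, size=rng.integers(3, 15))]
            assert chao1(sizes) == pytest.approx(skbio_chao1(sizes))

    def test_chao1_at_least_observed(self, rng):
        for _ in range(50):
            sizes = [int(x) for x in rng.integers(1, 5, size=10)]
            assert chao1(sizes) >= len(sizes)


class TestRarefaction:
    def test_full_sample_gives_observed(self):
        sizes = [5, 3, 1, 1]
        assert expected_richness(sizes, sum(sizes)) == pytest.approx(len(sizes))

    def test_single_draw_gives_one(self):
        assert expected_richness([5, 3, 2], 1) == pytest.approx(1.0)

    def test_analytic_matches_resampling_oracle(self, rng):
        sizes = [6, 4, 2, 1, 1]
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        for m in (3, 7, 11):
            analytic = expected_richness(sizes, m)
            mc = np.mean([
                len(np.unique(rng.choice(labels, size=m, replace=False)))
                for _ in range(10_000)
            ])
            assert analytic == pytest.approx(mc, abs=0.05)

    def test_curve_with_bootstrap_ci(self):
        part = {f"g{i}": i % 4 for i in range(20)}
        curve = rarefaction(part, n_boot=100, seed=1)
        assert curve.expected[-1] == pytest.approx(curve.s_obs)
        assert np.all(curve.ci_low <= curve.ci_high + 1e-12)
        assert curve.chao1 >= curve.s_obs

    def test_monotone_expected_curve(self):
        part = {f"g{i}": i % 3 for i in range(12)}
        curve = rarefaction(part, n_boot=10, seed=2)
        assert np.all(np.diff(curve.expected) >= -1e-12)


class TestComposition:
    def test_three_cluster_example(self):
        part = {"e1": 1, "e2": 1, "r1": 2, "e3": 3, "r2": 3}
        src = {"e1": "EVG", "e2": "EVG", "e3": "EVG", "r1": "RVG", "r2": "RVG"}
        df = composition(part, src).set_index("category")
        assert df.loc["EVG", "share_by_cluster"] == pytest.approx(1 / 3)
        assert df.loc["RVG", "share_by_cluster"] == pytest.approx(1 / 3)
        assert df.loc["shared", "share_by_cluster"] == pytest.approx(1 / 3)
        assert df["share_by_cluster"].sum() == pytest.approx(1.0)
        assert df["share_by_genome"].sum() == pytest.approx(1.0)

    def test_no_shared_clusters(self):
        part = {"e1": 1, "r1": 2}
        src = {"e1": "EVG", "r1": "RVG"}
        df = composition(part, src)
        assert "shared" not in set(df["category"])

    def test_unlabelled_genome_rejected(self):
        with pytest.raises(ValueError):
            composition({"a": 1}, {})


def test_cluster_sizes_sorted():
    assert cluster_sizes({"a": 1, "b": 1, "c": 2}) == [2, 1]
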