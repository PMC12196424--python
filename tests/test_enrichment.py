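import numpy as np
import pytest
from scipy import stats as sps

from oracles import brute_force_counts, hypergeom_moments
from regionenrich.atlas_io import ExpressionAtlas, GeneList
from regionenrich.enrichment import (
    ObservedCounts,
    ReferenceDistribution,
    analytic_reference,
    observed_counts,
    score_regions,
    simulate_reference,
)
from regionenrich.high_expression import HighExpressionIndex, high_expression_sets


def index_from_sets(highsets: dict[str, set[str]], regions: list[str]) -> HighExpressionIndex:
    """Build an index directly from per-gene region sets (bypasses the atlas)."""
    genes = tuple(highsets)
    flags = np.array(
        [[r in highsets[g] for r in regions] for g in genes], dtype=bool
    )
    # stats are irrelevant for null sampling; synthesise a constant-zero one
    from regionenrich.high_expression import GeneRegionStats

    stats = GeneRegionStats(
        genes=genes, mean=np.zeros(len(genes)), sd=np.zeros(len(genes)), ddof=1
    )
    return HighExpressionIndex(
        genes=genes, regions=tuple(regions), flags=flags, z_high=1.96, stats=stats
    )


class TestObservedCounts:
    def test_empty_list_all_zero(self):
        index = index_from_sets({"g1": {"A"}, "g2": {"B"}}, ["A", "B"])
        obs = observed_counts(index, [])
        np.testing.assert_array_equal(obs.counts, [0, 0])
        assert obs.contributing == ((), ())

    def test_direct_enumeration(self):
        index = index_from_sets({"g1": {"A", "B"}, "g2": {"B"}}, ["A", "B"])
        obs = observed_counts(index, ["g1", "g2"])
        np.testing.assert_array_equal(obs.counts, [1, 2])
        assert obs.contributing == (("g1",), ("g1", "g2"))

    def test_counts_sum_equals_flagged_mass(self, planted_index):
        rng = np.random.default_rng(4)
        gene_list = list(rng.choice(planted_index.genes, size=50, replace=False))
        obs = observed_counts(planted_index, gene_list)
        highsets = {g: set(planted_index.regions_for(g)) for g in gene_list}
        oracle = brute_force_counts(highsets, list(planted_index.regions), gene_list)
        np.testing.assert_array_equal(
            obs.counts, [oracle[r] for r in planted_index.regions]
        )
        assert obs.counts.sum() == sum(len(s) for s in highsets.values())

    def test_unknown_gene_rejected(self):
        index = index_from_sets({"g1": {"A"}}, ["A"])
        with pytest.raises(KeyError):
            observed_counts(index, ["nope"])


class TestAnalyticReference:
    def test_zero_membership_region(self):
        index = index_from_sets({f"g{i}": set() for i in range(10)}, ["A"])
        ref = analytic_reference(index, X=5)
        assert ref.mean[0] == 0.0 and ref.sd[0] == 0.0

    def test_hypergeometric_formula(self):
        sets = {f"g{i}": ({"A"} if i < 4 else set()) for i in range(10)}
        ref = analytic_reference(index_from_sets(sets, ["A"]), X=5)
        assert ref.mean[0] == pytest.approx(2.0)
        assert ref.sd[0] == pytest.approx(0.8165, abs=1e-4)

    def test_full_draw_degenerate(self):
        sets = {f"g{i}": ({"A"} if i < 4 else set()) for i in range(10)}
        ref = analytic_reference(index_from_sets(sets, ["A"]), X=10)
        assert ref.sd[0] == 0.0
        assert ref.mean[0] == pytest.approx(4.0)

    def test_matches_scipy_hypergeom(self):
        G, m, X = 37, 11, 13
        sets = {f"g{i}": ({"A"} if i < m else set()) for i in range(G)}
        ref = analytic_reference(index_from_sets(sets, ["A"]), X=X)
        dist = sps.hypergeom(G, m, X)
        assert ref.mean[0] == pytest.approx(dist.mean())
        assert ref.sd[0] == pytest.approx(dist.std())


class TestSimulateReference:
    def test_full_universe_draw_is_exact(self):
        sets = {f"g{i}": ({"A"} if i < 4 else set()) for i in range(10)}
        index = index_from_sets(sets, ["A"])
        ref = simulate_reference(index, X=10, iterations=50, seed=0)
        assert ref.sd[0] == 0.0
        assert ref.mean[0] == 4.0

    def test_matches_hypergeometric_oracle(self):
        sets = {f"g{i}": ({"A"} if i < 4 else set()) for i in range(10)}
        index = index_from_sets(sets, ["A"])
        iters = 100_000
        ref = simulate_reference(index, X=5, iterations=iters, seed=7)
        mean, sd = hypergeom_moments(10, 4, 5)
        assert ref.mean[0] == pytest.approx(mean, abs=3 * sd / iters**0.5)
        assert ref.sd[0] == pytest.approx(sd, rel=0.05)

    def test_seed_determinism(self, planted_index):
        a = simulate_reference(planted_index, X=20, iterations=2000, seed=42)
        b = simulate_reference(planted_index, X=20, iterations=2000, seed=42)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)
        np.testing.assert_array_equal(a.max_count, b.max_count)

    def test_batching_does_not_change_results(self, planted_index):
        a = simulate_reference(planted_index, X=20, iterations=1000, seed=5, batch_size=1000)
        b = simulate_reference(planted_index, X=20, iterations=1000, seed=5, batch_size=137)
        # same seed, different batching -> same draws in the same order
        np.testing.assert_allclose(a.mean, b.mean)

    def test_histogram_consistent_with_moments(self, planted_index):
        ref = simulate_reference(
            planted_index, X=15, iterations=3000, seed=9, keep_histogram=True
        )
        assert ref.histogram.shape == (planted_index.n_regions, 16)
        counts = np.arange(16)
        np.testing.assert_array_equal(ref.histogram.sum(axis=1), 3000)
        hist_mean = (ref.histogram * counts).sum(axis=1) / 3000
        np.testing.assert_allclose(hist_mean, ref.mean, atol=1e-12)

    def test_universe_bounds(self):
        index = index_from_sets({f"g{i}": set() for i in range(5)}, ["A"])
        with pytest.raises(ValueError):
            simulate_reference(index, X=6, iterations=10, seed=0)
        with pytest.raises(ValueError):
            simulate_reference(index, X=0, iterations=10, seed=0)

    def test_exclude_empty_genes_shrinks_universe(self):
        sets = {"g1": {"A"}, "g2": set(), "g3": {"A"}}
        index = index_from_sets(sets, ["A"])
        full = analytic_reference(index, X=2, include_empty_genes=True)
        reduced = analytic_reference(index, X=2, include_empty_genes=False)
        assert full.universe_size == 3
        assert reduced.universe_size == 2
        assert reduced.mean[0] == pytest.approx(2.0)


def make_reference(regions, mean, sd, max_count=None, X=10):
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if max_count is None:
        max_count = np.full(len(regions), X)
    return ReferenceDistribution(
        regions=tuple(regions),
        mean=mean,
        sd=sd,
        max_count=np.asarray(max_count),
        X=X,
        iterations=1000,
        seed=0,
        universe_size=100,
    )


def make_observed(regions, counts, contributing=None):
    counts = np.asarray(counts, dtype=int)
    if contributing is None:
        contributing = tuple(tuple(f"g{i}" for i in range(c)) for c in counts)
    return ObservedCounts(regions=tuple(regions), counts=counts, contributing=contributing)


class TestScoreRegions:
    def test_observed_equal_to_mean(self):
        table = score_regions(
            make_observed(["A"], [2]), make_reference(["A"], [2.0], [1.0])
        )
        row = table.iloc[0]
        assert row["z"] == 0.0
        assert row["p"] == pytest.approx(0.5)
        assert not row["significant"]
        assert row["fold_enrichment"] == pytest.approx(1.0)

    def test_bonferroni_threshold_193(self):
        # per-test level 0.05/193 = 2.591e-4; one-sided z* ~ 3.4726
        per_test = 0.05 / 193
        assert per_test == pytest.approx(2.591e-4, rel=1e-3)
        z_star = sps.norm.isf(per_test)
        assert z_star == pytest.approx(3.47, abs=0.005)
        ref = make_reference(["A"], [10.0], [1.0])
        below = score_regions(
            make_observed(["A"], [13]), ref, alpha=0.05, n_tests=193
        )
        above = score_regions(
            make_observed(["A"], [14]), ref, alpha=0.05, n_tests=193
        )
        assert not below.iloc[0]["significant"]  # z = 3 < 3.47
        assert above.iloc[0]["significant"]  # z = 4 > 3.47

    def test_uncorrected_one_sided_is_1645(self):
        ref = make_reference(["A"], [10.0], [1.0])
        t = score_regions(make_observed(["A"], [12]), ref, correction="none")
        assert t.iloc[0]["significant"]  # z = 2 > 1.6449
        t = score_regions(make_observed(["A"], [11]), ref, correction="none")
        assert not t.iloc[0]["significant"]  # z = 1 < 1.6449

    def test_uncorrected_two_sided_is_196(self):
        # z = 1.7 sits between the one-sided (1.6449) and two-sided (1.96) cuts
        ref = make_reference(["A"], [10.0], [10.0])
        obs = make_observed(["A"], [27])
        one = score_regions(obs, ref, correction="none", tail="one")
        two = score_regions(obs, ref, correction="none", tail="two")
        assert one.iloc[0]["significant"]
        assert not two.iloc[0]["significant"]
        # z = 2 clears both
        t = score_regions(make_observed(["A"], [30]), ref, correction="none", tail="two")
        assert t.iloc[0]["significant"]

    def test_fold_enrichment_arithmetic(self):
        t = score_regions(make_observed(["A"], [10]), make_reference(["A"], [2.0], [1.0]))
        assert t.iloc[0]["fold_enrichment"] == pytest.approx(5.0)

    def test_fold_undefined_when_mean_zero(self):
        t = score_regions(
            make_observed(["A"], [3]), make_reference(["A"], [0.0], [1.0])
        )
        assert np.isnan(t.iloc[0]["fold_enrichment"])

    def test_z_squared_identity(self):
        t = score_regions(make_observed(["A"], [7]), make_reference(["A"], [2.0], [1.5]))
        assert t.iloc[0]["z_squared"] == t.iloc[0]["z"] ** 2

    def test_degenerate_sd_zero_above_max(self):
        ref = make_reference(["A"], [2.0], [0.0], max_count=[2])
        t = score_regions(make_observed(["A"], [3]), ref)
        assert t.iloc[0]["significant"]
        assert np.isnan(t.iloc[0]["z"])

    def test_degenerate_sd_zero_at_mean(self):
        ref = make_reference(["A"], [2.0], [0.0], max_count=[2])
        t = score_regions(make_observed(["A"], [2]), ref)
        assert not t.iloc[0]["significant"]

    def test_empirical_p_from_histogram(self, planted_index):
        ref = simulate_reference(
            planted_index, X=15, iterations=2000, seed=3, keep_histogram=True
        )
        rng = np.random.default_rng(0)
        genes = list(rng.choice(planted_index.genes, size=15, replace=False))
        obs = observed_counts(planted_index, genes)
        t = score_regions(obs, ref)
        for r in range(planted_index.n_regions):
            k = int(obs.counts[r])
            ge = ref.histogram[r, k:].sum()
            assert t.iloc[r]["p_empirical"] == pytest.approx((1 + ge) / 2001)

    def test_empirical_decision_requires_histogram(self):
        ref = make_reference(["A"], [2.0], [1.0])
        with pytest.raises(ValueError, match="keep_histogram"):
            score_regions(make_observed(["A"], [3]), ref, decision="empirical")

    def test_empirical_decision_thresholds_tail_probability(self, planted_index):
        ref = simulate_reference(
            planted_index, X=15, iterations=5000, seed=13, keep_histogram=True
        )
        rng = np.random.default_rng(14)
        genes = list(rng.choice(planted_index.genes, size=15, replace=False))
        obs = observed_counts(planted_index, genes)
        t = score_regions(obs, ref, decision="empirical", alpha=0.05)
        per_test = 0.05 / planted_index.n_regions
        np.testing.assert_array_equal(
            t["significant"].to_numpy(), t["p_empirical"].to_numpy() < per_test
        )

    def test_adding_contributing_gene_weakly_increases_z(self, planted_index):
        target = planted_index.regions[5]
        carriers = [g for g in planted_index.genes if target in planted_index.regions_for(g)]
        others = [g for g in planted_index.genes if g not in carriers]
        base_list = others[:20]
        ref = analytic_reference(planted_index, X=20)
        ref_plus = analytic_reference(planted_index, X=21)
        j = list(planted_index.regions).index(target)
        t0 = score_regions(observed_counts(planted_index, base_list), ref)
        t1 = score_regions(
            observed_counts(planted_index, base_list + [carriers[0]]), ref_plus
        )
        assert t1.iloc[j]["z"] >= t0.iloc[j]["z"]

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_regions(make_observed(["A"], [1]), make_reference(["B"], [1.0], [1.0]))
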