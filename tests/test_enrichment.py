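import itertools
from collections import Counter

import numpy as np
import pytest

import mirset as ms
from mirset.bitsets import OpCounters
from mirset.enrichment import pool_overlaps


def _bitsets(inter, ann=None):
    uni = ms.build_universe(inter, ann)
    return uni, ms.mirna_bitsets(inter, uni)


class TestSampleGroups:
    def test_deterministic_given_seed(self):
        pop = [f"m{i}" for i in range(30)]
        assert ms.sample_groups(pop, 5, 50, seed=7) == ms.sample_groups(pop, 5, 50, seed=7)
        assert ms.sample_groups(pop, 5, 50, seed=7) != ms.sample_groups(pop, 5, 50, seed=8)

    def test_full_size_groups_equal_population(self):
        pop = ["a", "b", "c"]
        for g in ms.sample_groups(pop, 3, 10, seed=1):
            assert sorted(g) == pop

    def test_members_distinct_and_from_population(self):
        pop = [f"m{i}" for i in range(10)]
        for g in ms.sample_groups(pop, 4, 100, seed=3):
            assert len(set(g)) == 4 and set(g) <= set(pop)

    def test_singletons_uniform_within_binomial_error(self):
        pop = [f"m{i}" for i in range(8)]
        n = 8000
        freq = Counter(g[0] for g in ms.sample_groups(pop, 1, n, seed=11))
        # each miRNA ~ Binomial(n, 1/8); 4-sigma band
        expect, sd = n / 8, (n * (1 / 8) * (7 / 8)) ** 0.5
        for m in pop:
            assert abs(freq[m] - expect) < 4 * sd

    def test_oversized_group_fatal(self):
        with pytest.raises(ms.LogicError):
            ms.sample_groups(["a", "b"], 3, 1, seed=0)


class TestBuildPool:
    def test_single_group_matches_direct_union(self, tiny_tables):
        inter, ann = tiny_tables
        _, bits = _bitsets(inter, ann)
        pool = ms.build_pool([("mir-a", "mir-b")], bits)
        assert pool.union_bitsets[0] == ms.group_union([bits["mir-a"], bits["mir-b"]])

    def test_identical_groups_identical_patterns(self, tiny_tables):
        inter, ann = tiny_tables
        _, bits = _bitsets(inter, ann)
        pool = ms.build_pool([("mir-a", "mir-c"), ("mir-a", "mir-c")], bits)
        assert np.array_equal(pool.matrix[0], pool.matrix[1])

    def test_cardinalities_match_set_union_oracle(self, small_scenario):
        inter, ann, _, truth = small_scenario
        _, bits = _bitsets(inter, ann)
        groups = ms.sample_groups(inter.mirna_ids(), 5, 100, seed=2)
        pool = ms.build_pool(groups, bits)
        for g, bs in zip(groups, pool.union_bitsets):
            assert bs.cardinality() == len(set().union(*(truth.targets[m] for m in g)))

    def test_union_counter_is_n_times_size(self, small_scenario):
        inter, ann, _, _ = small_scenario
        _, bits = _bitsets(inter, ann)
        groups = ms.sample_groups(inter.mirna_ids(), 7, 64, seed=2)
        c = OpCounters()
        ms.build_pool(groups, bits, c)
        assert c.union_ops == 64 * 7

    def test_unknown_member_fatal(self, tiny_tables):
        inter, ann = tiny_tables
        _, bits = _bitsets(inter, ann)
        with pytest.raises(ms.LogicError):
            ms.build_pool([("mir-a", "mir-z")], bits)


class TestEmpiricalPvalue:
    def _setup(self, tiny_tables):
        inter, ann = tiny_tables
        uni, bits = _bitsets(inter, ann)
        cats = {c.category_id: c for c in ms.category_indexes(ann, uni)}
        return uni, bits, cats

    def test_maximum_overlap_has_p_zero(self, tiny_tables):
        uni, bits, cats = self._setup(tiny_tables)
        pool = ms.build_pool(ms.sample_groups(sorted(bits), 2, 50, seed=1), bits)
        cat = cats["GO:1"]
        exceed, p = ms.empirical_pvalue(cat.size, pool, cat, ms.RunConfig(iterations=50))
        assert (exceed, p) == (0, 0.0)

    def test_tie_boundary_between_conventions(self, tiny_tables):
        uni, bits, cats = self._setup(tiny_tables)
        # all pool groups identical => all overlaps equal the query's
        pool = ms.build_pool([("mir-a", "mir-b")] * 10, bits)
        cat = cats["GO:1"]
        q = ms.probe_overlap(ms.group_union([bits["mir-a"], bits["mir-b"]]), cat)
        assert ms.empirical_pvalue(q, pool, cat, ms.RunConfig(strict_greater=True))[1] == 0.0
        assert ms.empirical_pvalue(q, pool, cat, ms.RunConfig(strict_greater=False))[1] == 1.0

    def test_plus_one_correction_never_zero(self, tiny_tables):
        uni, bits, cats = self._setup(tiny_tables)
        pool = ms.build_pool(ms.sample_groups(sorted(bits), 2, 20, seed=1), bits)
        cat = cats["GO:1"]
        _, p = ms.empirical_pvalue(cat.size, pool, cat,
                                   ms.RunConfig(plus_one_correction=True))
        assert p == pytest.approx(1 / 21)

    def test_monotone_in_query_overlap(self, small_scenario):
        inter, ann, _, _ = small_scenario
        uni, bits = _bitsets(inter, ann)
        cat = ms.category_indexes(ann, uni)[0]
        pool = ms.build_pool(ms.sample_groups(inter.mirna_ids(), 5, 500, seed=9), bits)
        cfg = ms.RunConfig()
        ps = [ms.empirical_pvalue(q, pool, cat, cfg)[1] for q in range(1, cat.size + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_p_lies_on_achievable_grid(self, small_scenario):
        inter, ann, _, _ = small_scenario
        uni, bits = _bitsets(inter, ann)
        cat = ms.category_indexes(ann, uni)[0]
        n = 40
        pool = ms.build_pool(ms.sample_groups(inter.mirna_ids(), 5, n, seed=9), bits)
        _, p = ms.empirical_pvalue(1, pool, cat, ms.RunConfig())
        assert p in {k / n for k in range(n + 1)}


def brute_force_pvalues(truth, categories, query, groups, strict=True):
    """Independent oracle: plain python sets over explicitly given groups."""
    q_union = set().union(*(truth.targets[m] for m in query))
    out = {}
    for cid, (_, genes) in categories.items():
        gs = set(genes) & {g for ts in truth.targets.values() for g in ts}
        q = len(q_union & gs)
        if q == 0:
            out[cid] = (None, None)
            continue
        hits = [len(set().union(*(truth.targets[m] for m in g)) & gs) for g in groups]
        exceed = sum(1 for h in hits if (h > q if strict else h >= q))
        out[cid] = (exceed, exceed / len(groups))
    return out


class TestRunEnrichment:
    def test_exhaustive_enumeration_matches_brute_force(self):
        # 6 miRNAs, groups of 2 -> 15 possible groups; exact null distribution
        cfg = ms.ScenarioConfig(
            n_mirnas=6, n_genes=60, n_categories=8, query_size=2, seed=13,
            category_size_law=(5, 15),
            target_count_law=ms.TargetCountLaw(np.log(12), 0.6, 3, 30),
        )
        inter, ann, query, truth = ms.generate_scenario(cfg)
        groups = ms.all_groups(inter.mirna_ids(), 2)
        assert len(groups) == 15
        res, rep = ms.run_enrichment(query, inter, ann, ms.RunConfig(), groups=groups)
        oracle = brute_force_pvalues(truth, truth.categories, query.mirna_ids, groups)
        assert len(res) > 0
        for r in res:
            assert (r.exceed_count, r.empirical_p) == oracle[r.category_id]

    def test_bitset_and_naive_engines_identical(self, small_scenario, tmp_path):
        inter, ann, query, _ = small_scenario
        kw = dict(iterations=400, seed=5)
        res_b, rep_b = ms.run_enrichment(query, inter, ann, ms.RunConfig(engine="bitset", **kw))
        res_n, rep_n = ms.run_enrichment(query, inter, ann, ms.RunConfig(engine="naive", **kw))
        for a, b in zip(res_b, res_n):
            assert (a.category_id, a.exceed_count, a.empirical_p, a.significance) == (
                b.category_id, b.exceed_count, b.empirical_p, b.significance)
        assert (rep_b.union_ops, rep_b.probe_ops) == (rep_n.union_ops, rep_n.probe_ops)
        pb, pn = tmp_path / "b.csv", tmp_path / "n.csv"
        ms.write_results(res_b, pb)
        ms.write_results(res_n, pn)
        assert pb.read_bytes() == pn.read_bytes()

    def test_worker_count_does_not_change_results(self, small_scenario):
        inter, ann, query, _ = small_scenario
        runs = [
            ms.run_enrichment(query, inter, ann,
                              ms.RunConfig(iterations=300, seed=8, workers=w))[0]
            for w in (1, 2, 4)
        ]
        for other in runs[1:]:
            for a, b in zip(runs[0], other):
                assert (a.category_id, a.exceed_count, a.empirical_p) == (
                    b.category_id, b.exceed_count, b.empirical_p)

    def test_zero_overlap_categories_reported_na(self, tiny_tables):
        inter, ann = tiny_tables
        query = ms.QueryGroup(["mir-c"])  # targets only g4 -> GO:1, GO:3 untouched
        res, rep = ms.run_enrichment(query, inter, ann, ms.RunConfig(iterations=20, seed=1))
        by_id = {r.category_id: r for r in res}
        assert by_id["GO:1"].empirical_p is None and by_id["GO:1"].significance is None
        assert by_id["GO:2"].empirical_p is not None
        assert rep.n_excluded == 2 and rep.n_tested == 1

    def test_absent_query_mirnas_dropped_or_fatal(self, tiny_tables):
        inter, ann = tiny_tables
        res, rep = ms.run_enrichment(ms.QueryGroup(["mir-a", "mir-zzz"]), inter, ann,
                                     ms.RunConfig(iterations=10, seed=1))
        assert rep.dropped_query_mirnas == ["mir-zzz"] and rep.group_size == 1
        with pytest.raises(ms.LogicError):
            ms.run_enrichment(ms.QueryGroup(["mir-zzz"]), inter, ann)

    def test_operation_counters_match_formulas(self, small_scenario):
        inter, ann, query, _ = small_scenario
        n, size = 250, len(query.mirna_ids)
        res, rep = ms.run_enrichment(query, inter, ann, ms.RunConfig(iterations=n, seed=3))
        assert rep.union_ops == n * size + size
        tested_sizes = sum(r.category_size for r in res if r.tested)
        all_sizes = sum(r.category_size for r in res)
        assert rep.probe_ops == n * tested_sizes + all_sizes

    def test_planted_category_attains_smallest_p(self):
        cfg = ms.ScenarioConfig(
            n_mirnas=120, n_genes=1500, n_categories=15, seed=21,
            category_size_law=(20, 40),
            target_count_law=ms.TargetCountLaw(np.log(30), 1.0, 5, 300),
            planted=ms.PlantedSignal("CAT:0007", query_size=6, coverage_fraction=1.0),
        )
        inter, ann, query, truth = ms.generate_scenario(cfg)
        res, _ = ms.run_enrichment(query, inter, ann, ms.RunConfig(iterations=1500, seed=2))
        tested = [r for r in res if r.tested]
        best = min(tested, key=lambda r: r.empirical_p)
        assert best.category_id == "CAT:0007"
        assert res[0].category_id == "CAT:0007"  # sorted output leads with it

    def test_degenerate_full_population_query(self, tiny_tables):
        inter, ann = tiny_tables
        query = ms.QueryGroup(inter.mirna_ids())
        res, _ = ms.run_enrichment(query, inter, ann, ms.RunConfig(iterations=30, seed=4))
        assert all(r.empirical_p == 0.0 for r in res if r.tested)

    def test_exclude_query_from_null_pool(self, small_scenario):
        inter, ann, query, _ = small_scenario
        cfg = ms.RunConfig(iterations=50, seed=6, exclude_query_from_null=True)
        groups = ms.sample_groups(
            [m for m in inter.mirna_ids() if m not in set(query.mirna_ids)],
            len(query.mirna_ids), 50, seed=6)
        res_a, _ = ms.run_enrichment(query, inter, ann, cfg)
        res_b, _ = ms.run_enrichment(query, inter, ann,
                                     ms.RunConfig(iterations=50, seed=6), groups=groups)
        for a, b in zip(res_a, res_b):
            assert (a.category_id, a.exceed_count) == (b.category_id, b.exceed_count)


def test_pool_overlaps_counts_probes():
    inter = ms.InteractionTable([("m1", "g1"), ("m1", "g2"), ("m2", "g3")])
    uni = ms.build_universe(inter)
    bits = ms.mirna_bitsets(inter, uni)
    pool = ms.build_pool([("m1",), ("m2",)], bits)
    cat = ms.CategoryIndex("c", "c", np.array([0, 2]))
    c = OpCounters()
    ov = pool_overlaps(pool, cat, c)
    assert list(ov) == [1, 1] and c.probe_ops == 2 * 2
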