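import numpy as np
import pandas as pd
import pytest

import oracles
from tagarray import (
    LDGraph,
    apply_capacity,
    build_precincts,
    select_tags,
    select_tags_exact,
    select_tags_greedy,
)
from tagarray.tagging import (
    InfeasibleCapacityError,
    Precinct,
    PrecinctTooLargeError,
)


def graph(edges, universe=None, r2_min=0.8):
    edges = [(str(a), str(b), r) for a, b, r in edges]
    g = LDGraph(edges, r2_min=r2_min, window_bp=10**6)
    if universe is not None:
        g.nodes = frozenset(str(u) for u in universe)
    return g


def random_graph(rng, n, p):
    nodes = [f"n{k:02d}" for k in range(n)]
    edges = [
        (a, b, float(rng.uniform(0.8, 1.0)))
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if rng.random() < p
    ]
    return nodes, edges


def ann_for(tags, mafs, must=None):
    must = must or set()
    return pd.DataFrame(
        {
            "id": list(tags),
            "maf": list(mafs),
            "design_score": 0.9,
            "on_scaffold": False,
            "must_include": [t in must for t in tags],
        }
    )


class TestBuildPrecincts:
    def test_components_with_singletons(self):
        g = graph([(1, 2, 0.9), (2, 3, 0.85)], universe=[1, 2, 3, 4, 5])
        ps = build_precincts(g, {"1", "2", "3", "4", "5"})
        assert sorted(p.members for p in ps) == [("1", "2", "3"), ("4",), ("5",)]

    def test_empty_graph_all_singletons(self):
        g = graph([], universe=["a", "b"])
        ps = build_precincts(g, {"a", "b"})
        assert all(p.size == 1 for p in ps) and len(ps) == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            nodes, edges = random_graph(rng, 50, 0.03)
            g = graph(edges, universe=nodes)
            got = {frozenset(p.members) for p in build_precincts(g, nodes)}
            assert got == oracles.union_find_components(
                nodes, [(a, b) for a, b, _ in edges]
            )

    def test_node_outside_universe_rejected(self):
        g = graph([(1, 2, 0.9)])
        with pytest.raises(ValueError):
            build_precincts(g, {"1"})


def precinct_of(edges, members=None):
    if members is None:
        members = sorted({x for e in edges for x in e[:2]})
    return Precinct(tuple(sorted(members)), tuple(edges))


class TestSelectTagsExact:
    def test_path3_dominating_center(self):
        p = precinct_of([("1", "2", 0.9), ("2", "3", 0.9)])
        assert select_tags_exact(p) == ["2"]

    def test_path5_minimum_two(self):
        edges = [(str(i), str(i + 1), 0.9) for i in range(1, 5)]
        p = precinct_of(edges)
        chosen = select_tags_exact(p)
        assert len(chosen) == 2
        assert oracles.is_dominating(p.members, [(a, b) for a, b, _ in edges], chosen)

    def test_singleton(self):
        p = precinct_of([], members=["z"])
        assert select_tags_exact(p) == ["z"]

    def test_cap_refused(self):
        members = [f"m{k}" for k in range(20)]
        p = precinct_of([], members=members)
        with pytest.raises(PrecinctTooLargeError):
            select_tags_exact(p, cap=15)

    def test_deterministic_lexicographic_optimum(self):
        # square: two optimal singletons do not exist; {a,c} vs {a,d} vs ... ->
        # lexicographically smallest optimum must be returned every time
        edges = [("a", "b", 0.9), ("b", "c", 0.9), ("c", "d", 0.9), ("d", "a", 0.9)]
        p = precinct_of(edges)
        assert select_tags_exact(p) == ["a", "b"]


class TestSelectTagsGreedy:
    def test_star_center(self):
        edges = [("c", f"l{k}", 0.9) for k in range(5)]
        p = precinct_of(edges)
        assert select_tags_greedy(p) == ["c"]

    def test_path5_matches_exact(self):
        edges = [(str(i), str(i + 1), 0.9) for i in range(1, 5)]
        p = precinct_of(edges)
        assert len(select_tags_greedy(p)) == len(select_tags_exact(p)) == 2

    def test_maf_tiebreak(self):
        # complete triangle: any vertex dominates; higher-MAF one must win
        edges = [("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)]
        p = precinct_of(edges)
        assert select_tags_greedy(p, maf={"a": 0.1, "b": 0.3, "c": 0.2}) == ["b"]
        # without MAF the smaller id wins the tie
        assert select_tags_greedy(p) == ["a"]

    def test_greedy_never_beats_exact_and_always_covers(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            nodes, edges = random_graph(rng, int(rng.integers(2, 11)), 0.3)
            comps = oracles.union_find_components(nodes, [(a, b) for a, b, _ in edges])
            for comp in comps:
                sub = [e for e in edges if e[0] in comp]
                p = precinct_of(sub, members=comp)
                ex = select_tags_exact(p)
                gr = select_tags_greedy(p)
                pairs = [(a, b) for a, b, _ in sub]
                assert len(gr) >= len(ex)
                assert oracles.is_dominating(p.members, pairs, gr)
                assert oracles.is_dominating(p.members, pairs, ex)


class TestSelectTags:
    def test_two_disjoint_edges(self):
        g = graph([(1, 2, 0.9), (3, 4, 0.9)], universe=[1, 2, 3, 4])
        sel = select_tags(g, {"1", "2", "3", "4"})
        assert sel.n_tags == 2

    def test_singletons_tag_themselves(self):
        universe = [f"u{k}" for k in range(10)]
        g = graph([], universe=universe)
        sel = select_tags(g, universe)
        assert sorted(sel.tags) == sorted(universe)
        assert all(sel.cover[u] == (u, 1.0) for u in universe)

    def test_cover_complete_at_threshold(self):
        rng = np.random.default_rng(11)
        nodes, edges = random_graph(rng, 40, 0.08)
        g = graph(edges, universe=nodes)
        sel = select_tags(g, nodes)
        for n in nodes:
            tag, r2 = sel.cover[n]
            assert r2 >= (1.0 if tag == n else g.r2_min)

    def test_exact_sizes_match_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(2, 13))
            nodes, edges = random_graph(rng, n, float(rng.uniform(0.1, 0.5)))
            g = graph(edges, universe=nodes)
            sel = select_tags(g, nodes, exact_cap=12)
            for p in build_precincts(g, nodes):
                chosen = [t for t in sel.tags if t in p.members]
                assert len(chosen) == oracles.min_dominating_set_size(
                    p.members, [(a, b) for a, b, _ in p.edges]
                )
                checked += 1
        assert checked > 60

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        nodes, edges = random_graph(rng, 30, 0.1)
        g = graph(edges, universe=nodes)
        s1 = select_tags(g, nodes)
        s2 = select_tags(g, nodes)
        assert s1.tags == s2.tags and s1.cover == s2.cover


class TestApplyCapacity:
    def _selection(self, mafs, must=None):
        ids = [f"t{k}" for k in range(len(mafs))]
        g = graph([], universe=ids)
        sel = select_tags(g, ids)
        return sel, ann_for(ids, mafs, must=must)

    def test_capacity_sufficient_identity(self):
        sel, ann = self._selection([0.02, 0.3])
        out, floor, report = apply_capacity(sel, ann, capacity=5)
        assert out.tags == sel.tags and floor == 0.01 and report.empty

    def test_linear_scan_example(self):
        sel, ann = self._selection([0.010, 0.012, 0.020, 0.050])
        out, floor, _ = apply_capacity(sel, ann, capacity=2, floor_step=0.001)
        assert floor == pytest.approx(0.013)
        assert len(out.tags) == 2

    def test_capacity_zero_all_lost(self):
        sel, ann = self._selection([0.02, 0.05])
        out, floor, report = apply_capacity(sel, ann, capacity=0)
        assert out.tags == [] and len(report) == 2

    def test_must_include_never_removed(self):
        sel, ann = self._selection([0.011, 0.02, 0.4], must={"t0"})
        out, _, _ = apply_capacity(sel, ann, capacity=2)
        assert "t0" in out.tags and len(out.tags) == 2

    def test_infeasible_capacity(self):
        sel, ann = self._selection([0.02, 0.05], must={"t0", "t1"})
        with pytest.raises(InfeasibleCapacityError):
            apply_capacity(sel, ann, capacity=1)

    def test_matches_linear_scan_oracle_and_monotone(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            mafs = np.round(rng.uniform(0.01, 0.5, size=n), 3).tolist()
            must = set(
                f"t{k}" for k in range(n) if rng.random() < 0.05
            )
            sel, ann = self._selection(mafs, must=must)
            cap = int(rng.integers(len(must), n + 2))
            out, floor, _ = apply_capacity(sel, ann, capacity=cap)
            o_floor, o_kept = oracles.linear_scan_min_floor(
                mafs, [f"t{k}" in must for k in range(n)], cap, 0.01, 0.001
            )
            assert floor == pytest.approx(o_floor)
            assert len(out.tags) == o_kept
            # monotone: more capacity, no higher floor, no fewer tags
            out2, floor2, _ = apply_capacity(sel, ann, capacity=cap + 3)
            assert floor2 <= floor + 1e-12
            assert len(out2.tags) >= len(out.tags)

    def test_reselect_recovers_floor_eligible_orphans(self):
        # tag 'a' (low maf) covers 'b' (high maf); raising the floor drops 'a';
        # with reselect on, 'b' becomes its own tag instead of going uncovered
        g = graph([("a", "b", 0.9), ("c", "d", 0.85)], universe=["a", "b", "c", "d"])
        ann = ann_for(["a", "b", "c", "d"], [0.011, 0.3, 0.25, 0.24])
        sel = select_tags(g, ["a", "b", "c", "d"], maf={"a": 0.011, "b": 0.3, "c": 0.25, "d": 0.24})
        out_plain, floor_p, rep_plain = apply_capacity(sel, ann, capacity=2)
        out_rs, floor_rs, rep_rs = apply_capacity(sel, ann, capacity=2, reselect=True)
        eligible_lost = [
            r for _, r in rep_rs.iterrows()
            if float(ann.set_index("id").loc[r["id"], "maf"]) >= floor_rs
        ]
        assert eligible_lost == []
        assert len(out_rs.tags) <= 2
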