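"""Cross-referencing: per-seed above-chance tests, leading-edge flag
chi-square, PPI filtering and partner-threshold Fisher tests."""

import pytest

from coseed import (
    CorrelateList,
    PPIEdgeList,
    count_above_chance,
    le_flag_chisq,
    mc_minus_le_fet,
    per_seed_chance_test,
    ppi_mc_filter,
)
from coseed.correlation import CorrelateEntry
from coseed.crossref import MCPartnership

from test_stats import hypergeom_upper_tail


def _cl(seed, genes, eligible=True):
    return CorrelateList(
        seed_id=seed,
        entries=[CorrelateEntry(g, 0.8, 3) for g in genes],
        eligible=eligible,
    )


class TestPerSeedChance:
    def test_reference_universe_rounds_to_seven_percent(self):
        universe = {f"m{i}" for i in range(1500)}
        clist = _cl("m0", [f"m{i}" for i in range(1, 3)])
        _obs, expected, _res, _ = per_seed_chance_test(clist, universe, 23_000)
        assert expected == pytest.approx(1500 / 23_000)
        assert round(100 * expected) == 7

    def test_zero_annotated_in_list_is_not_above_chance(self):
        universe = {f"m{i}" for i in range(100)}
        clist = _cl("m0", [f"x{i}" for i in range(50)])
        obs, _exp, res, above = per_seed_chance_test(clist, universe, 1000)
        assert obs == 0.0 and not above

    def test_empty_list_gives_p_one(self):
        universe = {"m1", "m2"}
        _obs, _exp, res, above = per_seed_chance_test(_cl("m0", []), universe, 100)
        assert res.p_value == 1.0 and not above

    def test_planted_half_annotated_list_verified_by_hypergeometric_oracle(self):
        universe = {f"m{i}" for i in range(1610)}  # 7% of 23,000
        hits = [f"m{i}" for i in range(1, 51)]
        misses = [f"x{i}" for i in range(50)]
        clist = _cl("m0", hits + misses)
        obs, exp, res, above = per_seed_chance_test(clist, universe, 23_000)
        assert obs == pytest.approx(0.5) and above
        a, b = 50, 50
        c = 1610 - 50
        d = 23_000 - a - b - c
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(a, b, c, d), rel=1e-9
        )

    def test_count_above_chance_requires_eligible_lists(self):
        with pytest.raises(ValueError):
            count_above_chance([_cl("s", [], eligible=False)], {"s"}, 100)

    def test_all_empty_lists_count_zero(self):
        lists = [_cl("s1", []), _cl("s2", [])]
        count, frac = count_above_chance(lists, {"s1", "s2"}, 100)
        assert count == 0 and frac == 0.0


class TestLeFlagChisq:
    def test_independent_flags_score_near_zero(self):
        universe = {f"g{i}" for i in range(100)}
        le = {f"g{i}" for i in range(50)}
        flag = {f"g{i}" for i in range(0, 100, 2)}  # every other gene
        res = le_flag_chisq(le, flag, universe)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_counts_match_brute_force_set_intersection(self):
        universe = {f"g{i}" for i in range(60)}
        le = {f"g{i}" for i in range(20)}
        flag = {f"g{i}" for i in range(10, 40)}
        exclude = {f"g{i}" for i in range(5)}
        res = le_flag_chisq(le, flag, universe, exclude=exclude)
        pop = universe - exclude
        a = len(le & flag & pop)
        b = len((le & pop) - flag)
        c = len((flag & pop) - le)
        d = len(pop - le - flag)
        assert res.table == ((a, b), (c, d))

    def test_exclusion_removes_seed_contribution(self):
        universe = {f"g{i}" for i in range(40)}
        seeds = {f"g{i}" for i in range(10)}
        le = {f"g{i}" for i in range(15)}
        flag = {f"g{i}" for i in range(12)}
        res = le_flag_chisq(le, flag, universe, exclude=seeds)
        assert sum(res.table[0]) + sum(res.table[1]) == 30


class TestPPIFilter:
    def test_same_class_edges_dropped(self):
        edges = PPIEdgeList(edges={("p1", "p2"), ("q1", "q2"), ("p1", "q1")})
        kept, part = ppi_mc_filter(edges, {"p1", "p2"})
        assert kept.edges == {("p1", "q1")}
        assert part.mc_minus_partners == {"q1": 1}

    def test_star_graph_counts_distinct_annotated_partners(self):
        mc = {"m1", "m2", "m3", "m4"}
        edges = PPIEdgeList(edges={("x", m) for m in mc} | {("x", "y"), ("x", "z")})
        _kept, part = ppi_mc_filter(edges, mc)
        assert part.mc_minus_partners["x"] == 4

    def test_self_pairs_rejected_by_edge_list(self):
        with pytest.raises(ValueError):
            PPIEdgeList(edges={("a", "a")})


class TestMcMinusLeFet:
    def test_threshold_above_all_counts_gives_p_one(self):
        part = MCPartnership(mc_minus_partners={"x": 2, "y": 1})
        res = mc_minus_le_fet(part, {"x"}, {"x", "y", "z"}, min_partners=5)
        assert res.p_value == 1.0

    def test_counts_verified_by_brute_force_on_small_universe(self):
        universe = {f"g{i}" for i in range(100)}
        mc = {f"g{i}" for i in range(10)}
        part = MCPartnership(
            mc_minus_partners={f"g{i}": (i % 4) + 1 for i in range(10, 60)}
        )
        le = {f"g{i}" for i in range(5, 40)}
        for t in (1, 2, 5):
            res = mc_minus_le_fet(part, le, universe, t, mc_set=mc)
            pop = universe - mc
            retained = {p for p, c in part.mc_minus_partners.items() if c >= t} & pop
            a = len(retained & le)
            b = len(le & pop) - a
            c = len(retained) - a
            d = len(pop) - a - b - c
            if retained:
                assert res.table == ((a, b), (c, d))
                assert res.p_value == pytest.approx(
                    hypergeom_upper_tail(a, b, c, d), rel=1e-9
                )
            else:
                assert res.p_value == 1.0

    def test_min_partners_must_be_positive(self):
        with pytest.raises(ValueError):
            mc_minus_le_fet(MCPartnership(), set(), {"a"}, 0)
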