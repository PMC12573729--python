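"""Clock conversions, congruence classification and the turnover estimator."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolbshift import divtime
from wolbshift.divtime import ClockConfig, Isolate, TimeRange


class TestDistances:
    @pytest.mark.parametrize("ani,expected", [(100.0, 0.0), (99.0, 0.01)])
    def test_ani_to_distance(self, ani, expected):
        assert divtime.ani_to_distance(ani) == pytest.approx(expected)

    def test_p_distance_counts_comparable_sites(self):
        a = "A" * 99 + "C"
        b = "A" * 100
        assert divtime.p_distance(a, b) == pytest.approx(0.01)

    def test_p_distance_skips_ambiguous(self):
        assert divtime.p_distance("ANCG", "ATCG") == 0.0

    def test_p_distance_length_mismatch(self):
        with pytest.raises(ValueError):
            divtime.p_distance("ACGT", "ACG")


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert divtime.jc_correct(0.0) == 0.0

    def test_small_distance_closed_form(self):
        # high-precision evaluation of -(3/4) ln(1 - (4/3) 0.01)
        assert divtime.jc_correct(0.01) == pytest.approx(0.0100672652491055151, abs=1e-12)

    def test_monotone(self):
        assert divtime.jc_correct(0.02) > divtime.jc_correct(0.01)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="[Ss]aturated"):
            divtime.jc_correct(0.75)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=0.70))
    def test_inverse_recovers_distance(self, d):
        d_jc = divtime.jc_correct(d)
        assert abs(divtime.jc_expected_p(d_jc) - d) < 1e-12


class TestSplitRanges:
    def test_zero_distance_gives_zero_range(self):
        gen, years = divtime.wolb_split_range(0.0)
        assert (gen.lo, gen.hi) == (0.0, 0.0)
        assert (years.lo, years.hi) == (0.0, 0.0)

    def test_generation_bounds_arithmetic(self):
        gen, _ = divtime.wolb_split_range(3e-4)
        assert gen.lo == pytest.approx(1.0e5)
        assert gen.hi == pytest.approx(5.4348e5, rel=1e-4)

    def test_default_rate_bounds(self):
        clock = ClockConfig()
        assert clock.wolb_rate_min == 2.76e-10
        assert clock.wolb_rate_max == 1.5e-9

    def test_strict_interval_when_distance_positive(self):
        gen, years = divtime.wolb_split_range(1e-5)
        assert gen.lo < gen.hi
        assert years.lo < years.hi

    @pytest.mark.parametrize(
        "d,lo,hi",
        [(0.023, 1.0, None), (0.0, 0.0, 0.0), (0.015, None, 1.0)],
    )
    def test_mito_range_rates(self, d, lo, hi):
        r = divtime.mito_split_range(d)
        if lo is not None:
            assert r.lo == pytest.approx(lo)
        if hi is not None:
            assert r.hi == pytest.approx(hi)


# Hand-enumerated truth table of range relationships (symbiont vs host).
CONGRUENCE_CASES = [
    ((1, 3), (0, 4), "congruent"),   # containment, symbiont narrower
    ((0, 4), (1, 3), "congruent"),   # containment, host narrower
    ((0, 10), (4, 6), "congruent"),  # midpoint of larger inside smaller
    ((4, 6), (0, 10), "congruent"),  # same, arguments swapped
    ((5, 6), (1, 2), "older"),       # disjoint, symbiont later
    ((1, 2), (5, 6), "younger"),     # disjoint, symbiont earlier
    ((2, 8), (1, 4), "older"),       # overlap, no containment, mid(L)=5>4
    ((1, 4), (2, 8), "younger"),     # mirrored
    ((0, 2), (1, 3), "congruent"),   # equal widths, mid of host inside symbiont
    ((0, 4), (3, 7), "younger"),     # equal widths, overlap, midpoints apart
    ((3, 7), (0, 4), "older"),       # mirrored
    ((2, 2), (1, 3), "congruent"),   # point range inside host range
    ((0, 0), (1, 5), "younger"),     # point range outside host range
]


class TestCongruence:
    @pytest.mark.parametrize("w,h,expected", CONGRUENCE_CASES)
    def test_truth_table(self, w, h, expected):
        rw = TimeRange(*w)
        rh = TimeRange(*h)
        assert divtime.classify_congruence(rw, rh) == expected

    def test_unit_mismatch_raises(self):
        with pytest.raises(ValueError, match="unit"):
            divtime.classify_congruence(
                TimeRange(0, 1, "My"), TimeRange(0, 1, "generations")
            )


class TestCategorize:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("x1", "sp1", "w1"), ("x2", "sp1", "w1"), "intraspecific_intrastrain"),
            (("x1", "sp1", "w1"), ("x2", "sp1", "w2"), "intraspecific_interstrain"),
            (("x1", "sp1", "w1"), ("x2", "sp2", "w1"), "interspecific_intrastrain"),
            (("x1", "sp1", "w1"), ("x2", "sp2", "w2"), "interspecific_interstrain"),
        ],
    )
    def test_two_by_two(self, a, b, expected):
        assert divtime.categorize(Isolate(*a), Isolate(*b)) == expected


class TestRangeSummary:
    def test_single_comparison_is_identity(self):
        r = TimeRange(1, 2)
        assert divtime.range_summary([r]) == TimeRange(1, 2)

    def test_disjoint_ranges_envelope(self):
        env = divtime.range_summary([TimeRange(1, 2), TimeRange(5, 6)])
        assert (env.lo, env.hi) == (1, 6)

    def test_envelope_contains_members(self):
        ranges = [TimeRange(2, 4), TimeRange(1, 3), TimeRange(3, 7)]
        env = divtime.range_summary(ranges)
        assert all(env.contains_range(r) for r in ranges)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            divtime.range_summary([])


class TestComparisonOutputs:
    def _table(self):
        records = [
            {
                "isolate_a": Isolate("x1", "sp1", "w1"),
                "isolate_b": Isolate("x2", "sp2", "w1"),
                "wolb_range": TimeRange(1e5, 5e5),
                "host_range": TimeRange(2e5, 4e5),
            },
            {
                "isolate_a": Isolate("x1", "sp1", "w1"),
                "isolate_b": Isolate("x3", "sp1", "w2"),
                "wolb_range": TimeRange(2e6, 8e6),
                "host_range": TimeRange(1e5, 4e5),
            },
        ]
        return divtime.compare_ranges_table(records)

    def test_table_categories_and_verdicts(self):
        t = self._table()
        assert t.category.tolist() == [
            "interspecific_intrastrain", "intraspecific_interstrain",
        ]
        assert t.verdict.tolist() == ["congruent", "older"]

    def test_range_plot_written(self, tmp_path):
        out = tmp_path / "ranges.svg"
        divtime.plot_split_ranges(self._table(), str(out))
        assert out.exists() and out.stat().st_size > 0


class TestTurnover:
    def test_no_differences_zero_rate(self):
        tin = divtime.TurnoverInput(
            pairs=[(frozenset({"a"}), frozenset({"a"}), 1e6)]
        )
        assert divtime.turnover_rate(tin) == 0.0

    def test_headline_scale_arithmetic(self):
        """Four strain differences over 25 million total branch generations
        give 0.16 events per million host generations."""
        pairs = [
            (frozenset({"a", "b"}), frozenset({"a"}), 2.5e6),  # 1 difference
            (frozenset({"c"}), frozenset({"d"}), 2.5e6),       # 2 differences
            (frozenset({"e"}), frozenset(), 2.5e6),            # 1 difference
            (frozenset({"f"}), frozenset({"f"}), 2.5e6),       # 0 differences
            (frozenset(), frozenset(), 2.5e6),                 # 0 differences
        ]
        tin = divtime.TurnoverInput(pairs=pairs)
        # total D = 4, total G = 2 * 5 * 2.5e6 = 25e6
        assert divtime.turnover_rate(tin) == pytest.approx(0.16)

    def test_waiting_time_arithmetic(self):
        assert divtime.waiting_time(0.2, 1.0) == pytest.approx(5.0)

    def test_rate_recovery_on_simulated_histories(self):
        from wolbshift.experiments import turnover_recovery

        res = turnover_recovery(seed=1, n_seeds=20)
        assert res["relative_error"] <= 0.15

    def test_divergence_factor_one_doubles_rate(self):
        tin = divtime.TurnoverInput(pairs=[(frozenset({"a"}), frozenset(), 1e6)])
        r2 = divtime.turnover_rate(tin, ClockConfig(divergence_factor=2))
        r1 = divtime.turnover_rate(tin, ClockConfig(divergence_factor=1))
        assert r1 == pytest.approx(2 * r2)
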