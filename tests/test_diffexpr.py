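"""Normalization, the Poisson tag-count test, and Venn structure."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srnapipe.diffexpr import (
    DERecord,
    VennRegions,
    ac_density,
    ac_pvalue,
    call_de,
    de_overlap,
    exclusion_rule,
    normalize,
    venn,
)
from srnapipe.errors import ParameterError
from srnapipe.io_formats import TagCountTable

from .oracles import density_exact, pvalue_exact


def make_table(counts: dict, totals: dict) -> TagCountTable:
    return TagCountTable(pd.DataFrame(counts), totals, key="mirna")


class TestNormalize:
    def test_closed_form(self):
        t = make_table({"CK": [250]}, {"CK": 2_000_000})
        assert normalize(t).iloc[0, 0] == 125.0

    def test_zero_count_gets_adjustment(self):
        t = make_table({"CK": [0], "A": [10]}, {"CK": 1_000_000, "A": 1_000_000})
        norm = normalize(t)
        assert norm.iloc[0]["CK"] == 0.01
        assert norm.iloc[0]["A"] == 10.0

    def test_identity_scale(self):
        t = make_table({"CK": [10**6]}, {"CK": 10**6})
        assert normalize(t).iloc[0, 0] == 1e6

    def test_unadjusted_values_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 500, size=200)
        t = make_table({"CK": counts}, {"CK": int(counts.sum())})
        assert normalize(t)["CK"].sum() == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        t = make_table({"CK": [1]}, {"CK": 1})
        t.totals["CK"] = 0
        with pytest.raises(ParameterError):
            normalize(t)


class TestExclusionRule:
    @pytest.mark.parametrize(
        "trt,ctl,mode,expected",
        [
            (0.4, 0.7, "both", True),
            (0.4, 5.0, "both", False),
            (1.0, 1.0, "both", False),  # "less than 1" is strict
            (0.4, 5.0, "either", True),
            (1.0, 1.0, "either", False),
        ],
    )
    def test_modes(self, trt, ctl, mode, expected):
        assert exclusion_rule(trt, ctl, mode) is expected


class TestDensity:
    @pytest.mark.parametrize(
        "x,y,expected", [(0, 0, 0.5), (1, 1, 0.25), (2, 0, 0.125)]
    )
    def test_hand_values_equal_totals(self, x, y, expected):
        assert ac_density(x, y, 10**6, 10**6) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_rational_oracle_on_full_grid(self):
        """Log-space density agrees with stdlib-rational arithmetic for all
        counts up to 60, at unequal library sizes."""
        n1, n2 = 1_000_000, 1_700_000
        for x in range(61):
            for y in range(61):
                exact = float(density_exact(x, y, n1, n2))
                got = ac_density(x, y, n1, n2)
                assert math.isclose(got, exact, rel_tol=1e-10), (x, y)

    def test_sums_to_one_over_y(self):
        for x, n1, n2 in [(0, 10**6, 10**6), (7, 10**6, 3 * 10**6), (30, 5 * 10**6, 10**6)]:
            total = sum(ac_density(x, y, n1, n2) for y in range(4000))
            assert abs(total - 1.0) < 1e-9

    @given(x=st.integers(0, 40), y=st.integers(0, 40))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_symmetric_under_equal_totals(self, x, y):
        n = 2_000_000
        assert ac_density(x, y, n, n) == pytest.approx(ac_density(y, x, n, n), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ac_density(-1, 0, 10, 10)


class TestPvalue:
    def test_geometric_tail(self):
        # at x=0 and equal totals the density is 2^-(y+1); doubling the
        # upper tail at y=20 gives exactly 2^-19
        assert ac_pvalue(0, 20, 10**6, 10**6) == pytest.approx(2**-19, rel=1e-12)

    def test_symmetric_point_clips_to_one(self):
        assert ac_pvalue(5, 5, 10**6, 10**6) == 1.0
        assert ac_pvalue(0, 0, 123456, 123456) == 1.0

    def test_matches_exact_oracle(self):
        n1, n2 = 1_000_000, 1_000_000
        assert ac_pvalue(5, 50, n1, n2) == pytest.approx(
            float(pvalue_exact(5, 50, n1, n2)), rel=1e-10
        )
        n1, n2 = 2_000_000, 900_000
        for x, y in [(0, 0), (3, 1), (10, 30), (60, 2), (25, 25)]:
            assert ac_pvalue(x, y, n1, n2) == pytest.approx(
                float(pvalue_exact(x, y, n1, n2)), rel=1e-9
            ), (x, y)

    def test_symmetry_equal_totals(self):
        n = 10**6
        for x, y in [(3, 17), (0, 9), (12, 40)]:
            assert ac_pvalue(x, y, n, n) == pytest.approx(ac_pvalue(y, x, n, n), rel=1e-12)

    def test_monotone_away_from_center(self):
        n = 10**6
        x = 20
        ps_up = [ac_pvalue(x, y, n, n) for y in range(20, 60)]
        assert all(a >= b for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [ac_pvalue(x, y, n, n) for y in range(20, 0, -1)]
        assert all(a >= b for a, b in zip(ps_down, ps_down[1:]))

    def test_always_positive(self):
        assert ac_pvalue(0, 500, 10**6, 10**6) > 0.0

    def test_one_sided_alternatives(self):
        n = 10**6
        p2 = ac_pvalue(0, 20, n, n)
        assert ac_pvalue(0, 20, n, n, alternative="greater") == pytest.approx(p2 / 2)
        # lower tail of Y at y=0 given x=20 is the single density 2^-21
        assert ac_pvalue(20, 0, n, n, alternative="less") == pytest.approx(2.0**-21)


class TestCallDE:
    def _table(self):
        return make_table(
            {"CK": [100, 100, 0, 0], "A": [400, 130, 1024, 0]},
            {"CK": 1_000_000, "A": 1_000_000},
        )

    def test_thresholds(self):
        recs = call_de(self._table(), [("A", "CK")])
        by_id = {r.mirna_id: r for r in recs}
        r0 = by_id[0]  # 100 -> 400: 4x, highly significant
        assert r0.significant and r0.direction == "up"
        assert r0.log2fc == pytest.approx(2.0)
        r1 = by_id[1]  # 100 -> 130: |log2fc| < 1, never significant
        assert not r1.significant
        assert abs(r1.log2fc) < 1

    def test_zero_adjusted_fold_change(self):
        recs = call_de(self._table(), [("A", "CK")])
        r2 = next(r for r in recs if r.mirna_id == 2)  # 0 -> 1024
        assert r2.norm_control == 0.01
        assert r2.log2fc == pytest.approx(math.log2(1024 / 0.01))

    def test_double_zero_excluded(self):
        recs = call_de(self._table(), [("A", "CK")])
        r3 = next(r for r in recs if r.mirna_id == 3)
        assert r3.excluded and not r3.significant

    def test_exact_log2fc_identity(self):
        # normalized pair (0.01, 10.24) is exactly 2^-10
        t = make_table({"CK": [1024], "A": [0]}, {"CK": 100_000_000, "A": 100_000_000})
        rec = call_de(t, [("A", "CK")])[0]
        assert rec.norm_control == pytest.approx(10.24)
        assert rec.log2fc == pytest.approx(-10.0)

    def test_unknown_library_rejected(self):
        with pytest.raises(ParameterError):
            call_de(self._table(), [("B", "CK")])

    def test_alpha_zero_kills_all_calls(self):
        recs = call_de(self._table(), [("A", "CK")], alpha=0.0)
        assert not any(r.significant for r in recs)


class TestVenn:
    def test_reported_region_arithmetic(self):
        v = VennRegions(
            names=("CK", "A", "M"),
            exclusive=(34, 24, 34),
            pairwise=(174, 176, 167),
            triple=153,
        )
        assert v.union == 303
        assert v.set_sizes["CK"] == 222

    def test_disjoint_singletons(self):
        v = venn({"a": {1}, "b": {2}, "c": {3}})
        assert v.union == 3 and v.triple == 0 and v.exclusive == (1, 1, 1)

    def test_identical_sets(self):
        s = set(range(9))
        v = venn({"a": set(s), "b": set(s), "c": set(s)})
        assert v.union == 9 and v.triple == 9 and v.exclusive == (0, 0, 0)

    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_inclusion_exclusion(self, a, b, c):
        v = venn({"a": a, "b": b, "c": c})
        assert v.union == len(a | b | c)
        assert v.set_sizes == {"a": len(a), "b": len(b), "c": len(c)}
        assert sum(v.exclusive) + sum(v.pairwise_only) + v.triple == v.union

    def test_de_overlap_identical_sets_all_triple(self):
        recs = []
        for cmp_label in ("CK-VS-A", "CK-VS-M", "M-VS-A"):
            for mid in ("m1", "m2"):
                recs.append(
                    DERecord(mid, cmp_label, 1, 50, 10**6, 10**6, 1.0, 50.0, 5.6, 1e-9, False, True)
                )
        v = de_overlap(recs)
        assert v.triple == 2 and v.union == 2 and v.exclusive == (0, 0, 0)

    def test_de_overlap_empty_comparison(self):
        recs = []
        for cmp_label, sig in (("CK-VS-A", True), ("CK-VS-M", True), ("M-VS-A", False)):
            recs.append(
                DERecord("m1", cmp_label, 1, 50, 10**6, 10**6, 1.0, 50.0, 5.6, 1e-9, False, sig)
            )
        v = de_overlap(recs)
        assert v.set_sizes["M-VS-A"] == 0 and v.triple == 0
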