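"""Exact 2x2 statistics against brute-force enumeration, plus meta-analysis."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicscan.burden_stats import (
    CohortCounts,
    ZeroCellError,
    burden_report,
    fisher_exact,
    frequency,
    mantel_haenszel_or,
    meta_pooled,
    odds_ratio,
)


def enum_fisher(a, b, c, d, sidedness):
    """Independent oracle: enumerate all tables with the observed margins,
    weighting each by its exact multivariate-hypergeometric probability."""
    n1, K, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, K - (N - n1)), min(K, n1)
    denom = math.comb(N, n1)
    probs = {x: math.comb(K, x) * math.comb(N - K, n1 - x) / denom
             for x in range(lo, hi + 1)}
    if sidedness == "one_sided_greater":
        return sum(p for x, p in probs.items() if x >= a)
    return sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-12))


class TestOddsRatio:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 1293, 2, 5343), 20.66),
        ((10, 1293, 1, 5093), 39.4),
        ((5, 5, 5, 5), 1.0),
    ])
    def test_cross_product(self, counts, expected):
        assert odds_ratio(CohortCounts(*counts)) == pytest.approx(expected, abs=0.015)

    def test_zero_cell_raises_with_correction_hint(self):
        with pytest.raises(ZeroCellError, match="haldane"):
            odds_ratio(CohortCounts(3, 10, 0, 10))
        assert odds_ratio(CohortCounts(3, 10, 0, 10), haldane=True) == pytest.approx(
            (3.5 * 10.5) / (10.5 * 0.5)
        )

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        cc = CohortCounts(7, 13, 2, 40)
        swapped = CohortCounts(40, 2, 13, 7)  # both rows and both columns
        assert odds_ratio(cc) == pytest.approx(odds_ratio(swapped))


class TestFisherExact:
    @pytest.mark.parametrize("counts,sidedness,expected", [
        ((10, 1293, 2, 5343), "one_sided_greater", 3.638e-6),
        ((10, 1293, 2, 5345), "one_sided_greater", 3.627e-6),
        ((10, 1293, 1, 5093), "one_sided_greater", 1.073e-6),
    ])
    def test_published_scale_tables(self, counts, sidedness, expected):
        p = fisher_exact(CohortCounts(*counts), sidedness)
        assert p == pytest.approx(expected, rel=5e-4)

    def test_empty_event_column_gives_unity(self):
        assert fisher_exact(CohortCounts(0, 12, 0, 30), "one_sided_greater") == 1.0

    def test_matches_enumeration_on_toy_tables(self):
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if (a + b) == 0 or (c + d) == 0:
                continue
            cc = CohortCounts(a, b, c, d)
            for side in ("one_sided_greater", "two_sided"):
                assert fisher_exact(cc, side) == pytest.approx(
                    enum_fisher(a, b, c, d, side), abs=1e-12
                ), (a, b, c, d, side)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_point_probability_bounds_one_sided_p(self, t):
        a, b, c, d = t
        if a + b == 0 or c + d == 0:
            return
        cc = CohortCounts(a, b, c, d)
        from scipy.stats import hypergeom

        point = hypergeom.pmf(a, a + b + c + d, a + c, a + b)
        p1 = fisher_exact(cc, "one_sided_greater")
        assert point - 1e-12 <= p1 <= 1.0 + 1e-12


class TestFrequency:
    @pytest.mark.parametrize("events,n,expected", [
        (10, 1303, 0.77), (6, 955, 0.63), (0, 2926, 0.0),
    ])
    def test_percentage(self, events, n, expected):
        assert frequency(events, n) == expected

    def test_reporting_precision(self):
        assert frequency(6, 955, decimals=1) == 0.6

    def test_needs_positive_n(self):
        with pytest.raises(ValueError):
            frequency(1, 0)


class TestMeta:
    def test_pooled_fisher_on_identical_strata_equals_doubled_counts(self):
        cc = CohortCounts(4, 96, 1, 199)
        doubled = CohortCounts(8, 192, 2, 398)
        res = meta_pooled([cc, cc], method="pooled_fisher")
        assert res["p_value"] == pytest.approx(fisher_exact(doubled))

    def test_single_stratum_cmh_equals_fisher(self):
        cc = CohortCounts(6, 94, 2, 198)
        res = meta_pooled([cc], method="cmh")
        assert res["p_value"] == pytest.approx(fisher_exact(cc))

    def test_cmh_matches_enumeration_on_two_small_strata(self):
        s1, s2 = CohortCounts(3, 5, 1, 7), CohortCounts(2, 6, 2, 6)
        res = meta_pooled([s1, s2], method="cmh")

        def stratum_probs(cc):
            a, b, c, d = cc.as_tuple()
            n1, K, N = a + b, a + c, a + b + c + d
            lo, hi = max(0, K - (N - n1)), min(K, n1)
            denom = math.comb(N, n1)
            return {x: math.comb(K, x) * math.comb(N - K, n1 - x) / denom
                    for x in range(lo, hi + 1)}

        p1, p2 = stratum_probs(s1), stratum_probs(s2)
        t_obs = s1.cases_with_event + s2.cases_with_event
        p = sum(q1 * q2 for (x1, q1) in p1.items() for (x2, q2) in p2.items()
                if x1 + x2 >= t_obs)
        assert res["p_value"] == pytest.approx(p, abs=1e-12)

    def test_mh_or_agrees_with_statsmodels(self):
        import statsmodels.stats.contingency_tables as ct

        strata = [CohortCounts(8, 92, 3, 197), CohortCounts(5, 45, 2, 98)]
        tables = np.array([
            [[cc.cases_with_event, cc.cases_without],
             [cc.controls_with_event, cc.controls_without]] for cc in strata
        ]).transpose(1, 2, 0)
        st_or = ct.StratifiedTable(tables.astype(float)).oddsratio_pooled
        assert mantel_haenszel_or(strata) == pytest.approx(st_or, rel=1e-9)

    def test_cmh_recovers_common_odds_ratio_on_simulation(self):
        # strata share a true OR of ~4; the MH estimate should land near it
        rng = np.random.default_rng(0)
        ors = []
        for _ in range(200):
            strata = []
            for n_case, n_ctrl, p0 in ((300, 300, 0.05), (200, 400, 0.10)):
                p1 = min(1.0, 4 * p0 / (1 + 3 * p0))  # OR=4 on the odds scale
                a = rng.binomial(n_case, p1)
                c = rng.binomial(n_ctrl, p0)
                strata.append(CohortCounts(a, n_case - a, max(c, 1), n_ctrl - max(c, 1)))
            ors.append(mantel_haenszel_or(strata))
        assert np.median(ors) == pytest.approx(4.0, rel=0.25)


class TestBurdenReport:
    def _events(self, spec):
        import pandas as pd

        return pd.DataFrame({"event_type": spec})

    def test_per_type_tables_conserve_totals(self):
        rep = burden_report(
            self._events(["loss", "gain", "gain", "loh"]), 100,
            self._events(["loh"]), 500,
        )
        total = sum(t["counts"][0] for t in rep["by_type"].values())
        assert total == rep["overall"]["counts"][0] == 4
        assert rep["overall"]["case_frequency_pct"] == 4.0

    def test_zero_control_events_needs_explicit_correction(self):
        rep = burden_report(self._events(["loss"]), 100, self._events([]), 500)
        assert rep["overall"]["odds_ratio"] is None
        rep2 = burden_report(self._events(["loss"]), 100, self._events([]), 500,
                             haldane=True)
        assert rep2["overall"]["odds_ratio"] > 0
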