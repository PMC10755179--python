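import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dictyvar.association import (ContingencyTable, build_contingency,
                                  fisher_exact, odds_ratio, prevalence,
                                  screen_report)
from dictyvar.simulate import CloneScreenRecord


def T(a, b, c, d):
    return ContingencyTable(a, b, c, d)


class TestFisherExact:
    def test_balanced_minimal_table_is_one(self):
        assert fisher_exact(T(1, 0, 0, 1)) == pytest.approx(1.0)

    def test_five_five_diagonal(self):
        # both extreme tables of the 5/5 margins are equally probable
        assert fisher_exact(T(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_pooled_5prime_table_is_highly_significant(self):
        assert fisher_exact(T(55, 7, 1, 26)) < 1e-4

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(T(0, 0, 0, 0))

    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    def test_matches_scipy_two_sided(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = fisher_exact(T(a, b, c, d))
        ref = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    @given(st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20), st.integers(0, 20))
    def test_invariant_under_transposition(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact(T(a, b, c, d)) == pytest.approx(
            fisher_exact(T(a, c, b, d)), rel=1e-9)

    def test_monotone_evidence_beyond_expectation(self):
        """Moving mass from discordant to concordant cells (fixed margins)
        never increases p once past the table's expected value."""
        for (a, b, c, d) in [(5, 5, 5, 5), (8, 4, 4, 8), (10, 10, 2, 20)]:
            n, r1, c1 = a + b + c + d, a + b, a + c
            expect = r1 * c1 / n
            prev = None
            x = a
            while x + 1 <= min(r1, c1):
                if x >= expect:
                    p_here = fisher_exact(T(x, r1 - x, c1 - x, n - r1 - c1 + x))
                    p_next = fisher_exact(T(x + 1, r1 - x - 1, c1 - x - 1,
                                            n - r1 - c1 + x + 1))
                    assert p_next <= p_here * (1 + 1e-9)
                x += 1

    def test_null_rejection_rate_is_conservative(self):
        """Exact-test conservatism: under independent carriage/phenotype the
        rejection rate at alpha=0.05 stays at or below 0.05 + 2 MC errors."""
        rng = np.random.default_rng(20230901)
        n_tables, rejected = 400, 0
        for _ in range(n_tables):
            n = 40
            carries = rng.random(n) < 0.4
            fruits = rng.random(n) < 0.5
            a = int(np.sum(carries & ~fruits))
            b = int(np.sum(~carries & ~fruits))
            c = int(np.sum(carries & fruits))
            d = int(np.sum(~carries & fruits))
            if fisher_exact(T(a, b, c, d)) < 0.05:
                rejected += 1
        mc_err = math.sqrt(0.05 * 0.95 / n_tables)
        assert rejected / n_tables <= 0.05 + 2 * mc_err


class TestOddsRatio:
    def test_simple_value(self):
        assert odds_ratio(T(2, 1, 1, 2)).value == pytest.approx(4.0)

    def test_infinite_when_discordant_product_zero(self):
        r = odds_ratio(T(5, 0, 0, 5))
        assert r.infinite and r.value == math.inf

    def test_undefined_when_both_products_zero(self):
        assert odds_ratio(T(0, 3, 0, 4)).value is None

    @given(st.integers(0, 30), st.integers(1, 30),
           st.integers(1, 30), st.integers(0, 30))
    def test_matches_direct_arithmetic(self, a, b, c, d):
        assert odds_ratio(T(a, b, c, d)).value == pytest.approx((a * d) / (b * c))


class TestBuildContingency:
    def records(self):
        mk = CloneScreenRecord
        return [mk(1, "c1", "v", fruits=False, carries=True),
                mk(1, "c2", "v", fruits=False, carries=False),
                mk(1, "c3", "v", fruits=True, carries=True),
                mk(1, "c4", "v", fruits=True, carries=False)]

    def test_one_record_per_cell(self):
        tables = build_contingency(self.records(), "line")
        assert tables[1].cells == (1, 1, 1, 1)

    def test_totals_conserved_across_groupings(self):
        recs = self.records()
        for group_by in ("line", "variant"):
            tables = build_contingency(recs, group_by)
            assert sum(t.total for t in tables.values()) == len(recs)

    def test_empty_input_gives_empty_map(self):
        assert build_contingency([], "line") == {}

    def test_region_grouping_requires_region_map(self):
        with pytest.raises(ValueError):
            build_contingency(self.records(), "region", region_map={})


class TestScreenReport:
    def test_region_pooling_and_percentages(self):
        mk = CloneScreenRecord
        recs = []
        k = 0
        for line, cells in [(5, (20, 3, 0, 10)), (21, (35, 4, 1, 16))]:
            a, b, c, d = cells
            for fruits, carries, count in [(False, True, a), (False, False, b),
                                           (True, True, c), (True, False, d)]:
                for _ in range(count):
                    k += 1
                    recs.append(mk(line, f"c{k}", f"var{line}",
                                   fruits=fruits, carries=carries))
        report = screen_report(recs, {"var5": "5prime", "var21": "5prime"})
        pooled = report.per_region["5prime"]
        assert pooled.table.cells == (55, 7, 1, 26)
        assert pooled.carrier_pct_nonfruiting == pytest.approx(88.7, abs=0.05)
        assert pooled.carrier_pct_fruiting == pytest.approx(3.7, abs=0.05)
        assert pooled.p_value < 1e-4
        assert set(report.per_line) == {5, 21}
        assert report.per_line[5].p_value < 1e-4

    def test_all_fruiting_reports_no_data(self):
        recs = [CloneScreenRecord(1, "c1", "v", fruits=True, carries=True)]
        report = screen_report(recs, {"v": "3prime"})
        assert report.per_region["3prime"].carrier_pct_nonfruiting is None

    def test_unmapped_variant_is_an_error(self):
        recs = [CloneScreenRecord(1, "c1", "v", fruits=True, carries=True)]
        with pytest.raises(ValueError):
            screen_report(recs, {})


class TestPrevalence:
    def test_zero_of_958(self):
        p = prevalence(0, 958, 0.95)
        assert p.proportion == 0.0
        assert p.ci_low == 0.0
        assert 0 < p.ci_high < 0.01

    def test_simple_proportion(self):
        assert prevalence(75, 1000).proportion == pytest.approx(0.075)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            prevalence(0, 0)

    @given(st.integers(1, 500), st.data())
    def test_matches_statsmodels_beta_interval(self, n, data):
        from statsmodels.stats.proportion import proportion_confint

        k = data.draw(st.integers(0, n))
        p = prevalence(k, n, 0.95)
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert p.ci_low == pytest.approx(0.0 if np.isnan(lo) else lo, abs=1e-9)
        assert p.ci_high == pytest.approx(1.0 if np.isnan(hi) else hi, abs=1e-9)
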