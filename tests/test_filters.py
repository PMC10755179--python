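import math

import pytest

from dictyvar.filters import (FilterConfig, FilterDecision, annotate_af,
                              custom_filter, hard_filter_a, hard_filter_b,
                              intersect_callsets, mask_ancestral,
                              run_snv_cascade, validate_read_support,
                              OriginPopulationMissing,
                              ancestor_calls_from_records)
from dictyvar.records import (CallerMetricsA, CallerMetricsB, ReadCountTable,
                              SampleCall, VariantRecord)
from dictyvar.simulate import SampleMeta

from oracles import brute_force_survivors, random_callsets


def make_record(pos=100, ref="A", alt="T", qual=500.0, site_dp=100,
                metrics_a=None, metrics_b=None, calls=None, alts=None):
    return VariantRecord(chrom="c1", pos=pos, ref=ref, alt=alt, qual=qual,
                         site_dp=site_dp, alts=alts or (alt,),
                         metrics_a=metrics_a, metrics_b=metrics_b,
                         calls=calls or {})


def counts_with_ancestor(pos, ref_count, alt_count, ref="A", alt="T"):
    t = ReadCountTable()
    t.add("c1", pos, "ancestor", ref, alt, ref_count, alt_count)
    return t


class TestAncestralMask:
    def test_low_maf_site_removed(self, fcfg):
        rec = make_record(calls={"ancestor": SampleCall("ref", 0.15, 100)})
        counts = counts_with_ancestor(100, 85, 15)  # MAF 0.85
        kept, decisions = mask_ancestral(
            [rec], counts, ancestor_calls_from_records([rec]), fcfg)
        assert kept == []
        assert decisions[0].reasons == ("ancestor_maf",)

    def test_maf_exactly_at_threshold_is_kept(self, fcfg):
        rec = make_record(calls={"ancestor": SampleCall("ref", 0.10, 100)})
        counts = counts_with_ancestor(100, 90, 10)  # MAF 0.90: strict <
        kept, _ = mask_ancestral(
            [rec], counts, ancestor_calls_from_records([rec]), fcfg)
        assert kept == [rec]

    def test_ancestor_called_variant_removed(self, fcfg):
        rec = make_record(calls={"ancestor": SampleCall("alt", 0.99, 100)})
        counts = counts_with_ancestor(100, 1, 99)
        kept, decisions = mask_ancestral(
            [rec], counts, ancestor_calls_from_records([rec]), fcfg)
        assert kept == []
        assert "ancestor_variant" in decisions[0].reasons

    def test_ancestor_uncalled_removed(self, fcfg):
        rec = make_record(calls={"ancestor": SampleCall("missing", None, 0)})
        counts = counts_with_ancestor(100, 99, 1)
        kept, decisions = mask_ancestral(
            [rec], counts, ancestor_calls_from_records([rec]), fcfg)
        assert kept == []
        assert "ancestor_uncalled" in decisions[0].reasons

    def test_site_absent_from_counts_flagged_distinctly(self, fcfg):
        rec = make_record(calls={"ancestor": SampleCall("ref", 0.0, 100)})
        kept, decisions = mask_ancestral(
            [rec], ReadCountTable(), ancestor_calls_from_records([rec]), fcfg)
        assert kept == []
        assert "ancestor_uncalled" in decisions[0].reasons
        assert "ancestor_no_counts" in decisions[0].notes


PASSING_A = dict(QD=30.0, FS=0.0, SOR=1.0, MQ=60.0, MQRankSum=0.0,
                 ReadPosRankSum=0.0)
PASSING_B = dict(MQM=60.0, SAF=5, SAR=5, SAP=3.0, SRP=3.0, RPR=4, RPL=4)


class TestHardFilters:
    @pytest.mark.parametrize("override,expected_reason", [
        ({"QD": 1.5}, "QD"),
        ({"FS": 60.0}, "FS"),
        ({"SOR": 3.0}, "SOR"),
        ({"MQ": 40.0}, "MQ"),          # boundary: strict >
        ({"MQRankSum": -12.5}, "MQRankSum"),
        ({"ReadPosRankSum": -8.0}, "ReadPosRankSum"),
    ])
    def test_caller_a_single_rule_failures(self, override, expected_reason):
        rec = make_record(metrics_a=CallerMetricsA(**{**PASSING_A, **override}))
        d = hard_filter_a(rec)
        assert d.verdict == "fail"
        assert d.reasons == (expected_reason,)

    def test_caller_a_all_passing(self):
        rec = make_record(metrics_a=CallerMetricsA(**PASSING_A))
        assert hard_filter_a(rec).verdict == "pass"

    @pytest.mark.parametrize("override,expected_reason", [
        ({"SAF": 10, "SAR": 0}, "SAR"),
        ({"MQM": 40.0}, "MQM"),
        ({"RPR": 1}, "RPR"),           # boundary: strict >
        ({"SAP": 0.5}, "SAP"),
    ])
    def test_caller_b_single_rule_failures(self, override, expected_reason):
        rec = make_record(metrics_b=CallerMetricsB(**{**PASSING_B, **override}))
        d = hard_filter_b(rec)
        assert d.verdict == "fail"
        assert d.reasons == (expected_reason,)

    def test_caller_b_all_passing(self):
        rec = make_record(metrics_b=CallerMetricsB(**PASSING_B))
        assert hard_filter_b(rec).verdict == "pass"

    def test_missing_metric_noted_but_passing_by_default(self):
        rec = make_record(metrics_a=CallerMetricsA(**{**PASSING_A,
                                                      "MQRankSum": None}))
        d = hard_filter_a(rec)
        assert d.verdict == "pass"
        assert "metric_absent:MQRankSum" in d.notes

    def test_missing_metric_fails_under_strict_policy(self):
        rec = make_record(metrics_a=CallerMetricsA(**{**PASSING_A,
                                                      "MQRankSum": None}))
        d = hard_filter_a(rec, FilterConfig(missing_metric_fails=True))
        assert d.verdict == "fail"
        assert "MQRankSum" in d.reasons


def calls_with_ac(n_alt, n_ref=10, n_missing=0):
    calls = {}
    for i in range(n_alt):
        calls[f"a{i}"] = SampleCall("alt", 0.9, 50)
    for i in range(n_ref):
        calls[f"r{i}"] = SampleCall("ref", 0.0, 50)
    for i in range(n_missing):
        calls[f"m{i}"] = SampleCall("missing", None, 0)
    return calls


class TestCustomFilter:
    def test_high_ac_removed(self, fcfg):
        rec = make_record(calls=calls_with_ac(4))
        kept, decisions = custom_filter([rec], fcfg)
        assert kept == []
        assert decisions[0].reasons == ("max_ac",)

    def test_qual_boundary(self, fcfg):
        low = make_record(pos=1, qual=199.9, calls=calls_with_ac(1))
        ok = make_record(pos=2, qual=200.0, calls=calls_with_ac(1))
        kept, _ = custom_filter([low, ok], fcfg)
        assert [r.pos for r in kept] == [2]

    def test_missingness_removed(self, fcfg):
        rec = make_record(calls=calls_with_ac(1, n_ref=36, n_missing=11))
        kept, decisions = custom_filter([rec], fcfg)
        assert kept == []
        assert decisions[0].reasons == ("missingness",)

    def test_dp_mean_uses_surviving_sites(self, fcfg):
        recs = [make_record(pos=p, site_dp=dp, calls=calls_with_ac(1))
                for p, dp in [(1, 100), (2, 100), (3, 400)]]
        kept, decisions = custom_filter(recs, fcfg)
        # mean 200, threshold 300: only the 400x site falls
        assert [r.pos for r in kept] == [1, 2]
        failed = [d for d in decisions if d.verdict == "fail"]
        assert failed[0].key[1] == 3 and failed[0].reasons == ("excess_dp",)

    def test_indels_and_multiallelic_removed(self, fcfg):
        indel = make_record(pos=1, ref="AT", alt="A", calls=calls_with_ac(1))
        multi = make_record(pos=2, alts=("T", "C"), calls=calls_with_ac(1))
        kept, decisions = custom_filter([indel, multi], fcfg)
        assert kept == []
        reasons = {d.key[1]: d.reasons for d in decisions}
        assert "indel" in reasons[1] and "multiallelic" in reasons[2]

    def test_empty_input(self, fcfg):
        kept, decisions = custom_filter([], fcfg)
        assert kept == [] and decisions == []


class TestIntersection:
    def test_site_in_one_set_only_dropped(self):
        a = [make_record(pos=1), make_record(pos=2)]
        b = [make_record(pos=1)]
        consensus, dropped = intersect_callsets(a, b)
        assert [r.pos for r in consensus] == [1]
        assert dropped[0].reasons == ("not_in_both",)

    def test_empty_b_empties_consensus(self):
        consensus, _ = intersect_callsets([make_record(pos=1)], [])
        assert consensus == []

    def test_identical_sets_idempotent(self):
        a = [make_record(pos=p) for p in (1, 2, 3)]
        consensus, dropped = intersect_callsets(a, a)
        assert consensus == a and dropped == []

    def test_alt_mismatch_flagged(self):
        a = [make_record(pos=1, alt="T")]
        b = [make_record(pos=1, alt="G")]
        consensus, dropped = intersect_callsets(a, b)
        assert consensus == []
        assert dropped[0].reasons == ("alt_mismatch",)

    def test_consensus_carries_caller_a_annotations(self):
        ma = CallerMetricsA(**PASSING_A)
        a = [make_record(pos=1, metrics_a=ma)]
        b = [make_record(pos=1, metrics_b=CallerMetricsB(**PASSING_B))]
        consensus, _ = intersect_callsets(a, b)
        assert consensus[0].metrics_a is ma


def two_line_meta():
    return [SampleMeta("ancestor", None, "ancestor", "unknown"),
            SampleMeta("1", 1, "population", "unknown"),
            SampleMeta("1-NF1", 1, "clone", "fruiting"),
            SampleMeta("2", 2, "population", "unknown"),
            SampleMeta("3", 3, "population", "unknown"),
            SampleMeta("4", 4, "population", "unknown"),
            SampleMeta("5", 5, "population", "unknown")]


def support_counts(pos, pop_alt, other_alts=(0, 0, 0, 0)):
    t = ReadCountTable()
    t.add("c1", pos, "ancestor", "A", "T", 195, 0)
    t.add("c1", pos, "1", "A", "T", 195 - pop_alt, pop_alt)
    t.add("c1", pos, "1-NF1", "A", "T", 0, 54)
    for i, alt in enumerate(other_alts):
        t.add("c1", pos, str(i + 2), "A", "T", 195 - alt, alt)
    return t


class TestReadSupport:
    def test_origin_support_boundary(self, fcfg):
        meta = two_line_meta()
        clone_call = {"1-NF1": SampleCall("alt", 1.0, 54),
                      "1": SampleCall("ref", 0.02, 195)}
        rec4 = make_record(pos=10, calls=dict(clone_call))
        rec5 = make_record(pos=20, calls=dict(clone_call))
        counts4 = support_counts(10, 4)
        counts5 = support_counts(20, 5)
        final, dropped, _ = validate_read_support([rec4], counts4, meta, fcfg)
        assert final == [] and dropped[0].reasons == ("origin_support",)
        final, dropped, _ = validate_read_support([rec5], counts5, meta, fcfg)
        assert final == [rec5]  # "at least 5 reads" keeps exactly 5

    def test_cross_line_low_level_support_dropped(self, fcfg):
        meta = two_line_meta()
        rec = make_record(pos=10, calls={"1": SampleCall("alt", 0.5, 195)})
        counts = support_counts(10, 90, other_alts=(3, 3, 3, 3))
        final, dropped, flags = validate_read_support([rec], counts, meta, fcfg)
        assert final == []
        assert dropped[0].reasons == ("cross_line_support",)
        assert flags == [rec.key]

    def test_missing_origin_population_is_an_error(self, fcfg):
        meta = two_line_meta()
        rec = make_record(pos=10, calls={"1-NF1": SampleCall("alt", 1.0, 54)})
        with pytest.raises(OriginPopulationMissing, match="1-NF1"):
            validate_read_support([rec], ReadCountTable(), meta, fcfg)


class TestAnnotateAF:
    def test_af_is_alt_over_depth(self):
        rec = make_record(pos=10, calls={"1": SampleCall("alt", None, 0)})
        t = ReadCountTable()
        t.add("c1", 10, "1", "A", "T", 78, 117)
        annotate_af([rec], t)
        assert rec.calls["1"].af == pytest.approx(117 / 195)

    def test_zero_depth_leaves_af_absent(self):
        rec = make_record(pos=10, calls={"1": SampleCall("ref", None, 5)})
        t = ReadCountTable()
        t.add("c1", 10, "1", "A", "T", 0, 0)
        annotate_af([rec], t)
        assert rec.calls["1"].af is None
        assert rec.calls["1"].genotype == "ref"


class TestDecisionInvariant:
    def test_fail_iff_reasons(self):
        with pytest.raises(ValueError):
            FilterDecision(key=("c1", 1, "T"), stage="x", verdict="fail")
        with pytest.raises(ValueError):
            FilterDecision(key=("c1", 1, "T"), stage="x", verdict="pass",
                           reasons=("r",))


class TestCascadeProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_cascade_equals_brute_force(self, seed, fcfg):
        """Survivors of the staged cascade match an independent per-rule
        re-implementation on random call sets."""
        a, b, counts, meta = random_callsets(seed, n_sites=100)
        result = run_snv_cascade(a, b, counts, meta, fcfg)
        assert {r.key for r in result.final} == \
            brute_force_survivors(a, b, counts, meta, fcfg)

    def test_mask_and_custom_commute_without_dp_rule(self):
        cfg = FilterConfig(dp_mean_factor=math.inf)
        for seed in range(5):
            a, _, counts, meta = random_callsets(seed, n_sites=60)
            anc = ancestor_calls_from_records(a)
            m_then_c, _ = custom_filter(mask_ancestral(a, counts, anc, cfg)[0], cfg)
            c_then_m, _ = mask_ancestral(custom_filter(a, cfg)[0], counts, anc, cfg)
            assert {r.key for r in m_then_c} == {r.key for r in c_then_m}

    @pytest.mark.parametrize("tight", [
        dict(ancestor_maf_min=0.95),
        dict(max_missing_samples=2),
        dict(max_alt_ac=1),
        dict(min_qual=400.0),
        dict(min_origin_support_reads=20),
        dict(shared_support_min_reads=1, shared_support_min_lines=1),
    ])
    def test_tightening_thresholds_never_adds_survivors(self, tight):
        """Monotonicity, with the DP rule disabled for thresholds that feed
        its surviving-set mean."""
        base = FilterConfig(dp_mean_factor=math.inf)
        tighter = FilterConfig(dp_mean_factor=math.inf, **tight)
        for seed in range(5):
            a, b, counts, meta = random_callsets(seed, n_sites=80)
            loose = {r.key for r in run_snv_cascade(a, b, counts, meta, base).final}
            strict = {r.key for r in run_snv_cascade(a, b, counts, meta, tighter).final}
            assert strict <= loose

    def test_tightening_dp_factor_is_monotone(self):
        for seed in range(5):
            a, b, counts, meta = random_callsets(seed, n_sites=80)
            loose = {r.key for r in run_snv_cascade(
                a, b, counts, meta, FilterConfig(dp_mean_factor=1.5)).final}
            strict = {r.key for r in run_snv_cascade(
                a, b, counts, meta, FilterConfig(dp_mean_factor=1.0)).final}
            assert strict <= loose
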