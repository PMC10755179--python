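"""Emulated caller outputs.

Stands in for the two SNV callers and the SV caller: turns the simulated
read counts into two parallel call sets with realistic site metrics, plus
an SV call set. A site enters a sample's calls when its alternate reads
reach the callable threshold (>= 3 reads and >= 5% of depth by default).
True calls receive passing metric values with mild jitter; injected false
positives receive the single defect of their failure class, so each
filtration rule can be validated in isolation. QUAL scales with the total
number of supporting reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CallerMetricsA, CallerMetricsB, SampleCall, VariantRecord
from .simulate import SimConfig, TruthSet
from .sv import SVRecord

#: SV failure menu: one record per class, each violating exactly one rule.
SV_FP_CLASSES = ("sv_not_pass", "sv_low_qual", "sv_low_pe",
                 "sv_translocation", "sv_many_samples")


@dataclass
class EmulatedCallsets:
    """Outputs of the two SNV callers and the SV caller.

    Iterates as the 3-tuple ``(callset_a, callset_b, sv_calls)``;
    ``fp_classes`` maps an injected false-positive site key to its failure
    class (SNV sites) and ``sv_fp_classes`` does the same for SV records.
    """

    callset_a: list
    callset_b: list
    sv_calls: list
    fp_classes: dict = field(default_factory=dict)
    sv_fp_classes: dict = field(default_factory=dict)
    true_sv_keys: tuple = ()

    def __iter__(self):
        return iter((self.callset_a, self.callset_b, self.sv_calls))


def _passing_metrics_a(rng) -> CallerMetricsA:
    return CallerMetricsA(
        QD=float(rng.uniform(20, 30)), FS=float(rng.uniform(0, 5)),
        SOR=float(rng.uniform(0.5, 1.5)), MQ=float(rng.uniform(55, 60)),
        MQRankSum=float(rng.uniform(-1, 1)),
        ReadPosRankSum=float(rng.uniform(-1, 1)))


def _passing_metrics_b(rng, alt_total: int) -> CallerMetricsB:
    saf = max(1, alt_total // 2)
    sar = max(1, alt_total - saf)
    return CallerMetricsB(
        MQM=float(rng.uniform(55, 60)), SAF=saf, SAR=sar,
        SAP=float(rng.uniform(1, 10)), SRP=float(rng.uniform(1, 10)),
        RPR=max(2, alt_total // 2), RPL=max(2, alt_total // 2))


def emulate_callers(counts, truth: TruthSet, cfg: SimConfig) -> EmulatedCallsets:
    """Build the two SNV call sets and the SV call set from read counts."""
    rng = cfg.rng("callers")
    records_a, records_b = [], []
    fp_classes = {}

    for site, plan in counts.site_plans.items():
        chrom, pos = site
        calls = {}
        alt_total = 0
        site_dp = 0
        any_alt = False
        for sm in truth.sample_meta:
            dp = counts.depth(chrom, pos, sm.sample_id)
            site_dp += dp
            if dp == 0:
                calls[sm.sample_id] = SampleCall(genotype="missing", af=None, dp=0)
                continue
            ac = counts.alt_count(chrom, pos, sm.sample_id)
            called_alt = (ac >= cfg.callable_min_reads
                          and ac / dp >= cfg.callable_min_fraction)
            if called_alt:
                any_alt = True
                alt_total += ac
            calls[sm.sample_id] = SampleCall(
                genotype="alt" if called_alt else "ref", af=ac / dp, dp=dp)
        if not any_alt:
            continue  # below the callable threshold everywhere: not emitted

        qual = 20.0 * alt_total
        metrics_a = _passing_metrics_a(rng)
        metrics_b = _passing_metrics_b(rng, alt_total)
        fp = plan.fp_class if plan.kind == "fp" else None
        if fp == "low_qd":
            metrics_a.QD = 1.0
        elif fp == "strand_bias":
            metrics_b.SAF = alt_total
            metrics_b.SAR = 0
        elif fp == "low_mqm":
            metrics_b.MQM = 30.0
        elif fp == "low_qual":
            qual = 100.0

        def record(metrics_a=None, metrics_b=None):
            return VariantRecord(
                chrom=chrom, pos=pos, ref=plan.ref, alt=plan.alt, qual=qual,
                site_dp=site_dp, metrics_a=metrics_a, metrics_b=metrics_b,
                calls={s: SampleCall(c.genotype, c.af, c.dp)
                       for s, c in calls.items()})

        if fp is not None:
            fp_classes[(chrom, pos, plan.alt)] = fp
        if fp != "caller_b_only":
            records_a.append(record(metrics_a=metrics_a))
        if fp != "caller_a_only":
            records_b.append(record(metrics_b=metrics_b))

    sv_calls, sv_fp, true_keys = _emulate_svs(truth, cfg)
    return EmulatedCallsets(callset_a=records_a, callset_b=records_b,
                            sv_calls=sv_calls, fp_classes=fp_classes,
                            sv_fp_classes=sv_fp, true_sv_keys=true_keys)


def _emulate_svs(truth: TruthSet, cfg: SimConfig):
    """Planted true SVs plus one failing record per Delly-rule class."""
    rng = cfg.rng("svs")
    svs = []
    fp_classes = {}
    true_keys = []
    lines = sorted({m.line for m in truth.sample_meta if m.line is not None})
    types = ("DEL", "INV", "DUP")

    def line_samples(line):
        ids = [str(line)] + [c.sample_id for c in truth.clones_of(line)]
        return frozenset(ids)

    cursor = 1000
    for i in range(cfg.n_true_svs):
        line = lines[i % len(lines)]
        length = int(rng.integers(200, 2000))
        sv = SVRecord(sv_type=types[i % len(types)], chrom="chr1",
                      start=cursor, end=cursor + length,
                      pe=int(rng.integers(6, 20)),
                      qual=float(rng.uniform(40, 200)), filter_flag="PASS",
                      called_samples=line_samples(line))
        svs.append(sv)
        true_keys.append(sv.key)
        cursor += length + 500

    def fp(klass, **kw):
        nonlocal cursor
        length = int(rng.integers(200, 2000))
        base = dict(sv_type="DEL", chrom="chr1", start=cursor,
                    end=cursor + length, pe=int(rng.integers(6, 20)),
                    qual=float(rng.uniform(40, 200)), filter_flag="PASS",
                    called_samples=line_samples(lines[0]))
        base.update(kw)
        cursor += length + 500
        sv = SVRecord(**base)
        svs.append(sv)
        fp_classes[sv.key] = klass

    fp("sv_not_pass", filter_flag="LowQual")
    fp("sv_low_qual", qual=10.0)
    fp("sv_low_pe", pe=2)
    fp("sv_translocation", sv_type="TRA", chrom2="chr2", pe=10)
    everyone = [m.sample_id for m in truth.sample_meta]
    many = (frozenset(str(l) for l in lines[:4]) if len(lines) >= 4
            else frozenset(everyone[:4]))
    fp("sv_many_samples", called_samples=many)
    return svs, fp_classes, tuple(true_keys)
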