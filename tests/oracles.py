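"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package: every rule is checked
per site with plain comparisons and set algebra, so agreement with the
cascade is a meaningful cross-validation.
"""

from __future__ import annotations

import math

import numpy as np

from dictyvar.records import (CallerMetricsA, CallerMetricsB, ReadCountTable,
                              SampleCall, VariantRecord)
from dictyvar.simulate import SampleMeta


def brute_force_survivors(callset_a, callset_b, counts, meta, cfg,
                          ancestor_id="ancestor"):
    """Final key set of the cascade, recomputed rule by rule."""

    def ancestor_ok(rec):
        call = rec.calls.get(ancestor_id)
        if call is None or call.genotype == "missing" or call.genotype == "alt":
            return False
        if not counts.has_site(rec.chrom, rec.pos, ancestor_id):
            return False
        maf = counts.maf(rec.chrom, rec.pos, ancestor_id)
        return maf is None or maf >= cfg.ancestor_maf_min

    def hard_a_ok(rec):
        m = rec.metrics_a
        checks = [
            (m.QD, lambda v: v > 2), (m.FS, lambda v: v < 60),
            (m.SOR, lambda v: v < 3), (m.MQ, lambda v: v > 40),
            (m.MQRankSum, lambda v: v > -12.5),
            (m.ReadPosRankSum, lambda v: v > -8),
        ]
        return all(v is None or ok(v) for v, ok in checks)

    def hard_b_ok(rec):
        m = rec.metrics_b
        checks = [
            (m.MQM, lambda v: v > 40), (m.SAF, lambda v: v > 0),
            (m.SAR, lambda v: v > 0), (m.SAP, lambda v: v > 0.5),
            (m.SRP, lambda v: v > 0.5), (m.RPR, lambda v: v > 1),
            (m.RPL, lambda v: v > 1),
        ]
        return all(v is None or ok(v) for v, ok in checks)

    def custom_ok_pre_dp(rec):
        if len(rec.ref) != 1 or any(len(a) != 1 for a in rec.alts):
            return False
        if len(rec.alts) > 1:
            return False
        n_missing = sum(1 for c in rec.calls.values() if c.genotype == "missing")
        if n_missing > cfg.max_missing_samples:
            return False
        ac = sum(1 for c in rec.calls.values() if c.genotype == "alt")
        if ac > cfg.max_alt_ac:
            return False
        return rec.qual >= cfg.min_qual

    def one_side(records, hard_ok):
        pre = [r for r in records
               if ancestor_ok(r) and hard_ok(r) and custom_ok_pre_dp(r)]
        if not pre:
            return set()
        mean_dp = sum(r.site_dp for r in pre) / len(pre)
        return {r.key for r in pre
                if r.site_dp <= cfg.dp_mean_factor * mean_dp}

    a_keys = one_side(callset_a, hard_a_ok)
    b_keys = one_side(callset_b, hard_b_ok)
    consensus = {k for k in a_keys if k in b_keys}

    pop_of_line = {m.line: m.sample_id for m in meta if m.role == "population"}
    role = {m.sample_id: m.role for m in meta}
    line = {m.sample_id: m.line for m in meta}
    rec_by_key = {r.key: r for r in callset_a}

    final = set()
    for key in consensus:
        rec = rec_by_key[key]
        called = [s for s, c in rec.calls.items() if c.genotype == "alt"]
        ok = True
        for s in called:
            if role.get(s) != "clone":
                continue
            pop = pop_of_line[line[s]]
            if counts.alt_count(rec.chrom, rec.pos, pop, rec.alt) < cfg.min_origin_support_reads:
                ok = False
        called_lines = {line[s] for s in called if line.get(s) is not None}
        n_other = sum(
            1 for ln, pop in pop_of_line.items()
            if ln not in called_lines and counts.has_site(rec.chrom, rec.pos, pop)
            and counts.alt_count(rec.chrom, rec.pos, pop, rec.alt) >= cfg.shared_support_min_reads)
        if n_other >= cfg.shared_support_min_lines:
            ok = False
        if ok:
            final.add(key)
    return final


def brute_force_sv_keep(svs, cfg):
    """Per-rule SV filter: keep keys recomputed independently."""
    kept = set()
    for sv in svs:
        pe_floor = 5 if sv.sv_type == "TRA" else 3
        if (sv.filter_flag == "PASS"
                and sv.qual >= getattr(cfg, "sv_min_qual", 20.0)
                and sv.pe > pe_floor
                and sv.sv_type in ("DEL", "DUP", "INV", "INS")
                and (not sv.chrom2 or sv.chrom2 == sv.chrom)
                and len(sv.called_samples) <= getattr(cfg, "sv_max_samples", 3)):
            kept.add(sv.key)
    return kept


def random_meta(n_lines=4):
    meta = [SampleMeta("ancestor", None, "ancestor", "unknown")]
    for line in range(1, n_lines + 1):
        meta.append(SampleMeta(str(line), line, "population", "unknown"))
        meta.append(SampleMeta(f"{line}-NF1", line, "clone", "fruiting"))
    return meta


def random_callsets(seed, n_sites=100, n_lines=4):
    """Random call sets + counts spanning every rule's pass/fail space."""
    rng = np.random.default_rng(seed)
    meta = random_meta(n_lines)
    samples = [m.sample_id for m in meta]
    counts = ReadCountTable()
    records_a, records_b = [], []

    def pick(options):
        return options[int(rng.integers(len(options)))]

    for i in range(n_sites):
        pos = 10 * (i + 1)
        ref, alt = pick([("A", "T"), ("C", "G"), ("G", "A")])
        calls = {}
        for s in samples:
            depth = int(pick([0, 20, 60, 200]))
            if depth == 0:
                calls[s] = SampleCall("missing", None, 0)
                alt_reads = 0
            else:
                gt = pick(["ref", "ref", "ref", "alt", "missing"])
                if s == "ancestor":
                    gt = pick(["ref", "ref", "ref", "alt", "missing"])
                alt_reads = int(pick([0, 1, 3, 4, 5, int(0.3 * depth), int(0.9 * depth)]))
                alt_reads = min(alt_reads, depth)
                calls[s] = SampleCall(gt, alt_reads / depth, depth)
            counts.add("c1", pos, s, ref, alt, depth - alt_reads, alt_reads)
        qual = float(pick([50.0, 150.0, 199.9, 200.0, 500.0]))
        site_dp = int(pick([200, 400, 800, 5000]))
        ma = CallerMetricsA(
            QD=pick([1.0, 2.0, 25.0, None]), FS=pick([0.0, 59.9, 80.0]),
            SOR=pick([1.0, 3.0, 4.0]), MQ=pick([30.0, 40.0, 60.0]),
            MQRankSum=pick([-15.0, -12.5, 0.0, None]),
            ReadPosRankSum=pick([-10.0, -8.0, 0.0, None]))
        mb = CallerMetricsB(
            MQM=pick([30.0, 40.0, 60.0]), SAF=pick([0, 1, 8]),
            SAR=pick([0, 1, 8]), SAP=pick([0.2, 0.5, 4.0]),
            SRP=pick([0.2, 0.5, 4.0]), RPR=pick([0, 1, 2, 6]),
            RPL=pick([0, 1, 2, 6]))
        indel = rng.random() < 0.05
        multi = rng.random() < 0.05
        rec_kwargs = dict(
            chrom="c1", pos=pos,
            ref=ref if not indel else ref + "A",
            alt=alt, qual=qual, site_dp=site_dp,
            alts=(alt, "C") if multi and alt != "C" else (alt,))
        a = VariantRecord(metrics_a=ma, calls=calls, **rec_kwargs)
        records_a.append(a)
        if rng.random() < 0.85:  # usually the same site appears in B
            b_alt = rec_kwargs["alt"]
            if rng.random() < 0.05:
                b_alt = pick([x for x in "ACGT" if x not in (ref, alt)])
            kw = dict(rec_kwargs)
            kw["alt"] = b_alt
            kw["alts"] = (b_alt,) if len(rec_kwargs["alts"]) == 1 else (b_alt, "T")
            if kw["ref"] == b_alt:
                continue
            b = VariantRecord(
                metrics_b=mb,
                calls={s: SampleCall(c.genotype, c.af, c.dp)
                       for s, c in calls.items()}, **kw)
            records_b.append(b)
    return records_a, records_b, counts, meta
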