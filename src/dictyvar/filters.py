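"""The SNP filtration cascade.

Order of operations, applied independently to each caller's call set:

1. ancestral masking — drop sites where the ancestor was called as a
   variant, was left uncalled, or has a major allele frequency (MAF) below
   0.90 in its read counts (ancestral polymorphism);
2. per-caller hard filters on site metrics;
3. custom filters, in order: biallelic-SNV restriction (no indels, no
   multi-allelic sites), missingness (uncalled in more than 10 samples),
   alternate allele count (AC > 3), minimum QUAL of 200, and approximate
   read depth above 1.5x the mean DP of the sites surviving the preceding
   custom rules;

then the two filtered sets are intersected (a site must survive both), and
finally read support is validated: every clone call needs at least 5
alternate reads in its origin population, and any SNP with low-level
support for the same allele across multiple other lines is dropped.

Every removal is recorded as a :class:`FilterDecision`, the machine-checkable
replacement for a manual browser review.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

from .records import ReadCountTable, VariantRecord, sample_line


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults are the published values."""

    ancestor_maf_min: float = 0.90
    max_missing_samples: int = 10
    max_alt_ac: int = 3
    min_qual: float = 200.0
    dp_mean_factor: float = 1.5
    min_origin_support_reads: int = 5
    shared_support_min_reads: int = 2
    shared_support_min_lines: int = 2
    missing_metric_fails: bool = False
    # SV thresholds (consumed by sv.filter_svs)
    sv_min_qual: float = 20.0
    sv_min_pe: int = 3
    sv_min_pe_tra: int = 5
    sv_max_samples: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.ancestor_maf_min <= 1:
            raise ValueError("ancestor_maf_min must be in (0, 1]")
        for name in ("max_missing_samples", "max_alt_ac", "min_qual",
                     "dp_mean_factor", "min_origin_support_reads",
                     "shared_support_min_reads", "shared_support_min_lines"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FilterDecision:
    """Audit-trail entry for one record at one stage.

    ``reasons`` holds the violated rules (non-empty iff the verdict is
    "fail"); ``notes`` holds informational flags that do not affect the
    verdict (e.g. ``metric_absent:MQRankSum``).
    """

    key: tuple
    stage: str
    verdict: str  # pass | fail
    reasons: tuple = ()
    notes: tuple = ()

    def __post_init__(self) -> None:
        if self.verdict not in ("pass", "fail"):
            raise ValueError("verdict must be 'pass' or 'fail'")
        if (self.verdict == "fail") != bool(self.reasons):
            raise ValueError("verdict=fail iff reasons non-empty")


def ancestor_calls_from_records(records, ancestor_id: str = "ancestor") -> dict:
    """Extract the ancestor's genotype per site from the records themselves."""
    calls = {}
    for r in records:
        call = r.calls.get(ancestor_id)
        calls[r.site] = call.genotype if call is not None else "missing"
    return calls


def mask_ancestral(records, ancestor_counts: ReadCountTable, ancestor_calls,
                   cfg: FilterConfig, ancestor_id: str = "ancestor"):
    """Remove sites with pre-existing variation in the ancestor.

    A site is removed (from all samples) when the ancestor was called as a
    variant, left uncalled, or its MAF in the ancestor read counts falls
    below ``ancestor_maf_min`` (strict ``<``). A site absent from the
    ancestor counts is treated as uncalled and flagged distinctly.
    """
    kept, decisions = [], []
    for r in records:
        reasons, notes = [], []
        gt = ancestor_calls.get(r.site, "missing")
        if gt == "alt":
            reasons.append("ancestor_variant")
        elif gt == "missing":
            reasons.append("ancestor_uncalled")
        if ancestor_counts.has_site(r.chrom, r.pos, ancestor_id):
            maf = ancestor_counts.maf(r.chrom, r.pos, ancestor_id)
            if maf is not None and maf < cfg.ancestor_maf_min:
                reasons.append("ancestor_maf")
        else:
            if "ancestor_uncalled" not in reasons:
                reasons.append("ancestor_uncalled")
            notes.append("ancestor_no_counts")
        if reasons:
            decisions.append(FilterDecision(r.key, "ancestral_mask", "fail",
                                            tuple(reasons), tuple(notes)))
        else:
            kept.append(r)
            decisions.append(FilterDecision(r.key, "ancestral_mask", "pass",
                                            notes=tuple(notes)))
    return kept, decisions


_HARD_RULES_A = (
    ("QD", lambda v: v > 2),
    ("FS", lambda v: v < 60),
    ("SOR", lambda v: v < 3),
    ("MQ", lambda v: v > 40),
    ("MQRankSum", lambda v: v > -12.5),
    ("ReadPosRankSum", lambda v: v > -8),
)

_HARD_RULES_B = (
    ("MQM", lambda v: v > 40),
    ("SAF", lambda v: v > 0),
    ("SAR", lambda v: v > 0),
    ("SAP", lambda v: v > 0.5),
    ("SRP", lambda v: v > 0.5),
    ("RPR", lambda v: v > 1),
    ("RPL", lambda v: v > 1),
)


def _hard_filter(record: VariantRecord, metrics, rules, stage: str,
                 cfg: Optional[FilterConfig]) -> FilterDecision:
    if metrics is None:
        raise ValueError(f"record {record.key} lacks metrics for {stage}")
    strict = cfg.missing_metric_fails if cfg is not None else False
    reasons, notes = [], []
    for name, ok in rules:
        value = getattr(metrics, name)
        if value is None:
            notes.append(f"metric_absent:{name}")
            if strict:
                reasons.append(name)
        elif not ok(value):
            reasons.append(name)
    verdict = "fail" if reasons else "pass"
    return FilterDecision(record.key, stage, verdict, tuple(reasons), tuple(notes))


def hard_filter_a(record: VariantRecord, cfg: Optional[FilterConfig] = None) -> FilterDecision:
    """Best-practices hard filter of caller A (all inequalities strict)."""
    return _hard_filter(record, record.metrics_a, _HARD_RULES_A, "hard_filter_a", cfg)


def hard_filter_b(record: VariantRecord, cfg: Optional[FilterConfig] = None) -> FilterDecision:
    """Mapping-quality / strand-balance / read-placement filter of caller B."""
    return _hard_filter(record, record.metrics_b, _HARD_RULES_B, "hard_filter_b", cfg)


def custom_filter(records, cfg: FilterConfig):
    """Shared custom filters, applied in the specified order.

    The DP rule is order-dependent by construction: its mean is computed
    over the sites that survived the preceding custom rules of this very
    call, per call set.
    """
    decisions = []
    survivors = []
    for r in records:
        reasons = []
        if r.is_indel:
            reasons.append("indel")
        if r.is_multiallelic:
            reasons.append("multiallelic")
        if not reasons:
            if len(r.samples_missing()) > cfg.max_missing_samples:
                reasons.append("missingness")
            if r.alt_ac > cfg.max_alt_ac:
                reasons.append("max_ac")
            if r.qual < cfg.min_qual:
                reasons.append("low_qual")
        if reasons:
            decisions.append(FilterDecision(r.key, "custom_filter", "fail",
                                            tuple(reasons)))
        else:
            survivors.append(r)

    kept = []
    if survivors:
        mean_dp = sum(r.site_dp for r in survivors) / len(survivors)
        threshold = cfg.dp_mean_factor * mean_dp
        for r in survivors:
            if r.site_dp > threshold:
                decisions.append(FilterDecision(r.key, "custom_filter", "fail",
                                                ("excess_dp",)))
            else:
                kept.append(r)
                decisions.append(FilterDecision(r.key, "custom_filter", "pass"))
    return kept, decisions


def intersect_callsets(set_a_filtered, set_b_filtered):
    """Cross-caller consensus: keep sites present in both filtered sets.

    The consensus record carries caller A's annotations. A site present in
    both sets but with different alternate alleles is dropped and flagged.
    """
    b_by_key = {r.key: r for r in set_b_filtered}
    b_by_site = {}
    for r in set_b_filtered:
        b_by_site.setdefault(r.site, set()).add(r.alt)
    consensus, dropped = [], []
    for r in set_a_filtered:
        if r.key in b_by_key:
            consensus.append(r)
        elif r.site in b_by_site:
            dropped.append(FilterDecision(r.key, "intersection", "fail",
                                          ("alt_mismatch",)))
        else:
            dropped.append(FilterDecision(r.key, "intersection", "fail",
                                          ("not_in_both",)))
    return consensus, dropped


class OriginPopulationMissing(KeyError):
    """A clone's origin population has no read counts at a required site."""


def _meta_maps(meta):
    by_id = {m.sample_id: m for m in meta}
    pop_of_line = {m.line: m.sample_id for m in meta if m.role == "population"}
    return by_id, pop_of_line


def validate_read_support(records, counts: ReadCountTable, meta,
                          cfg: FilterConfig):
    """Origin-population support and cross-line low-level support checks.

    Returns ``(final_records, dropped_decisions, flags)`` where ``flags``
    lists the cross-line-support keys (flagged and dropped).
    """
    by_id, pop_of_line = _meta_maps(meta)
    final, dropped, flags = [], [], []
    for r in records:
        reasons = []
        called = r.samples_with_alt()
        called_lines = set()
        for s in called:
            sm = by_id.get(s)
            if sm is None or sm.role == "ancestor":
                continue
            called_lines.add(sm.line)
        # clone calls need >= min_origin_support_reads alt reads in the origin population
        for s in called:
            sm = by_id.get(s)
            if sm is None or sm.role != "clone":
                continue
            pop = pop_of_line.get(sm.line)
            if pop is None or not counts.has_site(r.chrom, r.pos, pop):
                raise OriginPopulationMissing(
                    f"origin population of clone {s!r} (line {sm.line}) has no "
                    f"read counts at {r.chrom}:{r.pos}")
            if counts.alt_count(r.chrom, r.pos, pop, r.alt) < cfg.min_origin_support_reads:
                reasons.append("origin_support")
                break
        # low-level support for the same allele across multiple other lines
        other_support = 0
        for line, pop in pop_of_line.items():
            if line in called_lines or not counts.has_site(r.chrom, r.pos, pop):
                continue
            if counts.alt_count(r.chrom, r.pos, pop, r.alt) >= cfg.shared_support_min_reads:
                other_support += 1
        if other_support >= cfg.shared_support_min_lines:
            reasons.append("cross_line_support")
            flags.append(r.key)
        if reasons:
            dropped.append(FilterDecision(r.key, "read_support", "fail",
                                          tuple(dict.fromkeys(reasons))))
        else:
            final.append(r)
    return final, dropped, flags


def annotate_af(records, counts: ReadCountTable):
    """Set each sample call's AF to alt reads / depth from the count table."""
    for r in records:
        for s, call in r.calls.items():
            if not counts.has_site(r.chrom, r.pos, s):
                continue
            d = counts.depth(r.chrom, r.pos, s)
            call.dp = d
            call.af = (counts.alt_count(r.chrom, r.pos, s, r.alt) / d) if d > 0 else None
    return records


@dataclass
class CascadeResult:
    final: list
    decisions: list
    flags: list
    stage_counts: dict


def run_snv_cascade(callset_a, callset_b, counts: ReadCountTable, meta,
                    cfg: FilterConfig, ancestor_id: str = "ancestor") -> CascadeResult:
    """Full cascade: mask, hard filters, custom filters, intersection,
    read-support validation, AF annotation."""
    decisions = []
    stage_counts = {"input_a": len(callset_a), "input_b": len(callset_b)}

    def one_side(records, hard, label):
        anc = ancestor_calls_from_records(records, ancestor_id)
        masked, d = mask_ancestral(records, counts, anc, cfg, ancestor_id)
        decisions.extend(d)
        hard_kept = []
        for r in masked:
            dec = hard(r, cfg)
            decisions.append(dec)
            if dec.verdict == "pass":
                hard_kept.append(r)
        kept, d = custom_filter(hard_kept, cfg)
        decisions.extend(d)
        stage_counts[f"masked_{label}"] = len(masked)
        stage_counts[f"hard_{label}"] = len(hard_kept)
        stage_counts[f"custom_{label}"] = len(kept)
        return kept

    a_final = one_side(callset_a, hard_filter_a, "a")
    b_final = one_side(callset_b, hard_filter_b, "b")
    consensus, d = intersect_callsets(a_final, b_final)
    decisions.extend(d)
    stage_counts["consensus"] = len(consensus)
    final, d, flags = validate_read_support(consensus, counts, meta, cfg)
    decisions.extend(d)
    stage_counts["final"] = len(final)
    annotate_af(final, counts)
    return CascadeResult(final=final, decisions=decisions, flags=flags,
                         stage_counts=stage_counts)
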