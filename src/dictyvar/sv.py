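"""Structural-variant records and the germline SV filtering rules.

The filter retains simple, intrachromosomal SVs (DEL/DUP/INV/INS) that are
flagged PASS with QUAL >= 20 and paired-end support PE > 3 (PE > 5 would
apply to translocations, but translocations are excluded as
interchromosomal anyway), and discards SVs genotyped in more than 3 samples
— the same cap used for the SNP alternate allele count, because a variant
is only expected in the population and clone sample(s) of a single line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SIMPLE_SV_TYPES = ("DEL", "DUP", "INV", "INS")
SV_TYPES = SIMPLE_SV_TYPES + ("TRA",)


@dataclass
class SVRecord:
    sv_type: str
    chrom: str
    start: int
    end: int
    pe: int
    qual: float
    filter_flag: str = "PASS"  # PASS | LowQual | other
    called_samples: frozenset = field(default_factory=frozenset)
    chrom2: str = ""  # second chromosome for translocations

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.pe < 0:
            raise ValueError("pe must be >= 0")
        if self.sv_type != "TRA" and self.start > self.end:
            raise ValueError("start must be <= end for intrachromosomal SVs")
        if isinstance(self.called_samples, (set, tuple, list)):
            self.called_samples = frozenset(self.called_samples)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.sv_type)

    @property
    def is_intrachromosomal(self) -> bool:
        return self.sv_type != "TRA" and (not self.chrom2 or self.chrom2 == self.chrom)


def filter_svs(svs, cfg=None):
    """Apply the germline SV rules; returns (kept, decisions).

    ``cfg`` may override thresholds via attributes ``sv_min_qual``,
    ``sv_min_pe``, ``sv_min_pe_tra`` and ``sv_max_samples``.
    """
    from .filters import FilterDecision

    min_qual = getattr(cfg, "sv_min_qual", 20.0)
    min_pe = getattr(cfg, "sv_min_pe", 3)        # strict: keep requires pe > 3
    min_pe_tra = getattr(cfg, "sv_min_pe_tra", 5)
    max_samples = getattr(cfg, "sv_max_samples", 3)

    kept, decisions = [], []
    for sv in svs:
        reasons = []
        if sv.filter_flag != "PASS":
            reasons.append("not_pass")
        if sv.qual < min_qual:
            reasons.append("low_qual")
        pe_floor = min_pe_tra if sv.sv_type == "TRA" else min_pe
        if sv.pe <= pe_floor:
            reasons.append("low_pe")
        if sv.sv_type not in SIMPLE_SV_TYPES or not sv.is_intrachromosomal:
            reasons.append("not_intrachromosomal")
        if len(sv.called_samples) > max_samples:
            reasons.append("too_many_samples")
        if reasons:
            decisions.append(FilterDecision(key=sv.key, stage="sv_filter",
                                            verdict="fail", reasons=tuple(reasons)))
        else:
            kept.append(sv)
            decisions.append(FilterDecision(key=sv.key, stage="sv_filter",
                                            verdict="pass"))
    return kept, decisions


def sv_gene_overlap(svs, genes):
    """Closed-interval overlap between SV spans and gene CDS intervals.

    Returns ``{sv.key: [(gene_id, region), ...]}`` where ``region`` says
    which half of the gene (5prime/3prime, in transcript coordinates) the SV
    *start* falls in; an SV starting upstream of the coding sequence counts
    as 5prime, downstream as 3prime.
    """
    from .annotate import region_of_position

    out = {}
    for sv in svs:
        hits = []
        for gene in genes:
            if gene.chrom != sv.chrom:
                continue
            if any(max(sv.start, s) <= min(sv.end, e) for s, e in gene.cds_intervals):
                hits.append((gene.gene_id, region_of_position(sv.start, gene)))
        out[sv.key] = hits
    return out
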