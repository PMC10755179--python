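"""VCF 4.2 dialect I/O (pysam-backed).

The modeled dialect: haploid GT (single allele index), per-sample AF and DP
FORMAT fields, caller metrics as site INFO, 1-based positions. Multi-allelic
records are preserved and flagged, never decomposed silently. SV call sets
use SVTYPE/END/PE INFO keys and the FILTER column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .records import (CallerMetricsA, CallerMetricsB, SampleCall,
                      VariantRecord)
from .sv import SVRecord

_INFO_DEFS = [
    ("DP", "1", "Integer", "Approximate read depth across samples"),
    ("QD", "1", "Float", "Variant quality by depth"),
    ("FS", "1", "Float", "Phred-scaled Fisher strand bias"),
    ("SOR", "1", "Float", "Symmetric odds ratio strand bias"),
    ("MQ", "1", "Float", "RMS mapping quality"),
    ("MQRankSum", "1", "Float", "Mapping quality rank-sum"),
    ("ReadPosRankSum", "1", "Float", "Read position rank-sum"),
    ("MQM", "1", "Float", "Mean mapping quality of alternate reads"),
    ("SAF", "1", "Integer", "Alternate reads on the forward strand"),
    ("SAR", "1", "Integer", "Alternate reads on the reverse strand"),
    ("SAP", "1", "Float", "Alternate strand balance probability"),
    ("SRP", "1", "Float", "Reference strand balance probability"),
    ("RPR", "1", "Integer", "Alternate reads placed right"),
    ("RPL", "1", "Integer", "Alternate reads placed left"),
]

_SV_INFO_DEFS = [
    ("SVTYPE", "1", "String", "Structural variant type"),
    ("END", "1", "Integer", "End position"),
    ("CHR2", "1", "String", "Second chromosome (translocations)"),
    ("PE", "1", "Integer", "Paired-end support"),
]

_FORMAT_DEFS = [
    ("GT", "1", "String", "Haploid genotype"),
    ("AF", "1", "Float", "Alternate allele read fraction"),
    ("DP", "1", "Integer", "Read depth"),
]


@dataclass
class VcfHeader:
    """The dialect's header: contigs, samples, free-form metadata lines."""

    samples: list = field(default_factory=list)
    contigs: dict = field(default_factory=dict)  # name -> length
    meta_lines: list = field(default_factory=list)


class VcfFormatError(ValueError):
    pass


def _build_pysam_header(header: VcfHeader, sv: bool = False) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in header.contigs.items():
        h.contigs.add(name, length=length)
    defs = _SV_INFO_DEFS if sv else _INFO_DEFS
    for key, num, typ, desc in defs:
        h.info.add(key, num, typ, desc)
    for key, num, typ, desc in _FORMAT_DEFS:
        h.formats.add(key, num, typ, desc)
    if sv:
        h.filters.add("LowQual", None, None, "Low quality structural variant")
    for line in header.meta_lines:
        try:
            h.add_line(line)
        except ValueError:
            pass
    for s in header.samples:
        h.add_sample(s)
    return h


def write_vcf(header: VcfHeader, records, path) -> None:
    """Write variant records as VCF 4.2 with declared INFO/FORMAT keys."""
    declared = set(header.samples)
    for r in records:
        extra = set(r.calls) - declared
        if extra:
            raise VcfFormatError(
                f"record {r.chrom}:{r.pos} references undeclared sample(s) "
                f"{sorted(extra)}")
    h = _build_pysam_header(header)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for r in records:
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 stop=r.pos - 1 + len(r.ref),
                                 alleles=(r.ref,) + tuple(r.alts))
            rec.qual = r.qual
            rec.info["DP"] = int(r.site_dp)
            for metrics in (r.metrics_a, r.metrics_b):
                if metrics is None:
                    continue
                for key in metrics.KEYS:
                    v = getattr(metrics, key)
                    if v is not None:
                        rec.info[key] = v
            for s in header.samples:
                call = r.calls.get(s, SampleCall())
                if call.genotype == "missing":
                    rec.samples[s]["GT"] = (None,)
                else:
                    rec.samples[s]["GT"] = (1 if call.genotype == "alt" else 0,)
                if call.af is not None:
                    rec.samples[s]["AF"] = round(float(call.af), 4)
                rec.samples[s]["DP"] = int(call.dp)
            out.write(rec)


def read_vcf(path):
    """Read a VCF into (VcfHeader, [VariantRecord]).

    Positions stay 1-based; unknown INFO keys are ignored for the metric
    containers but kept in the header model's meta lines; multi-allelic
    records keep all their ALT alleles (``is_multiallelic``).
    """
    records = []
    with pysam.VariantFile(str(path)) as vf:
        header = VcfHeader(
            samples=list(vf.header.samples),
            contigs={name: c.length for name, c in vf.header.contigs.items()},
        )
        for i, rec in enumerate(vf, start=1):
            try:
                records.append(_to_record(rec, header.samples))
            except Exception as exc:  # pragma: no cover - malformed input path
                raise VcfFormatError(f"malformed record at body line {i}: {exc}")
    return header, records


def _metric_or_none(info, key):
    v = info.get(key)
    if v is None:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return v


def _to_record(rec, samples) -> VariantRecord:
    info = rec.info
    metrics_a = None
    if any(k in info for k in CallerMetricsA.KEYS):
        metrics_a = CallerMetricsA(**{k: _metric_or_none(info, k)
                                      for k in CallerMetricsA.KEYS})
    metrics_b = None
    if any(k in info for k in CallerMetricsB.KEYS):
        metrics_b = CallerMetricsB(**{k: _metric_or_none(info, k)
                                      for k in CallerMetricsB.KEYS})
    calls = {}
    for s in samples:
        fmt = rec.samples[s]
        gt = fmt.get("GT")
        allele = gt[0] if gt else None
        genotype = ("missing" if allele is None
                    else "alt" if allele >= 1 else "ref")
        af = fmt.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        dp = fmt.get("DP") or 0
        calls[s] = SampleCall(genotype=genotype,
                              af=None if af is None else float(af), dp=int(dp))
    return VariantRecord(
        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
        alts=tuple(rec.alts), qual=float(rec.qual or 0.0),
        site_dp=int(_metric_or_none(info, "DP") or 0),
        metrics_a=metrics_a, metrics_b=metrics_b, calls=calls)


def write_sv_vcf(header: VcfHeader, svs, path) -> None:
    h = _build_pysam_header(header, sv=True)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for sv in svs:
            rec = out.new_record(contig=sv.chrom, start=sv.start - 1,
                                 stop=sv.end, alleles=("N", f"<{sv.sv_type}>"))
            rec.qual = sv.qual
            rec.info["SVTYPE"] = sv.sv_type
            rec.stop = sv.end  # writes the END INFO key
            rec.info["PE"] = int(sv.pe)
            if sv.chrom2:
                rec.info["CHR2"] = sv.chrom2
            if sv.filter_flag == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add("LowQual")
            for s in header.samples:
                rec.samples[s]["GT"] = (1 if s in sv.called_samples else 0,)
            out.write(rec)


def read_sv_vcf(path):
    svs = []
    with pysam.VariantFile(str(path)) as vf:
        header = VcfHeader(
            samples=list(vf.header.samples),
            contigs={name: c.length for name, c in vf.header.contigs.items()},
        )
        for rec in vf:
            called = frozenset(
                s for s in header.samples
                if rec.samples[s].get("GT") and rec.samples[s]["GT"][0] == 1)
            flags = list(rec.filter.keys())
            svs.append(SVRecord(
                sv_type=rec.info["SVTYPE"], chrom=rec.chrom, start=rec.pos,
                end=int(rec.info.get("END", rec.stop)),
                pe=int(rec.info.get("PE", 0)), qual=float(rec.qual or 0.0),
                filter_flag=flags[0] if flags else "PASS",
                called_samples=called,
                chrom2=str(rec.info.get("CHR2", "") or "")))
    return header, svs
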