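"""Core domain types shared across the pipeline.

A :class:`VariantRecord` is one call-set site with per-caller quality
metrics and per-sample haploid calls; a :class:`ReadCountTable` holds the
pileup-level ref/alt read counts from which allele frequencies and the
ancestor's major allele frequency (MAF) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import pandas as pd

GENOTYPES = ("ref", "alt", "missing")


@dataclass
class CallerMetricsA:
    """Site-level metrics of the haplotype-based caller (GATK-style INFO)."""

    QD: Optional[float] = None
    FS: Optional[float] = None
    SOR: Optional[float] = None
    MQ: Optional[float] = None
    MQRankSum: Optional[float] = None
    ReadPosRankSum: Optional[float] = None

    KEYS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")


@dataclass
class CallerMetricsB:
    """Site-level metrics of the pooled-haplotype caller (Freebayes-style INFO)."""

    MQM: Optional[float] = None
    SAF: Optional[int] = None
    SAR: Optional[int] = None
    SAP: Optional[float] = None
    SRP: Optional[float] = None
    RPR: Optional[int] = None
    RPL: Optional[int] = None

    KEYS = ("MQM", "SAF", "SAR", "SAP", "SRP", "RPR", "RPL")


@dataclass
class SampleCall:
    """One sample's haploid call at a site.

    ``genotype`` is "ref", "alt" or "missing"; ``af`` is the alternate-allele
    read fraction (defined only when ``dp`` > 0).
    """

    genotype: str = "missing"
    af: Optional[float] = None
    dp: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"invalid genotype {self.genotype!r}")


@dataclass
class VariantRecord:
    """One biallelic site (SNV or indel allele) with per-sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float = 0.0
    site_dp: int = 0
    alts: tuple = ()  # all ALT alleles; len > 1 flags a multi-allelic record
    metrics_a: Optional[CallerMetricsA] = None
    metrics_b: Optional[CallerMetricsB] = None
    calls: dict = field(default_factory=dict)  # sample_id -> SampleCall

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")
        if not self.alts:
            self.alts = (self.alt,)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt)

    @property
    def site(self) -> tuple:
        return (self.chrom, self.pos)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_biallelic_snv(self) -> bool:
        return not self.is_multiallelic and not self.is_indel

    def samples_with_alt(self) -> list:
        return [s for s, c in self.calls.items() if c.genotype == "alt"]

    def samples_missing(self) -> list:
        return [s for s, c in self.calls.items() if c.genotype == "missing"]

    @property
    def alt_ac(self) -> int:
        """Alternate allele count: samples called alt (haploid; missing excluded)."""
        return len(self.samples_with_alt())


@dataclass
class SnpFixtureRow:
    """One row of the published SNP table (site, gene, samples, consequence)."""

    chrom_site: str
    gene_id: str
    samples: tuple
    consequence: str
    impact: str
    aa_change: Optional[str] = None
    gene_name: Optional[str] = None

    ALLOWED_CONSEQUENCES = (
        "missense_var.",
        "stop_gained",
        "synonymous_var.",
        "upstream_gene_var.",
        "downstream_gene_var.",
    )

    def __post_init__(self) -> None:
        if self.consequence not in self.ALLOWED_CONSEQUENCES:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; allowed: "
                f"{', '.join(self.ALLOWED_CONSEQUENCES)}"
            )
        if not self.samples:
            raise ValueError("samples must be non-empty")

    @property
    def lines(self) -> set:
        """Evolved lines touched by this SNP (leading integer of each sample)."""
        return {sample_line(s) for s in self.samples}


def sample_line(sample_id: str) -> int:
    """Line of a sample: the leading integer of its id ('7-NF2' -> 7)."""
    head = sample_id.split("-")[0]
    try:
        return int(head)
    except ValueError:
        raise ValueError(f"cannot derive line from sample id {sample_id!r}") from None


class ReadCountTable:
    """Per-site per-sample ref/alt read counts (pileup summary).

    Entries are keyed by ``(chrom, pos, sample_id)`` and hold the ref base,
    the alt base and their read counts; depth is their sum. The major allele
    frequency (MAF) at a site/sample is max(ref, alt) / depth.
    """

    COLUMNS = ["chrom", "pos", "sample", "ref", "alt", "ref_count", "alt_count", "depth"]

    def __init__(self) -> None:
        self._entries: dict = {}
        self.site_plans: dict = {}  # (chrom, pos) -> SitePlan, set by the simulator

    def add(self, chrom: str, pos: int, sample: str, ref: str, alt: str,
            ref_count: int, alt_count: int) -> None:
        if ref_count < 0 or alt_count < 0:
            raise ValueError("read counts must be non-negative")
        self._entries[(chrom, pos, sample)] = (ref, alt, int(ref_count), int(alt_count))

    def __contains__(self, key: tuple) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def has_site(self, chrom: str, pos: int, sample: str) -> bool:
        return (chrom, pos, sample) in self._entries

    def depth(self, chrom: str, pos: int, sample: str) -> int:
        ref, alt, rc, ac = self._entries[(chrom, pos, sample)]
        return rc + ac

    def alt_count(self, chrom: str, pos: int, sample: str, alt: Optional[str] = None) -> int:
        """Reads supporting ``alt`` (0 if the stored alt base differs)."""
        ref_b, alt_b, rc, ac = self._entries[(chrom, pos, sample)]
        if alt is not None and alt != alt_b:
            return 0
        return ac

    def af(self, chrom: str, pos: int, sample: str) -> Optional[float]:
        ref_b, alt_b, rc, ac = self._entries[(chrom, pos, sample)]
        d = rc + ac
        return None if d == 0 else ac / d

    def maf(self, chrom: str, pos: int, sample: str) -> Optional[float]:
        ref_b, alt_b, rc, ac = self._entries[(chrom, pos, sample)]
        d = rc + ac
        return None if d == 0 else max(rc, ac) / d

    def samples_at(self, chrom: str, pos: int) -> list:
        return [s for (c, p, s) in self._entries if c == chrom and p == pos]

    def iter_entries(self) -> Iterator[tuple]:
        for (chrom, pos, sample), (ref, alt, rc, ac) in self._entries.items():
            yield chrom, pos, sample, ref, alt, rc, ac

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, p, s, r, a, rc, ac, rc + ac)
            for c, p, s, r, a, rc, ac in self.iter_entries()
        ]
        return pd.DataFrame(rows, columns=self.COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadCountTable":
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.chrom, int(row.pos), str(row.sample), row.ref, row.alt,
                      int(row.ref_count), int(row.alt_count))
        return table

    @classmethod
    def from_tsv(cls, path) -> "ReadCountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
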