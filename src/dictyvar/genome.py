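"""Toy reference genomes and gene models.

The real study aligned reads to the AX4 reference; here a small random
genome stands in so the whole pipeline can be exercised end-to-end. The
*D. discoideum* genome is extremely AT-rich (>77% A+T), so base composition
is a tunable parameter of the generator.

Gene models are deliberately minimal: ordered CDS intervals (1-based,
closed, non-overlapping), a strand, and a ``region_boundary`` splitting the
coding sequence into a 5' and a 3' region in transcript coordinates. The
two-exon layout mirrors the focal receptor gene of the study, whose exon 1
(signal peptide + extracellular binding domain) and exon 2 (7-transmembrane
domain) are of roughly equal length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    cds_intervals: tuple  # ((start, end), ...) 1-based closed, transcript order
    region_boundary: int  # CDS offset (0-based, exclusive) ending the 5' region

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.cds_intervals:
            raise ValueError("gene must have at least one CDS interval")
        for s, e in self.cds_intervals:
            if s < 1 or e < s:
                raise ValueError(f"bad CDS interval ({s}, {e})")
        # transcript order: ascending genomic on +, descending on -
        starts = [s for s, _ in self.cds_intervals]
        if self.strand == "+" and starts != sorted(starts):
            raise ValueError("+ strand CDS intervals must ascend")
        if self.strand == "-" and starts != sorted(starts, reverse=True):
            raise ValueError("- strand CDS intervals must descend (transcript order)")
        # non-overlap
        spans = sorted((s, e) for s, e in self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("CDS intervals overlap")
        if self.cds_length % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")
        if not 0 < self.region_boundary < self.cds_length:
            raise ValueError("region_boundary must fall inside the CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple:
        """Genomic (start, end) covering all CDS intervals."""
        return (min(s for s, _ in self.cds_intervals),
                max(e for _, e in self.cds_intervals))

    @property
    def tss(self) -> int:
        """Genomic position of the transcript 5' end."""
        return self.cds_intervals[0][0] if self.strand == "+" else self.cds_intervals[0][1]

    @property
    def tes(self) -> int:
        """Genomic position of the transcript 3' end."""
        return self.cds_intervals[-1][1] if self.strand == "+" else self.cds_intervals[-1][0]

    def cds_offset(self, pos: int):
        """0-based transcript-coordinate offset of genomic ``pos``.

        Returns None when ``pos`` is not inside any CDS interval (e.g. an
        intron or flank).
        """
        off = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None

    def contains(self, pos: int) -> bool:
        return self.cds_offset(pos) is not None


@dataclass
class ToyGenome:
    chromosomes: dict = field(default_factory=dict)  # name -> sequence string
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if set(seq) - set(BASES):
                raise ValueError(f"chromosome {name} has bases outside ACGT")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            _, end = g.span
            if end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} extends past its chromosome")

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """1-based closed-interval slice."""
        return self.chromosomes[chrom][start - 1:end]

    def cds_sequence(self, gene: GeneModel) -> str:
        """Coding sequence in transcript orientation (introns excluded)."""
        parts = []
        for s, e in gene.cds_intervals:
            seg = self.sequence(gene.chrom, s, e)
            parts.append(seg if gene.strand == "+" else revcomp(seg))
        return "".join(parts)

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def position_at_offset(gene: GeneModel, off: int) -> int:
    """Genomic position of a 0-based transcript-coordinate CDS offset."""
    for s, e in gene.cds_intervals:
        length = e - s + 1
        if off < length:
            return s + off if gene.strand == "+" else e - off
        off -= length
    raise ValueError("offset outside CDS")


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class PackingError(ValueError):
    """Requested genes cannot be placed on the requested chromosomes."""


def make_reference(n_chroms: int, chrom_len: int, n_genes: int,
                   at_fraction: float, seed: int) -> ToyGenome:
    """Generate a random AT-biased genome with non-overlapping two-exon genes.

    Genes are placed left to right with fixed inter-gene gaps; a
    :class:`PackingError` is raised when they cannot fit. Deterministic for
    a given seed.
    """
    if chrom_len < 1000:
        raise ValueError("chrom_len must be >= 1000")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not 0 < at_fraction < 1:
        raise ValueError("at_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    chromosomes = {}
    for i in range(n_chroms):
        seq = rng.choice(list("ATCG"), size=chrom_len, p=[p_at, p_at, p_gc, p_gc])
        chromosomes[f"chr{i + 1}"] = "".join(seq)

    genes = []
    gap = 300  # intergenic gap between consecutive CDS spans
    chrom_names = list(chromosomes)
    ci = 0
    cursor = 200
    for gi in range(n_genes):
        exon1 = 3 * int(rng.integers(100, 200))
        exon2 = 3 * int(rng.integers(100, 200))
        intron = 60
        span = exon1 + intron + exon2
        placed = False
        while ci < len(chrom_names):
            if cursor + span + 200 <= chrom_len:
                start = cursor
                strand = "+" if rng.random() < 0.5 else "-"
                iv1 = (start, start + exon1 - 1)
                iv2 = (start + exon1 + intron, start + exon1 + intron + exon2 - 1)
                if strand == "+":
                    intervals = (iv1, iv2)
                    boundary = exon1
                else:
                    # transcript 5' end is the genomic right; exon sizes swap roles
                    intervals = (iv2, iv1)
                    boundary = exon2
                genes.append(GeneModel(
                    gene_id=f"g{gi + 1:03d}",
                    chrom=chrom_names[ci],
                    strand=strand,
                    cds_intervals=intervals,
                    region_boundary=boundary,
                ))
                cursor += span + gap
                placed = True
                break
            ci += 1
            cursor = 200
        if not placed:
            raise PackingError(
                f"cannot place gene {gi + 1} of {n_genes} on "
                f"{n_chroms} chromosome(s) of length {chrom_len}"
            )
    return ToyGenome(chromosomes=chromosomes, genes=genes)
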