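"""Variant consequence classification against toy gene models.

A pared-down effect predictor for the simulated genomes: coding SNVs are
translated codon-by-codon (standard nuclear code, strand-aware) into
stop_gained / missense_variant / synonymous_variant; positions within a
configurable flank of a transcript end become upstream/downstream gene
variants; everything else is intergenic. The impact mapping is the fixed
one used by common effect predictors (stop_gained=High, missense=Moderate,
synonymous=Low, up/downstream=Modifier).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .genome import GeneModel, ToyGenome, position_at_offset, revcomp

IMPACT = {
    "stop_gained": "High",
    "missense_variant": "Moderate",
    "synonymous_variant": "Low",
    "upstream_gene_variant": "Modifier",
    "downstream_gene_variant": "Modifier",
    "intergenic": "Modifier",
}

DEFAULT_FLANK = 1000


@dataclass(frozen=True)
class Consequence:
    term: str
    impact: str
    gene_id: Optional[str] = None
    aa_change: Optional[str] = None  # "K/*", "D/N", ...

    def __post_init__(self) -> None:
        if self.term not in IMPACT:
            raise ValueError(f"unknown consequence term {self.term!r}")
        if IMPACT[self.term] != self.impact:
            raise ValueError(
                f"{self.term} must have impact {IMPACT[self.term]}, got {self.impact}")


class ReferenceMismatch(ValueError):
    """Variant REF disagrees with the genome base at its position."""


def _translate(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "*" if aa == "*" else aa


def classify_variant(v, genes, genome: ToyGenome,
                     flank: int = DEFAULT_FLANK) -> Consequence:
    """Classify a biallelic SNV against the gene models.

    Raises :class:`ReferenceMismatch` when the record's REF is not the
    genome base at its position.
    """
    if genome.base_at(v.chrom, v.pos) != v.ref:
        raise ReferenceMismatch(
            f"reference_mismatch at {v.chrom}:{v.pos}: record ref {v.ref!r} "
            f"!= genome {genome.base_at(v.chrom, v.pos)!r}")

    for gene in genes:
        if gene.chrom != v.chrom:
            continue
        off = gene.cds_offset(v.pos)
        if off is None:
            continue
        cds = genome.cds_sequence(gene)
        codon_i = off // 3
        within = off % 3
        codon = cds[3 * codon_i:3 * codon_i + 3]
        base = v.alt if gene.strand == "+" else revcomp(v.alt)
        alt_codon = codon[:within] + base + codon[within + 1:]
        ref_aa = _translate(codon)
        alt_aa = _translate(alt_codon)
        if alt_aa == ref_aa:
            term = "synonymous_variant"
            aa_change = None
        elif alt_aa == "*":
            term = "stop_gained"
            aa_change = f"{ref_aa}/*"
        else:
            term = "missense_variant"
            aa_change = f"{ref_aa}/{alt_aa}"
        return Consequence(term=term, impact=IMPACT[term], gene_id=gene.gene_id,
                           aa_change=aa_change)

    # not coding: nearest flank in transcript orientation
    for gene in genes:
        if gene.chrom != v.chrom:
            continue
        term = _flank_term(v.pos, gene, flank)
        if term is not None:
            return Consequence(term=term, impact=IMPACT[term], gene_id=gene.gene_id)
    return Consequence(term="intergenic", impact="Modifier")


def _flank_term(pos: int, gene: GeneModel, flank: int) -> Optional[str]:
    start, end = gene.span
    if gene.strand == "+":
        if start - flank <= pos < start:
            return "upstream_gene_variant"
        if end < pos <= end + flank:
            return "downstream_gene_variant"
    else:
        if end < pos <= end + flank:
            return "upstream_gene_variant"
        if start - flank <= pos < start:
            return "downstream_gene_variant"
    return None


def region_of_position(pos: int, gene: GeneModel) -> str:
    """Which half of the gene a genomic position falls in (5prime/3prime).

    Coding positions use their transcript offset against the gene's region
    boundary; positions outside the CDS count as 5prime when on the
    transcript-upstream side and 3prime when downstream (an SV starting
    upstream of the coding sequence belongs to the 5' region).
    """
    off = gene.cds_offset(pos)
    if off is not None:
        return "5prime" if off < gene.region_boundary else "3prime"
    start, end = gene.span
    upstream_side = pos < start if gene.strand == "+" else pos > end
    downstream_side = pos > end if gene.strand == "+" else pos < start
    if upstream_side:
        return "5prime"
    if downstream_side:
        return "3prime"
    # intron: compare genomically with the region-boundary position
    boundary_pos = position_at_offset(gene, gene.region_boundary - 1)
    if gene.strand == "+":
        return "5prime" if pos <= boundary_pos else "3prime"
    return "5prime" if pos >= boundary_pos else "3prime"


def assign_region(v, gene: GeneModel, flank: int = DEFAULT_FLANK) -> str:
    """Assign a variant to the 5' or 3' region of a gene.

    The variant must overlap the gene's CDS or its flanks; otherwise a
    ValueError is raised.
    """
    if gene.chrom != v.chrom:
        raise ValueError(f"variant {v.chrom}:{v.pos} not associated with "
                         f"gene {gene.gene_id}")
    off = gene.cds_offset(v.pos)
    start, end = gene.span
    if off is None and not (start - flank <= v.pos <= end + flank):
        raise ValueError(f"variant {v.chrom}:{v.pos} not associated with "
                         f"gene {gene.gene_id}")
    return region_of_position(v.pos, gene)


def gc_content(gene: GeneModel, genome: ToyGenome) -> float:
    """(G+C) fraction of the concatenated coding sequence (introns excluded)."""
    cds = genome.cds_sequence(gene)
    return (cds.count("G") + cds.count("C")) / len(cds)
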