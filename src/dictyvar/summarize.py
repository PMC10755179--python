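"""Summaries of the final variant set: per-gene tallies, cross-line
sharing, per-sample counts, and allele-frequency summaries by gene group.

A "line" is the leading integer of a sample id (population samples are the
bare line number; clones are hyphenated, e.g. "7-NF2"); the ancestor is
excluded. Per-line totals use union semantics: a SNP called in both a
line's population and its clone counts once for the line.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .records import SnpFixtureRow, sample_line


@dataclass
class GeneTally:
    n_snps: int
    n_lines: int
    consequences: Counter


def tally_per_gene(rows) -> dict:
    """gene_id -> (distinct sites, distinct lines, consequence counts)."""
    sites: dict = {}
    lines: dict = {}
    cons: dict = {}
    for row in rows:
        sites.setdefault(row.gene_id, set()).add(row.chrom_site)
        lines.setdefault(row.gene_id, set()).update(row.lines)
        cons.setdefault(row.gene_id, Counter())[row.consequence] += 1
    return {g: GeneTally(n_snps=len(sites[g]), n_lines=len(lines[g]),
                         consequences=cons[g])
            for g in sites}


def cross_line_sharing(rows) -> list:
    """Sites whose called samples span more than one evolved line.

    A clone and its own population count as one line.
    """
    shared = []
    for row in rows:
        if len(row.lines) > 1:
            shared.append(row)
    return shared


def per_sample_counts(rows, all_samples=None) -> dict:
    """sample_id -> number of distinct sites listing that sample."""
    counts: dict = {s: 0 for s in (all_samples or ())}
    for row in rows:
        for s in row.samples:
            counts[s] = counts.get(s, 0) + 1
    return counts


def per_line_counts(rows) -> dict:
    """line -> distinct sites called in any of the line's samples (union)."""
    sites: dict = {}
    for row in rows:
        for line in row.lines:
            sites.setdefault(line, set()).add(row.chrom_site)
    return {line: len(s) for line, s in sites.items()}


def consequence_counts(rows) -> Counter:
    return Counter(row.consequence for row in rows)


def mean_population_af(records, gene_subset, meta) -> float:
    """Mean origin-population alternate read fraction over a gene subset.

    ``records`` are final pipeline records with AF annotated and a
    ``gene_id`` attribute (set by annotation); the origin population of a
    record is the population sample of the line in which it was called.
    SNPs lacking a population AF are excluded with a warning. Returns None
    when the subset is empty.
    """
    pop_of_line = {m.line: m.sample_id for m in meta if m.role == "population"}
    by_id = {m.sample_id: m for m in meta}
    values = []
    for r in records:
        gene = (getattr(r, "gene_id", None)
                or getattr(getattr(r, "consequence", None), "gene_id", None))
        if gene not in gene_subset:
            continue
        called_lines = sorted({by_id[s].line for s in r.samples_with_alt()
                               if s in by_id and by_id[s].line is not None})
        afs = []
        for line in called_lines:
            pop = pop_of_line.get(line)
            call = r.calls.get(pop)
            if call is not None and call.af is not None:
                afs.append(call.af)
        if afs:
            values.append(sum(afs) / len(afs))
        else:
            warnings.warn(f"SNP {r.chrom}:{r.pos} lacks a population AF; excluded",
                          stacklevel=2)
    if not values:
        return None
    return sum(values) / len(values)


@dataclass(frozen=True)
class SiteRow:
    """Lightweight row adapter exposing the same interface as a fixture row."""

    chrom_site: str
    gene_id: str
    samples: tuple
    consequence: str
    impact: str
    aa_change: str = None

    @property
    def lines(self) -> set:
        return {sample_line(s) for s in self.samples}


def rows_from_records(records) -> list:
    """Adapt final pipeline records (with an attached ``consequence``) to the
    row interface consumed by the tally functions."""
    rows = []
    for r in records:
        samples = tuple(s for s in r.samples_with_alt() if s != "ancestor")
        if not samples:
            continue
        cons = getattr(r, "consequence", None)
        rows.append(SiteRow(
            chrom_site=f"{r.chrom}:{r.pos}",
            gene_id=getattr(cons, "gene_id", None) or "intergenic",
            samples=samples,
            consequence=getattr(cons, "term", "unannotated"),
            impact=getattr(cons, "impact", "Modifier"),
            aa_change=getattr(cons, "aa_change", None)))
    return rows
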