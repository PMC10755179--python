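"""TSV I/O: published-table fixtures, clone screens, sample metadata,
read-count tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .records import SnpFixtureRow
from .simulate import CloneScreenRecord, SampleMeta

SNP_FIXTURE_COLUMNS = ["chrom_site", "gene_id", "samples", "consequence",
                       "impact", "aa_change"]


def _split_gene(field: str):
    """'DDB_G0272244 (grlG)' -> ('DDB_G0272244', 'grlG')."""
    field = field.strip()
    if "(" in field:
        gid, name = field.split("(", 1)
        return gid.strip(), name.rstrip(")").strip()
    return field, None


def load_snp_fixture(path) -> list:
    """Load the published SNP table (six columns, tab-separated).

    Sample strings like "7 & 7-NF2" are split on "&"; the line of a sample
    is its leading integer. Unknown consequence strings raise a ValueError
    listing the allowed values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    rows = []
    for rec in df.itertuples(index=False):
        gid, gname = _split_gene(rec.gene_id)
        samples = tuple(s.strip() for s in str(rec.samples).split("&"))
        aa = rec.aa_change if isinstance(rec.aa_change, str) and rec.aa_change not in ("", "-", "—") else None
        rows.append(SnpFixtureRow(
            chrom_site=rec.chrom_site.strip(), gene_id=gid, gene_name=gname,
            samples=samples, consequence=rec.consequence.strip(),
            impact=rec.impact.strip(), aa_change=aa))
    return rows


def load_clone_screen(path, meta=None) -> list:
    """Load a clone-screen TSV (line, clone_id, variant_id, fruits, carries).

    Phenotype and genotype must be binary 0/1; duplicated
    (line, clone_id, variant_id) triples are an error. When sample metadata
    is provided, every line must have a population sample in it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line": int, "clone_id": str,
                                            "variant_id": str})
    records = []
    seen = set()
    known_lines = ({m.line for m in meta if m.role == "population"}
                   if meta is not None else None)
    for rec in df.itertuples(index=False):
        for field in ("fruits", "carries"):
            v = getattr(rec, field)
            if v not in (0, 1):
                raise ValueError(f"{field} must be 0 or 1, got {v!r}")
        key = (rec.line, rec.clone_id, rec.variant_id)
        if key in seen:
            raise ValueError(f"duplicated clone-screen record {key}")
        seen.add(key)
        if known_lines is not None and rec.line not in known_lines:
            raise ValueError(f"line {rec.line} not present in sample metadata")
        records.append(CloneScreenRecord(
            line=int(rec.line), clone_id=str(rec.clone_id),
            variant_id=str(rec.variant_id), fruits=bool(rec.fruits),
            carries=bool(rec.carries)))
    return records


def write_clone_screen(records, path) -> None:
    df = pd.DataFrame(
        [(r.line, r.clone_id, r.variant_id, int(r.fruits), int(r.carries))
         for r in records],
        columns=["line", "clone_id", "variant_id", "fruits", "carries"])
    df.to_csv(path, sep="\t", index=False)


def load_region_counts(path) -> dict:
    """Region-pooled clone-screen cell counts.

    Columns: region, carriers_nonfruiting, noncarriers_nonfruiting,
    carriers_fruiting, noncarriers_fruiting. Returns region ->
    ContingencyTable.
    """
    from .association import ContingencyTable

    df = pd.read_csv(path, sep="\t")
    return {rec.region: ContingencyTable(
        a=int(rec.carriers_nonfruiting), b=int(rec.noncarriers_nonfruiting),
        c=int(rec.carriers_fruiting), d=int(rec.noncarriers_fruiting))
        for rec in df.itertuples(index=False)}


def write_sample_meta(meta, path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, "" if m.line is None else m.line, m.role, m.phenotype)
         for m in meta],
        columns=["sample_id", "line", "role", "phenotype"])
    df.to_csv(path, sep="\t", index=False)


def load_sample_meta(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    meta = []
    for rec in df.itertuples(index=False):
        line = None if pd.isna(rec.line) or rec.line == "" else int(rec.line)
        meta.append(SampleMeta(sample_id=str(rec.sample_id), line=line,
                               role=rec.role, phenotype=rec.phenotype))
    return meta


def load_table1(path) -> pd.DataFrame:
    """Per-sample SNP counts and mean mapped depths (47 samples)."""
    return pd.read_csv(path, sep="\t", dtype={"sample": str})


def data_path(name: str) -> Path:
    """Path to a packaged fixture TSV."""
    return Path(__file__).parent / "data" / name
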