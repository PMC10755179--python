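"""End-to-end orchestration: simulate, filter, annotate, summarize,
associate, with a manifest of stage counts and output hashes."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import annotate as ann
from .association import screen_report
from .callers import emulate_callers
from .filters import FilterConfig, run_snv_cascade
from .genome import make_reference
from .records import sample_line
from .simulate import SimConfig, simulate_clone_screen, simulate_evolution, \
    simulate_readcounts
from .summarize import (consequence_counts, cross_line_sharing,
                        per_line_counts, per_sample_counts, rows_from_records,
                        tally_per_gene)
from .sv import filter_svs, sv_gene_overlap
from .tables import write_clone_screen, write_sample_meta
from .vcfio import VcfHeader, write_sv_vcf, write_vcf


@dataclass
class RecoveryStats:
    """Recovery of planted truth by the full cascade."""

    sensitivity: float  # recovered / planted with final frequency >= threshold
    n_eligible: int
    n_recovered: int
    fp_survivors: dict  # fp class -> number surviving (0 everywhere = specificity 1)
    sv_true_kept: int
    sv_fp_survivors: dict

    @property
    def specificity_ok(self) -> bool:
        return (all(v == 0 for v in self.fp_survivors.values())
                and all(v == 0 for v in self.sv_fp_survivors.values()))


def simulate_experiment(cfg: SimConfig, n_chroms: int = 2,
                        chrom_len: int = 200_000, n_genes: int = 12,
                        at_fraction: float = 0.77):
    """Convenience bundle: genome, truth, counts, emulated call sets."""
    genome = make_reference(n_chroms, chrom_len, n_genes, at_fraction,
                            seed=cfg.seed)
    truth = simulate_evolution(genome, cfg)
    counts = simulate_readcounts(truth, genome, cfg)
    emulated = emulate_callers(counts, truth, cfg)
    return genome, truth, counts, emulated


def measure_recovery(truth, counts, emulated, fcfg: FilterConfig,
                     freq_threshold: float = 0.2) -> RecoveryStats:
    """Run the cascade and score it against the planted truth."""
    result = run_snv_cascade(emulated.callset_a, emulated.callset_b, counts,
                             truth.sample_meta, fcfg)
    final_keys = {r.key for r in result.final}
    eligible = [m for m in truth.mutations if m.final_frequency >= freq_threshold]
    recovered = [m for m in eligible if m.key in final_keys]
    fp_survivors: dict = {}
    for key, klass in emulated.fp_classes.items():
        fp_survivors.setdefault(klass, 0)
        if key in final_keys:
            fp_survivors[klass] += 1
    kept_svs, _ = filter_svs(emulated.sv_calls, fcfg)
    kept_keys = {sv.key for sv in kept_svs}
    sv_fp: dict = {}
    for key, klass in emulated.sv_fp_classes.items():
        sv_fp.setdefault(klass, 0)
        if key in kept_keys:
            sv_fp[klass] += 1
    return RecoveryStats(
        sensitivity=(len(recovered) / len(eligible)) if eligible else 1.0,
        n_eligible=len(eligible), n_recovered=len(recovered),
        fp_survivors=fp_survivors,
        sv_true_kept=sum(1 for k in emulated.true_sv_keys if k in kept_keys),
        sv_fp_survivors=sv_fp)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: SimConfig, fcfg: FilterConfig, out_dir,
                 n_clones_per_line: int = 20) -> dict:
    """Execute all stages on a simulated experiment and write a run manifest.

    Stages: simulate -> filter-snv -> filter-sv -> annotate -> summarize ->
    associate. Every emitted file is listed in the manifest with a content
    hash; stage record counts make the narrative tallies machine-readable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}

    genome, truth, counts, emulated = simulate_experiment(cfg)
    header = VcfHeader(samples=[m.sample_id for m in truth.sample_meta],
                       contigs={c: len(s) for c, s in genome.chromosomes.items()})
    write_vcf(header, emulated.callset_a, out / "caller_a.vcf")
    write_vcf(header, emulated.callset_b, out / "caller_b.vcf")
    write_sv_vcf(header, emulated.sv_calls, out / "sv_calls.vcf")
    counts.to_tsv(out / "readcounts.tsv")
    write_sample_meta(truth.sample_meta, out / "sample_meta.tsv")
    manifest["stages"]["simulate"] = {
        "mutations": len(truth.mutations),
        "callset_a": len(emulated.callset_a),
        "callset_b": len(emulated.callset_b),
        "sv_calls": len(emulated.sv_calls),
    }

    result = run_snv_cascade(emulated.callset_a, emulated.callset_b, counts,
                             truth.sample_meta, fcfg)
    write_vcf(header, result.final, out / "final_snvs.vcf")
    _write_decisions(result.decisions, out / "snv_decisions.tsv")
    manifest["stages"]["filter_snv"] = result.stage_counts

    kept_svs, sv_decisions = filter_svs(emulated.sv_calls, fcfg)
    write_sv_vcf(header, kept_svs, out / "final_svs.vcf")
    _write_decisions(sv_decisions, out / "sv_decisions.tsv")
    manifest["stages"]["filter_sv"] = {"input": len(emulated.sv_calls),
                                       "kept": len(kept_svs)}

    for r in result.final:
        r.consequence = ann.classify_variant(r, genome.genes, genome)
    overlaps = sv_gene_overlap(kept_svs, genome.genes)
    manifest["stages"]["annotate"] = {
        "snvs": len(result.final),
        "sv_gene_overlaps": sum(1 for v in overlaps.values() if v)}

    rows = rows_from_records(result.final)
    gene_tallies = tally_per_gene(rows)
    summary = {
        "n_sites": len(rows),
        "n_genes": len([g for g in gene_tallies if g != "intergenic"]),
        "per_line": per_line_counts(rows),
        "per_sample": per_sample_counts(
            rows, [m.sample_id for m in truth.sample_meta]),
        "consequences": dict(consequence_counts(rows)),
        "shared_sites": [r.chrom_site for r in cross_line_sharing(rows)],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest["stages"]["summarize"] = {"sites": len(rows)}

    screen = simulate_clone_screen(truth, n_clones_per_line, cfg.seed)
    write_clone_screen(screen, out / "clone_screen.tsv")
    region_map = {m.variant_id: ("5prime" if m.mclass == "5prime" else "3prime")
                  for m in truth.mutations}
    report = screen_report(screen, region_map) if screen else None
    if report is not None:
        assoc = {
            "per_line": {str(k): {"table": v.table.cells, "p": v.p_value}
                         for k, v in report.per_line.items()},
            "per_region": {k: {"table": v.table.cells, "p": v.p_value,
                               "carrier_pct_nonfruiting": v.carrier_pct_nonfruiting,
                               "carrier_pct_fruiting": v.carrier_pct_fruiting}
                           for k, v in report.per_region.items()},
        }
        (out / "association.json").write_text(json.dumps(assoc, indent=2))
    manifest["stages"]["associate"] = {"screen_records": len(screen)}

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_decisions(decisions, path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tstage\tverdict\treasons\tnotes\n")
        for d in decisions:
            key = ":".join(str(k) for k in d.key)
            fh.write(f"{key}\t{d.stage}\t{d.verdict}\t"
                     f"{','.join(d.reasons)}\t{','.join(d.notes)}\n")
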