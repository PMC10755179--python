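"""Serial-passage evolution simulator.

Emulates the study design: replicate lines founded from one clonal
ancestor, passaged by replating a fixed number of thoroughly mixed spores.
Selected mutations follow a deterministic logistic recursion

    f' = f (1 + s) / (1 + f s)

(equivalently, the odds f/(1-f) multiply by (1+s) each passage) followed by
binomial resampling of the founders, so each passage is one
selection-plus-bottleneck step. Clones are single cells drawn at the final
frequencies; a clone carrying a 5'-class mutation is non-fruiting with a
configurable penetrance.

Read counts are emulated at the mapped-depth level (no reads, no aligner):
depth is Poisson around the role's mean and alternate reads are binomial at
the sample's allele frequency adjusted by a scalar error rate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genome import ToyGenome, BASES, position_at_offset as _pos_at_offset

MUTATION_CLASSES = ("5prime", "3prime", "other", "neutral")

#: Failure menu for injected caller false positives. Each class carries a
#: defect that exactly one filtration rule (or the cross-caller
#: intersection) is responsible for removing.
FP_CLASSES = (
    "low_qd",             # fails the QD > 2 hard filter (caller A)
    "strand_bias",        # SAR = 0, fails the strand-balance rule (caller B)
    "low_mqm",            # MQM <= 40, fails the mapping-quality rule (caller B)
    "low_qual",           # QUAL < 200 in both callers
    "excess_dp",          # site depth far above the surviving-set mean
    "missingness",        # uncalled in more than 10 samples
    "high_ac",            # alternate AC > 3 via multi-line planting
    "caller_a_only",      # never emitted by caller B
    "caller_b_only",      # never emitted by caller A
    "low_origin_support", # clone call with < 5 alt reads in its origin population
    "cross_line_support", # low-level alt support in several other lines' populations
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the published design: 24 replicate lines, 31 passages of
    one million founding spores, and mapped depths of about 195x for
    population samples and 54x for clones.
    """

    n_lines: int = 24
    n_passages: int = 31
    founder_count: int = 10 ** 6
    mutation_rate: float = 0.1        # expected new selected mutations / line / passage
    selection_coeff: float = 0.7      # per-passage relative advantage s
    penetrance_nonfruiting: float = 1.0
    depth_population: float = 195.0
    depth_clone: float = 54.0
    error_rate: float = 2e-4          # per-base error in the counted pileup
    ancestral_poly_sites: int = 50
    fp_sites: int = 22
    seed: int = 0
    # emulation parameters (not paper rules)
    callable_min_reads: int = 3
    callable_min_fraction: float = 0.05
    ancestral_maf_range: tuple = (0.55, 0.90)
    class_weights: dict = field(default_factory=lambda: {
        "5prime": 0.3, "3prime": 0.3, "other": 0.3, "neutral": 0.1})
    selection_by_class: dict = field(default_factory=dict)  # class -> s override
    initial_frequency: Optional[float] = None  # default 1 / founder_count
    n_true_svs: int = 3

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "penetrance_nonfruiting", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.founder_count < 1:
            raise ValueError("founder_count must be >= 1")
        if self.n_lines < 1 or self.n_passages < 1:
            raise ValueError("n_lines and n_passages must be >= 1")
        if self.selection_coeff < 0:
            raise ValueError("selection_coeff must be >= 0")
        lo, hi = self.ancestral_maf_range
        if not 0.5 <= lo <= hi <= 1.0:
            raise ValueError("ancestral_maf_range must lie in [0.5, 1]")

    def rng(self, label: str) -> np.random.Generator:
        """Labeled child stream of the single master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(label.encode())]))

    def s_for(self, mclass: str) -> float:
        if mclass == "neutral":
            return self.selection_by_class.get("neutral", 0.0)
        return self.selection_by_class.get(mclass, self.selection_coeff)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    line: Optional[int]  # None for the ancestor
    role: str            # ancestor | population | clone
    phenotype: str       # fruiting | nonfruiting | unknown

    def __post_init__(self) -> None:
        if self.role not in ("ancestor", "population", "clone"):
            raise ValueError(f"bad role {self.role!r}")
        if self.role in ("ancestor", "population") and self.phenotype != "unknown":
            raise ValueError("ancestor/population phenotype must be 'unknown'")


@dataclass(frozen=True)
class Mutation:
    line: int
    chrom: str
    pos: int
    ref: str
    alt: str
    mclass: str
    arise_passage: int
    trajectory: tuple  # frequency at passages 0..n_passages

    @property
    def final_frequency(self) -> float:
        return self.trajectory[-1]

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt)


@dataclass
class TruthSet:
    mutations: list
    sample_genotypes: dict  # (sample_id, (chrom,pos,alt)) -> 0/1 (ancestor + clones)
    sample_meta: list
    penetrance_nonfruiting: float = 1.0

    def mutations_of_line(self, line: int) -> list:
        return [m for m in self.mutations if m.line == line]

    def meta_by_id(self) -> dict:
        return {m.sample_id: m for m in self.sample_meta}

    def clones_of(self, line: int) -> list:
        return [m for m in self.sample_meta if m.role == "clone" and m.line == line]

    def population_sample(self, line: int) -> str:
        for m in self.sample_meta:
            if m.role == "population" and m.line == line:
                return m.sample_id
        raise KeyError(f"no population sample for line {line}")


@dataclass(frozen=True)
class CloneScreenRecord:
    line: int
    clone_id: str
    variant_id: str
    fruits: bool
    carries: bool


@dataclass(frozen=True)
class SitePlan:
    """Planned identity of a simulated site (truth / ancestral / false positive)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str                 # mutation | ancestral | fp
    fp_class: Optional[str] = None
    ancestor_maf: Optional[float] = None
    target_samples: tuple = ()   # samples with the planted signal (fp sites)
    support_samples: tuple = ()  # samples given fixed low-level support
    missing_samples: tuple = ()  # samples forced to zero depth

    @property
    def site(self) -> tuple:
        return (self.chrom, self.pos)


def logistic_trajectory(f0: float, s: float, n_passages: int) -> list:
    """Deterministic recursion iterated without resampling (test oracle)."""
    freqs = [f0]
    f = f0
    for _ in range(n_passages):
        f = f * (1 + s) / (1 + f * s)
        freqs.append(f)
    return freqs


def build_sample_meta(cfg: SimConfig) -> list:
    meta = [SampleMeta("ancestor", None, "ancestor", "unknown")]
    for line in range(1, cfg.n_lines + 1):
        meta.append(SampleMeta(str(line), line, "population", "unknown"))
    return meta  # clone phenotype depends on genotypes; clones added later


def simulate_evolution(genome: ToyGenome, cfg: SimConfig) -> TruthSet:
    """Plant selected mutations and evolve them through the passaging design."""
    rng = cfg.rng("evolution")
    classes = list(cfg.class_weights)
    weights = np.array([cfg.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()

    focal = genome.genes[0] if genome.genes else None
    other_genes = genome.genes[1:]
    chrom_names = list(genome.chromosomes)
    used_positions = set()
    f_init = cfg.initial_frequency or 1.0 / cfg.founder_count

    def draw_position(mclass: str):
        for _ in range(1000):
            if mclass in ("5prime", "3prime") and focal is not None:
                gene = focal
                if mclass == "5prime":
                    off = int(rng.integers(0, gene.region_boundary))
                else:
                    off = int(rng.integers(gene.region_boundary, gene.cds_length))
                pos = _pos_at_offset(gene, off)
                chrom = gene.chrom
            elif mclass == "other" and other_genes:
                gene = other_genes[int(rng.integers(len(other_genes)))]
                off = int(rng.integers(0, gene.cds_length))
                pos = _pos_at_offset(gene, off)
                chrom = gene.chrom
            else:  # neutral (or no genes): anywhere outside gene spans
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
                if any(g.chrom == chrom and g.span[0] - 10 <= pos <= g.span[1] + 10
                       for g in genome.genes):
                    continue
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("could not find a free site to plant a mutation")

    mutations = []
    for line in range(1, cfg.n_lines + 1):
        for passage in range(1, cfg.n_passages + 1):
            for _ in range(rng.poisson(cfg.mutation_rate)):
                mclass = classes[int(rng.choice(len(classes), p=weights))]
                chrom, pos = draw_position(mclass)
                ref = genome.base_at(chrom, pos)
                alt = str(rng.choice([b for b in BASES if b != ref]))
                s = cfg.s_for(mclass)
                traj = [0.0] * (passage - 1) + [f_init]
                f = f_init
                for _ in range(passage, cfg.n_passages + 1):
                    f = f * (1 + s) / (1 + f * s)
                    f = rng.binomial(cfg.founder_count, f) / cfg.founder_count
                    traj.append(f)
                mutations.append(Mutation(
                    line=line, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    mclass=mclass, arise_passage=passage,
                    trajectory=tuple(traj)))

    meta = build_sample_meta(cfg)
    genotypes = {}
    for m in mutations:
        genotypes[("ancestor", m.key)] = 0
    for line in range(1, cfg.n_lines + 1):
        clone_id = f"{line}-NF1"
        carried_5prime = False
        for m in mutations:
            if m.line == line:
                g = int(rng.random() < m.final_frequency)
            else:
                g = 0
            genotypes[(clone_id, m.key)] = g
            if g and m.mclass == "5prime":
                carried_5prime = True
        nonfruiting = carried_5prime and rng.random() < cfg.penetrance_nonfruiting
        meta.append(SampleMeta(clone_id, line, "clone",
                               "nonfruiting" if nonfruiting else "fruiting"))
    return TruthSet(mutations=mutations, sample_genotypes=genotypes,
                    sample_meta=meta,
                    penetrance_nonfruiting=cfg.penetrance_nonfruiting)


def plan_sites(genome: ToyGenome, truth: TruthSet, cfg: SimConfig) -> list:
    """Deterministic plan of every simulated site.

    Truth mutations come first, then ancestral-polymorphism sites (ancestor
    MAF drawn from the configured range, all below the masking threshold by
    default), then injected caller false positives cycling through
    :data:`FP_CLASSES`.
    """
    plans = [SitePlan(chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt, kind="mutation")
             for m in truth.mutations]
    used = {p.site for p in plans}
    rng = cfg.rng("site_plan")
    chrom_names = list(genome.chromosomes)

    def free_position():
        for _ in range(10000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("no free site available")

    lo, hi = cfg.ancestral_maf_range
    for _ in range(cfg.ancestral_poly_sites):
        chrom, pos = free_position()
        ref = genome.base_at(chrom, pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        maf = float(rng.uniform(lo, hi))
        plans.append(SitePlan(chrom=chrom, pos=pos, ref=ref, alt=alt,
                              kind="ancestral", ancestor_maf=maf))

    populations = [m.sample_id for m in truth.sample_meta if m.role == "population"]
    clones = [m.sample_id for m in truth.sample_meta if m.role == "clone"]
    all_samples = [m.sample_id for m in truth.sample_meta]
    n_lines = len(populations)
    for i in range(cfg.fp_sites):
        fp_class = FP_CLASSES[i % len(FP_CLASSES)]
        chrom, pos = free_position()
        ref = genome.base_at(chrom, pos)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        target: tuple
        support: tuple = ()
        missing: tuple = ()
        if fp_class == "high_ac":
            k = min(4, n_lines)
            picks = rng.choice(n_lines, size=k, replace=False)
            target = tuple(populations[j] for j in picks)
        elif fp_class == "low_origin_support":
            clone = clones[int(rng.integers(len(clones)))]
            target = (clone,)
            support = (str(_line_of(clone)),)  # origin population, fixed 3 reads
        elif fp_class == "cross_line_support":
            pick = int(rng.integers(n_lines))
            target = (populations[pick],)
            others = [p for j, p in enumerate(populations) if j != pick]
            k = min(4, len(others))
            idx = rng.choice(len(others), size=k, replace=False)
            support = tuple(others[j] for j in idx)
        elif fp_class == "missingness":
            target = (populations[int(rng.integers(n_lines))],)
            eligible = [s for s in all_samples
                        if s != "ancestor" and s not in target]
            k = min(12, len(eligible))
            idx = rng.choice(len(eligible), size=k, replace=False)
            missing = tuple(eligible[j] for j in idx)
        else:
            target = (populations[int(rng.integers(n_lines))],)
        plans.append(SitePlan(chrom=chrom, pos=pos, ref=ref, alt=alt, kind="fp",
                              fp_class=fp_class, target_samples=target,
                              support_samples=support, missing_samples=missing))
    return plans


def _line_of(sample_id: str) -> int:
    return int(sample_id.split("-")[0])


def simulate_readcounts(truth: TruthSet, genome: ToyGenome, cfg: SimConfig):
    """Emit per-site per-sample ref/alt read counts for every planned site."""
    from .records import ReadCountTable

    rng = cfg.rng("reads")
    plans = plan_sites(genome, truth, cfg)
    mut_by_site = {m.key[:2]: m for m in truth.mutations}
    table = ReadCountTable()
    e = cfg.error_rate

    for plan in plans:
        for sm in truth.sample_meta:
            mean_depth = cfg.depth_clone if sm.role == "clone" else cfg.depth_population
            depth = int(rng.poisson(mean_depth))
            if sm.sample_id in plan.missing_samples:
                depth = 0
            if plan.kind == "fp" and plan.fp_class == "excess_dp":
                depth *= 10

            f = 0.0
            if plan.kind == "mutation":
                m = mut_by_site[plan.site]
                if sm.role == "population" and sm.line == m.line:
                    f = m.final_frequency
                elif sm.role == "clone":
                    f = float(truth.sample_genotypes[(sm.sample_id, m.key)])
            elif plan.kind == "ancestral":
                minor = 1.0 - plan.ancestor_maf
                if sm.role == "clone":
                    f = float(rng.random() < minor)
                else:
                    f = minor
            else:  # fp
                if sm.sample_id in plan.target_samples:
                    f = 1.0 if sm.role == "clone" else 0.3

            if plan.kind == "fp" and sm.sample_id in plan.support_samples:
                # fixed low-level support, below the callable fraction
                alt_reads = min(3, depth)
            else:
                p = f * (1 - e) + (1 - f) * e
                alt_reads = int(rng.binomial(depth, p)) if depth > 0 else 0
            table.add(plan.chrom, plan.pos, sm.sample_id, plan.ref, plan.alt,
                      depth - alt_reads, alt_reads)
    table.site_plans = {p.site: p for p in plans}
    return table


def simulate_clone_screen(truth: TruthSet, n_clones_per_line: int, seed: int) -> list:
    """Draw fresh clones at final line frequencies and genotype/phenotype them.

    One record per clone x mutation of its line, mirroring the PCR screen of
    additional clonal isolates.
    """
    if n_clones_per_line < 1:
        raise ValueError("n_clones_per_line must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"screen")]))
    records = []
    lines = sorted({m.line for m in truth.sample_meta if m.line is not None})
    for line in lines:
        muts = truth.mutations_of_line(line)
        if not muts:
            continue
        for k in range(1, n_clones_per_line + 1):
            clone_id = f"{line}-S{k}"
            carries_5prime = False
            carried = {}
            for m in muts:
                g = bool(rng.random() < m.final_frequency)
                carried[m.variant_id] = g
                if g and m.mclass == "5prime":
                    carries_5prime = True
            fruits = not (carries_5prime
                          and rng.random() < truth.penetrance_nonfruiting)
            for m in muts:
                records.append(CloneScreenRecord(
                    line=line, clone_id=clone_id, variant_id=m.variant_id,
                    fruits=fruits, carries=carried[m.variant_id]))
    return records
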