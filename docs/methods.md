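# Methods

## The filtration cascade

The cascade treats two independently produced call sets (a
haplotype-based caller "A" and a pooled-continuous caller "B") as
replicates of the same inference and only trusts their intersection.
Per call set, in order:

1. **Ancestral mask.** A site is removed from all samples when the
   ancestor was called as a variant, was left uncalled, or its major
   allele frequency (MAF = majority reads / depth in the ancestor's
   pileup) is below `ancestor_maf_min` (default 0.90, strict `<`). A site
   absent from the ancestor's read counts is treated as uncalled and
   additionally flagged `ancestor_no_counts`.
2. **Hard filters.** Caller A: QD > 2, FS < 60, SOR < 3, MQ > 40,
   MQRankSum > −12.5, ReadPosRankSum > −8. Caller B: MQM > 40, SAF > 0,
   SAR > 0, SAP > 0.5, SRP > 0.5, RPR > 1, RPL > 1. All inequalities are
   strict. A *missing* metric does not fail its rule by default (rank-sum
   annotations are legitimately absent at sites without heterozygous-like
   evidence); it is recorded as a `metric_absent:*` note, and a strict
   policy is available via `FilterConfig(missing_metric_fails=True)`.
3. **Custom filters**, in order: indels and multi-allelic sites out;
   sites uncalled in more than `max_missing_samples` (10) samples out;
   alternate allele count (samples called alt, haploid, missing excluded)
   above `max_alt_ac` (3) out — with two or at most three samples per
   line, a real mutation cannot legitimately appear more often; QUAL
   below `min_qual` (200) out ("minimum of 200" read as ≥ 200 keeps);
   finally sites whose DP exceeds `dp_mean_factor` (1.5) times the mean
   DP *of the sites that survived the preceding custom rules of the same
   call set* are removed. That surviving-set scope is stated explicitly
   for caller B's pipeline and is adopted for both sides; it makes the DP
   rule order-dependent by construction, which the tests pin down
   exactly.
4. **Intersection.** A site survives only if present (same chromosome,
   position and alternate allele) in both filtered sets; the consensus
   record carries caller A's annotations. Same-site records with
   different alternates are dropped and flagged `alt_mismatch`.
5. **Read support.** Every SNP called in a clone must be supported by at
   least `min_origin_support_reads` (5) alternate reads in the clone's
   origin population ("at least 5" keeps exactly 5). Any SNP whose
   alternate allele has `shared_support_min_reads` (2) or more supporting
   reads in the populations of `shared_support_min_lines` (2) or more
   lines *other than those in which it was called* is flagged
   `cross_line_support` and dropped. The published rule gives no numeric
   criterion for "shared low-level support across multiple lines"; the
   2-reads/2-lines default is deliberately aggressive and both knobs are
   exposed in `FilterConfig`.

Manual browser review is replaced by the machine-checkable audit trail:
every removal is a `FilterDecision` with a stage, failing rules and
informational notes; nothing is dropped silently.

A caveat on monotonicity: tightening any single rule's threshold shrinks
that rule's surviving set, but thresholds upstream of the DP rule feed
its surviving-set mean, so tightening (say) the missingness cap can in
principle re-admit a high-DP site by lowering a low-DP site out of the
mean. The property tests therefore assert monotonicity per rule and for
the DP factor itself, not across the coupling.

## SV rules

Keep iff: FILTER is PASS, QUAL ≥ 20 (inclusive, per the stated rule),
paired-end support PE > 3 (PE > 5 would apply to translocations, but
translocations are excluded anyway as interchromosomal), type is a
simple single-interval DEL/DUP/INV/INS on one chromosome, and the SV is
genotyped in at most 3 samples. Gene overlap uses 1-based closed
intervals against CDS exons; the 5′/3′ region of an SV is decided by
where its start falls in transcript coordinates, with starts upstream of
the coding sequence counting as 5′.

## Association statistics

Clone screens are tallied into 2×2 tables: a = carriers ∧ non-fruiting,
b = non-carriers ∧ non-fruiting, c = carriers ∧ fruiting,
d = non-carriers ∧ fruiting. Significance uses Fisher's exact test
computed from first principles: with margins fixed, the two-sided p is
the sum of hypergeometric probabilities of all tables no more probable
than the observed one (the minimum-likelihood convention of the common
desktop packages; the original analysis does not state sidedness, and
two-sided is adopted). Probabilities are computed in log space from a
cached cumulative log-factorial table; the ≤-probability comparison uses
a 10⁻⁷ relative tie tolerance so floating-point noise cannot split tied
tables. Aggregation across lines is simple pooling of cells, per-line
tests are primary, and no multiplicity correction is applied (none was
applied originally). The odds ratio (a·d)/(b·c) is reported as a
companion effect size, with explicit infinite and undefined (0/0) cases.

Non-fruiting prevalence among clonal plaques is k/n with an exact
Clopper–Pearson interval obtained by beta-quantile inversion
(`Beta(k, n−k+1)` and `Beta(k+1, n−k)` quantiles at α/2 and 1−α/2). Where
a screen distinguishes total loss of fruiting from merely aberrant
fruiting bodies, choosing which clones count as non-fruiters is left to
the caller (pass the strict or the liberal k).

## The simulator

The generator emulates the study design, not its raw data:

- **Design.** One clonal ancestor; `n_lines` = 24 replicate lines;
  `n_passages` = 31; each passage replates `founder_count` = 10⁶
  thoroughly mixed spores. A passage is modeled as one
  selection-plus-bottleneck step (the published design reports ~290
  generations over 31 passages without stating generations per passage,
  so within-passage growth is left implicit).
- **Dynamics.** A selected mutation at frequency f follows the logistic
  recursion f′ = f(1+s)/(1+fs) — equivalently, odds multiply by (1+s)
  per passage — followed by binomial resampling of the founders. New
  mutations arise per line per passage as Poisson(`mutation_rate`) at
  initial frequency 1/`founder_count`.
- **Classes.** Mutations are 5′-class or 3′-class (both in the focal
  two-exon receptor gene, before/after the exon-1 boundary), "other"
  (elsewhere in coding sequence) or neutral (intergenic, s = 0). Clones
  are single cells drawn at the line's final frequencies; a clone
  carrying a 5′-class mutation is non-fruiting with probability
  `penetrance_nonfruiting` (default 1.0) — 3′-class mutations are
  selected but phenotype-neutral in isolation, mirroring the observed
  association pattern.
- **Read counts.** Mapped-depth level only: depth ~ Poisson(195) for the
  ancestor and populations, Poisson(54) for clones (the published mean
  mapped depths); alternate reads ~ Binomial(depth, f(1−e) + (1−f)e).
  The scalar error e defaults to 2×10⁻⁴, representing post-alignment,
  base-quality-filtered pileup counts rather than raw sequencer error;
  at 195× this keeps spurious ≥2-read support in an unrelated population
  below ~10⁻³ per site, so the cross-line rule stays specific.
- **Ancestral polymorphism.** `ancestral_poly_sites` (50) sites carry a
  standing minor allele in every sample; the ancestor's true MAF is drawn
  uniformly from `ancestral_maf_range` = (0.55, 0.90), i.e. all below the
  masking threshold. Sites near the top of that range may still show an
  observed MAF ≥ 0.90 by sampling noise, in which case the ancestor is
  called as a variant (callable threshold) and the site is masked by that
  rule instead — the mask is tested as a system, not a single inequality.
- **Caller emulation.** A site enters a sample's calls at ≥ 3 alternate
  reads and ≥ 5% of depth (an emulation parameter, not a published rule;
  exposed in `SimConfig`). True calls get passing metric values with
  jitter; QUAL is 20 × total supporting reads. `fp_sites` (22) injected
  false positives cycle through eleven failure classes — low QD, strand
  bias (SAR = 0), low MQM, low QUAL, excess DP, > 10 missing samples,
  AC > 3 via multi-line planting, caller-A-only, caller-B-only, < 5-read
  origin support, and cross-line low-level support — each carrying
  exactly the defect its responsible rule must catch. The SV set
  contains 3 planted true SVs plus one failing record per SV rule.
  Constructing the missingness class requires more than 10 of the
  samples to be blanked, so simulations exercising every class need at
  least 6 lines (13 samples).
- **Seeding.** A single master seed; every stochastic stage draws from a
  labeled child stream, so truth, counts, call sets and screens reproduce
  byte-for-byte for a given `SimConfig`.

What the generator does **not** emulate: reads, alignment, base-quality
profiles, the genome's simple-sequence repeats and low-complexity tracts
(a major real-world source of artifacts), linkage between co-segregating
mutations in one lineage (clone genotypes are drawn independently per
mutation), and multi-clone sampling per line. Passing recovery tests
therefore demonstrate that the cascade implements its rules correctly
and that those rules separate the modeled signal from the modeled
artifact classes — not that they would achieve the same sensitivity on
real AT-rich sequencing data.

## Toy genomes and annotation

`make_reference` builds random chromosomes at a tunable A+T fraction
(default 0.77, matching the organism's extreme AT richness) and places
non-overlapping two-exon genes (exon lengths 300–600 nt each, 60 nt
intron, random strand). Consequence classification translates the
affected codon (standard nuclear code, strand-aware): stop_gained/High,
missense/Moderate, synonymous/Low; positions within a 1 kb flank are
upstream/downstream gene variants (Modifier). Intron and far-intergenic
positions fall back to an intergenic/Modifier call — splice and UTR
classes are out of scope. The 5′/3′ region boundary defaults to the end
of exon 1 in transcript coordinates but any CDS offset is accepted,
since the halves are an analysis convention rather than a biological
annotation.

## Problem sizes and numerical choices

- Tests and the acceptance script validate recovery on 6-line × 31-passage
  simulations at full study depths, pooling 8 replicate seeds (~20–30
  eligible planted mutations at final frequency ≥ 0.2); the full 24-line
  configuration remains the default for library users.
- Sensitivity is scored on mutations with final frequency ≥ 0.2: below
  the callable band the pipeline is *designed* to reject clone-private
  calls without population support, so low-frequency planted mutations
  are expected casualties, as in the original stringent design.
- Fisher p-values are exact; the only tolerance is the 10⁻⁷ relative tie
  cushion. The exhaustive oracle check covers every 2×2 table with total
  ≤ 60 against an independent hypergeometric-pmf enumeration.
- Degenerate inputs: empty record lists flow through every stage as empty
  outputs; a contingency table with total 0 and prevalence with n = 0 are
  errors; an all-fruiting screen reports carrier percentage as "no data"
  (None) rather than 0.
- The DP rule with an empty surviving set is a no-op; `dp_mean_factor`
  may be set to infinity to disable it.

## Known limitations

- Genome-scale published results that depend on the deposited reads (the
  12 filtered SVs, the 61% vs 41% mean population read support contrast)
  are not reproduced at desk scale; the simulation-recovery properties
  and the qualitative selection-strength ordering stand in for them.
- The published SNP table does not print alleles, so its VCF
  reconstruction uses synthetic ref/alt bases; counts and identities are
  preserved, sequences are not.
- The pipeline models haploid calls only (the organism is haploid); no
  genotype likelihoods, realignment or base-quality recalibration.
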