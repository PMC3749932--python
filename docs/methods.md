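# Methods

`tandemsweep` analyses amplicon-resequencing and qPCR data from a genomic
region carrying a tandem triplication of a gene (copies labelled
HMA4-1/-2/-3), where a hard selective sweep acted on one copy's promoter
while ectopic gene conversion (EGC) keeps the three near-identical coding
sequences exchanging tracts. This note documents the models, the rules,
the numerical choices, and what the bundled simulator does and does not
emulate.

## The segment map

The region is observed through 13 ordered amplicon segments S1–S13:
distant single-copy controls (S1, S13, far enough to be effectively
unlinked), flanking controls (S2, S3, S11, S12), the three copy-specific
promoters (S4, S6, S9), the three jointly amplified 3′ coding portions
(S5, S7, S10), and a copy-2-specific downstream amplicon (S8) whose 5′
end reads into the copy-2 coding frame. Segment offsets (in bp) encode
the physical layout; the distant controls sit 198 kb and ~2.5 Mb outside
the array, following the syntenic distances reported for the congener
genome used in the original study design. Coordinates are 0-based
half-open internally, 1-based in reports.

## Clone cleaning

Sanger clones from one PCR amplicon of one individual are noisy draws
from the individual's alleles. Cleaning applies, in order:

1. **Clustering** of identical clone sequences per individual × amplicon.
2. **Taq-error correction.** A singleton clone is merged into a
   better-supported cluster when it differs at ≤ 2 positions
   (`max_taq_mismatches`) and each differing variant is observed in no
   other clone of the group (sole observer). The cap exists because a
   clone with many private differences is better explained as an
   unsampled allele than as a pile-up of polymerase errors; it is kept
   and flagged low-support instead. A polymerase error that happens to
   recreate another allele's base at a polymorphic column is invisible
   to the sole-observer rule, by construction.
3. **Chimera flagging.** PCR template switches create single-breakpoint
   recombinants. A clone is chimeric iff it matches no parent exactly
   but equals parent A up to a breakpoint and parent B after it, with at
   least 2 A/B-diagnostic sites on each flank (one flanking site is
   indistinguishable from a Taq singleton). Up to 2 clone-private
   sole-observer positions are masked first, so a chimera that also
   carries a Taq error stays detectable. Parent candidates are the
   group's authentic clusters. Clusters that themselves satisfy the
   authenticity rule are never flagged: EGC makes genuine alleles look
   recombinant, and a reproducibly observed sequence is treated as real.
   The rule therefore has a known blind spot — two independent template
   switches that produce the *same* chimeric sequence in two PCRs pass
   the authenticity rule and survive as a spurious allele. This is
   inherent to reproducibility-based authentication, not to this
   implementation.
4. **Authenticity.** A sequence is authentic when observed ≥ 3 times in
   one PCR or in ≥ 2 independent PCRs of the same genotype.
5. **Zygosity.** One authentic allele at a single-copy segment means an
   inferred homozygote; the second allele is materialized as a flagged
   duplicate row before any statistic (genealogy figures mark such
   alleles with an asterisk). More than two alleles at a single-copy
   segment is a hard error (contamination or unrecognized paralogy).

Cleaning is deterministic: permuting clone input order changes nothing.

## Paralog assignment

The 3′ coding amplicon co-amplifies all three copies, so a diploid
individual shows up to six alleles of unknown locus. Assignment combines
hard and soft evidence with an exact parsimony search:

- **S8-overlap anchors (hard).** A coding haplotype whose 3′ end equals
  the 5′ overlap of one of an individual's S8 alleles must occupy a
  copy-2 slot in that individual.
- **Reference anchors (soft).** A haplotype exactly matching a reference
  sequence of known position (e.g. from fully sequenced large-insert
  clones) has that copy seeded into its species-wide copy set. Soft,
  because EGC can place the same haplotype elsewhere in other
  individuals; a hard reading would make genuine conversion carriers
  infeasible.
- **Objective.** Minimize Σ_h (|copies(h)| − 1): prefer each haplotype
  to live at a single locus species-wide. All optima are enumerated by
  depth-first search with exact cost pruning; the search decomposes over
  connected components of the carrier graph (individuals linked by
  shared haplotypes), over which the objective is additive.
- **Ambiguity, not arbitration.** A haplotype whose copy set differs
  between optima is flagged ambiguous with the union reported — never an
  arbitrary pick. A haplotype multi-copy in *every* optimum is reported
  shared: that is the EGC evidence surface. A per-individual scoring
  mode is available (`scope="individual"`).

Identifiability caveat: presence-only data cannot prove sharing into a
locus when the recipient's slots can be rearranged around it (a strictly
more parsimonious non-sharing explanation exists whenever homozygosity
slack is available). Sharing is provable through the anchored copy-2 or
through slack-free carrier configurations; elsewhere the solver reports
ambiguity by design.

## Diversity and neutrality statistics

All per-site statistics use complete deletion (columns containing any
gap or N removed); indels re-enter only through gap recoding in the
network module. Inferred homozygote duplicates are materialized first.

- π is the mean pairwise difference per site (uncorrected by default; a
  Jukes–Cantor-corrected variant is exposed separately, since the
  convention of the classical analysis software is uncorrected).
  Reported in ‰ in profile tables.
- S counts polymorphic columns; η sums (alleles − 1) per column; η_s
  counts variants carried by exactly one sequence (at most alleles − 1
  per column, one allele being the background).
- Tajima's D uses the standard variance constants computed from n and S,
  with k̄ computed on exactly the masked columns used for S.
- Fu & Li's D* and F* are the outgroup-free forms based on η and η_s,
  with the corrected variance constants that later re-derivations of the
  original test established (the convention of DnaSP-era software). η
  rather than S enters throughout.
- Statistics undefined at S = 0 are reported NA, never 0.
- Divergence K between groups is the Jukes–Cantor correction of the mean
  between-group per-site mismatch; undefined at p̂ ≥ 0.75.
- The divergence–diversity relation across segments is summarized by OLS
  of K on π with the F(1, n−2) test.

Multi-copy segments are flagged in profiles: their pooled π mixes
paralogs (that elevation *is* the concerted-evolution signal); per-copy
values are available after assignment.

## Haplotype networks

Gap runs are recoded so one indel event equals one mutational step:
maximal gap runs with identical boundaries are one shared binary state;
any boundary or length difference makes distinct states; all columns
covered by any run are removed from the SNP matrix, so an event is never
double-counted. The network connects haplotypes in order of increasing
recoded distance, adding all pairs at the level where their components
first touch (ties yield retained loops — with EGC the reticulation is
the signal), and expanding multi-step edges into chains of unnamed
intermediates.

The 95% connection limit comes from a statistical-parsimony estimator:
substitutions hit sites uniformly; a connection of j observed steps over
L sites is parsimonious when no site was hit twice; the number of actual
substitutions is estimated from j/L with the Jukes–Cantor multiple-hit
correction M = min(max(j, round(L·K(j/L))), L−1), giving
P = Π_{i<M} (1 − i/L); the limit is the largest j with P ≥ 0.95
(L=1252 → 11 steps at the defaults). This follows the logic of the
classical estimator; numeric parity with the historical TCS binary's
undocumented rounding is not claimed.

## Genealogies

Trees are distance-based (neighbor joining on p- or JC distances) with
column-bootstrap support percentages (seeded, deterministic), negative
branch lengths clamped to zero with a log notice, and optional outgroup
rooting. Likelihood tree search is deliberately out of scope — for these
data distance methods give the same branching orders — and outputs are
labelled distance-based. The sweep leaves a tree-shape signature: short
internal branches (star-like genealogies) at swept segments.

## AMOVA

Three nested levels: geographic regions / collection sites within
regions / alleles within sites, with two alleles per diploid individual
as the units. Distances are weighted difference counts (transitions =
transversions = 1, deletions = 0). Squared distances are partitioned
into sums of squares per level; method-of-moments coefficients for
unequal group sizes give the variance components and Φ-statistics
(Φ_CT regions/total, Φ_SC sites/within-region, Φ_ST combined).
Negative component estimates are reported as-is with a flag
(truncation at zero is an option, not the default). Permutation schemes:
alleles among sites across the sample (Φ_ST), alleles among sites within
regions (Φ_SC), whole sites among regions (Φ_CT);
p = (#{perm ≥ obs} + 1)/(n_perm + 1), seeded. On very small datasets a
permutation can reconstruct a maximal configuration, so p > 1/(n+1) is
possible even for perfectly structured data.

## qPCR quantification

Reaction efficiency E is estimated per reaction by window of linearity:
baseline = median of the first 5 cycles; candidate windows of 4–6
cycles within the exponential phase (above 3× baseline noise, below 2%
of the signal maximum — saturation flattens the log-linear slope and
biases E downward); the window with the best linear fit of log10 F vs
cycle wins, E = 10^slope ∈ (1, 2]. Implausible single-reaction fits are
excluded with a log entry; the per-amplicon mean E over reactions is
applied (per-reaction mode available behind a flag).

Relative quantity RQ = E^(Cq_cal − Cq_sample). Copy number = target RQ
divided by the geometric mean of ≥ 2 single-copy reference RQs, scaled
so a single-copy calibrator genome equals 1. s.e.m. over technical
replicates is propagated through E^(ΔCq ± sem). Reference adequacy is
scored geNorm-style: V_jk = SD over samples of log2(RQ_j/RQ_k), M_j =
mean_k V_jk, plus the pairwise-variation CV of normalized reference
quantities. Transcript levels use the two-efficiency ratio
E_t^(ΔCq_t)/E_r^(ΔCq_r) against a constitutive reference gene and a
calibrator sample, with per-primer-pair efficiencies (1.88/1.90 defaults
for the two target assays).

## The forward simulator

A diploid Wright–Fisher population carries the 13-segment region
(600 bp per segment). Per generation: fitness-weighted parent sampling
within island-model demes (one deme per collection site, migration 0.1),
meiotic crossover at segment boundaries with probability proportional to
the physical gap (1e-4 per kb per meiosis), finite-sites Jukes–Cantor
mutation, and EGC events copying a geometric tract (mean 400 bp, allowed
to enter from outside the segment) between array copies of the same
individual. The three coding segments start identical (the
post-duplication state) and diverge by mutation against homogenization
by EGC. After a 10N-generation burn-in a beneficial mutation (additive
s = 0.2) is injected mid-promoter of the third copy and conditioned on
fixation by re-running from the injection state; sampling happens 20
generations after fixation, emulating a very recent completed sweep.

Defaults are desk-scale study conditions, chosen once: N = 200, μ =
6.25e-6 per base per generation so that θ = 4Nμ = 5‰ matches the
observed neutral control diversity; s = 0.2 because at N = 200 a weaker
sweep (2Ns ≈ 20) fixes in a substantial fraction of 2N generations and
cannot produce the deep diversity valley a strong recent sweep leaves —
rescaling selection upward while shrinking N is standard practice; EGC
g₀ = 5e-4 per copy per generation with 400-bp tracts, an exploratory
choice (tract lengths and rates for this locus are unquantified) that
realizes the qualitative fingerprint: elevated within-copy coding
diversity, suppressed between-copy divergence, and occasional
whole-amplicon shared haplotypes. These parameters are **not** a
calibrated demographic fit to any real population.

Artifact emulation: clones are drawn per individual × amplicon × PCR
(2 PCRs × 6 clones for single-copy amplicons; 3 × 19 for the six-allele
coding pool); with probability 0.05 a clone is replaced by a
single-switch chimera of two distinct templates; Taq errors hit at
2e-4 per base. qPCR plates carry Cq = Cq_cal − log_E(quantity) +
N(0, 0.15), with 16 technical replicates for the genomic assay and 3
per cDNA for transcripts; amplification curves are synthesized as
baseline plus a saturating exponential. Transcript levels of array
carriers are 50-fold the calibrator with lognormal biological scatter
(σ = 0.4), spanning roughly 20–130-fold.

What the simulator does **not** emulate: sequencing base-call errors and
quality scores, alignment uncertainty (all sequences share coordinates
by construction, so no aligner is needed or provided for synthetic
data), indel mutation (network gap recoding is exercised on constructed
fixtures), copy-number variation between individuals, selfing, and
linked selection beyond the single sweep. Passing tests therefore show
the *rules and estimators* behave correctly under the stated model, not
that the model captures every property of field data.

## Statistical checks and their problem sizes

The test suite validates π/S/η/η_s/θ_W against brute-force enumeration
(100 random alignments, 1e-12), Tajima's D and Fu & Li's D*/F* against
exact-rational transcriptions of their constants (1e-10), neutral
calibration of D on 500 coalescent samples (n=20, θ=5, within 3 MC-SE
of 0), the sweep fingerprint on 40 forward replicates (profile minimum
at the swept promoter on the replicate mean; D < 0 there in ≥ 90% of
replicates — per-replicate location of the minimum is dominated by
single-locus coalescent variance, so the averaged profile is the
meaningful statement), the EGC fingerprint on 15 replicates per
conversion rate in {0, g₀, 10g₀} (monotone within MC error, significant
end-to-end), chimera precision/recall ≥ 0.95 (recall over chimeras with
≥ 2 diagnostic sites per flank that are not authenticity-shielded),
Taq-singleton correction (clones with ≤ 2 sole-observer errors and a
supported source), assignment recovery on 50 synthetic instances (no
confidently wrong label; ambiguity unions cover the truth), and integer
copy-number recovery (≥ 95% at σ_Cq = 0.15). Replicate counts are sized
for a single CPU; `scripts/acceptance.py` re-derives the same
quantities from scratch at configurable sizes.

## Known limitations

- The connection-limit estimator matches the published logic, not any
  specific historical binary.
- The authenticity rule's blind spot for recurrent identical chimeras
  (above).
- Parsimony assignment is exact but presence-only; read depths are not
  used as evidence.
- Desk-scale simulation parameters are rescaled, not fitted; absolute
  values (e.g. fixation times) should not be interpreted
  demographically.
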