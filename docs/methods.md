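# Methods

This document records the statistical model, the default parameters and why
they were chosen, what the synthetic-data generator does and does not
emulate, the numerical choices, and the known limitations. Nothing here
asserts an empirical result that is not computed by the test suite or by
`scripts/acceptance.py`.

## Data model

- Coordinates are 1-based and closed on both ends. Chromosome names are
  normalized by stripping a `chr` prefix, so `chr1` and `1` are one axis.
- Indel alleles are anchored (VCF style): a deletion's `ref` is the anchor
  base plus the deleted bases and its `alt` is the anchor; insertions are
  the mirror image. The record validates this at construction.
- Segment profiles are canonicalized on entry: the minor allele is folded to
  `min(minor, total − minor)`, segments are sorted, and overlaps are an
  error. All downstream scores operate on the canonical form, so row order
  and major/minor labeling in input files cannot change a result.
- Two assembly fixtures ship with the package: `toy` (three 100 Mb
  chromosomes, fast tests) and `hg19_fixture` (chr1–22 and X with standard
  lengths and centromere intervals, for realistic arm capacities). Both are
  small TSVs; user assemblies load from the same format.

## Genomic scar scores

Per autosomal arm, segments are clipped to the arm, then smoothed to a fixed
point by alternately (i) dropping segments shorter than 3 Mb and (ii)
merging physically ordered neighbours with identical allele-specific states
(the merge spans the gap left by a drop). After smoothing:

- **LST** counts ordered pairs of adjacent segments that are each ≥ 10 Mb
  and differ in allele-specific state; the sample score is the autosomal sum.
- **NtAI** counts allelic-imbalance segments (total − minor ≠ minor) that
  touch the telomeric end of an arm, do not cross the centromere, and do not
  constitute a whole-chromosome imbalance.
- **FGA** is the length-weighted fraction of segmented genome whose total
  copy number differs from the sample baseline `round(ploidy)`; sex
  chromosomes are excluded.

The 3 Mb filter runs before merging, so two adjacent sub-3 Mb pieces of one
state are removed rather than merged; split-invariance of the scores
therefore holds only for splits whose pieces stay ≥ 3 Mb (the property
tests respect this).

Decision boundaries: LST-high is `lst ≥ 15` (inclusive); NtAI support is
`ntai > 16` (strict). These are the published whole-exome thresholds for
the HRD scar literature and are carried in `RunConfig`, not hard-coded.

## Mutational signatures

SNVs are tallied into 96 channels — six pyrimidine-centred substitution
types by 16 flanking contexts — with purine-reference sites folded by
reverse complement. Context comes from ±1 bp of the supplied reference; a
record whose `ref` disagrees with the reference sequence is an error (not a
skip), while chromosome-edge sites are skipped with a warning and counted.

Exposures are refit by nonnegative least squares against a fixed dictionary:
minimize ‖c/Σc − Sw‖₂ subject to w ≥ 0, zero out normalized weights below
0.06, refit on the retained support until stable, renormalize to sum 1.
The 0.06 floor is the convention of standard refitting tools; it suppresses
spurious small assignments that NNLS otherwise distributes across many
columns. Samples with fewer than 20 SNVs are flagged `insufficient_snvs`
and not refit — below that count the 96-channel spectrum is too sparse for
a stable fit. The dominant signature groups as: signature 3 → HRD,
signatures 1/5 → aging, else other.

**The packaged signature dictionary is synthetic.** It is a deterministic
96×30 matrix (fixed internal seed) whose leading columns mimic the
qualitative shapes of well-characterized processes: signature 1 concentrates
C>T at NpCpG, signatures 2/13 concentrate C>T / C>G at TpCpN, signature 3 is
near-flat, signature 5 is flat with a T>C lean, and the rest are random
sparse profiles. It supports simulation, refitting, and grouping logic, but
weights fit against it are not comparable to fits against the reference
catalog. Any 96×K probability-column DataFrame can be passed in its place.

## Small-deletion microhomology

For a deletion of length L with both flanks available, the microhomology
length is `max(LCP(deleted, 3' flank), LCS(deleted, 5' flank))` capped at
L − 1, where LCP/LCS are longest common prefix/suffix. A full-length match
on either side means the deletion lies inside a longer perfect repeat and
is classified repeat-mediated — never microhomology. A flank shorter than
L (chromosome edge) yields a *missing* call, not zero. A junction counts as
microhomology-mediated at ≥ 2 bp: a 1 bp match arises by chance ~1/4 of the
time. Deletions longer than 50 bp are excluded from the length statistics
(exome callers rarely emit larger events); the long-deletion flag is a mean
deleted length ≥ 5 bp.

## HRD feature set

The per-sample call joins the scar flags, deletion features, and dominant
signature group. By default `hrd_call` is "dominant signature 3"; an
optional k-of-n voting mode over the four supporting flags exists for
sensitivity analyses. Sample-id mismatches across the joined inputs are an
error. MSI-high is a precomputed instability score ≥ 3.5; hypermutation is
≥ 1000 somatic mutations, and hypermutated samples must be excluded before
any cohort comparison (the cohort wrappers enforce this).

## Clonality index

For lesions A and B, mutations are matched on (chrom, pos, ref, alt) after
trimming shared allele padding (suffix then prefix). Each shared mutation j
carries a chance probability q_j of independent recurrence; the clonality
index is `−log10 Π q_j` and the pair is related when `Π q_j < alpha`
(default 0.05). The default background model uses hotspot recurrence
frequencies for hotspot-flagged mutations and (gene cohort frequency) /
(gene coding length) otherwise, with conservative defaults (0.01 over
1500 bp) for unannotated genes; `q_of` accepts any callable override. The
allele trimming canonicalizes padding differences only — it does not shift
indels through repeat runs, which would require the reference sequence.

## Clonal decomposition

**Filters.** A paired mutation is retained iff (a) matched-normal depth
≥ 20, (b) tumor depth ≥ 50 in every component, (c) at least one component's
VAF is ≥ 5× the normal VAF, and (d) tumor depth ≤ 1500 in every component
(above that, mapping artifacts dominate). The rejection tally attributes
each rejected mutation to the first failing rule in (a)–(d) order;
retention itself is order-independent.

**CCF.** With purity ρ, local total copy number CN_t and multiplicity m,
the expected VAF is `ccf · ρ · m / (ρ · CN_t + (1 − ρ) · 2)`.
`estimate_ccf` inverts this for each m in 1..CN_t and keeps the candidate
closest to [0, 1], ties to the smaller m. Mutations outside any segment, or
in zero-copy regions, default to CN_t = 2 with a warning.

**Clustering.** A Dirichlet-process mixture in which each cluster carries
one CCF per component and a mutation's alt count in component c is
beta-binomial around the expected VAF with fixed precision 500 (the
published default for this model family; it encodes overdispersion beyond
binomial sampling). The per-mutation multiplicity is *marginalized* over
1..CN_t with a geometric prior (odds 0.25 per extra copy) favouring
single-copy states: most somatic point mutations sit on one chromatid, and
a flat prior leaves a ccf-versus-ccf/2 degeneracy at even copy numbers
while a hard per-mutation choice is unstable exactly when a candidate CCF
crosses 1. Inference is blocked Gibbs on a truncated stick-breaking
representation (truncation 20): joint assignment updates, stick weights,
gridded cluster CCFs (101-point uniform grid, sampled by the Gumbel-max
trick), and a Gamma(1, 1)-prior concentration update. Defaults: 20 000
iterations, 10 000 burn-in, thinning 10. Hard clusters are connected
components of the posterior co-clustering graph thresholded at 0.5 —
deterministic given the chain, no label-switching heuristics. Clusters are
presented largest-mean-CCF first.

**Rules.** A cluster is truncal iff its CCF is within 0.1 of the per-
component maximum in every component. Clonal selection is reported when a
non-truncal cluster has CCF ≤ 0.3 in one component and ≥ 0.7 in the other;
the verdict names the component where the subclone dominates. The clone
tree is two leaves (one per component) on a trunk; branch lengths are
aggregated cluster sizes, and a branch cluster attaches to the component
with the higher CCF (alphabetical tie-break).

## Cohort statistics

Fisher's exact test (two-sided, via `scipy.stats.fisher_exact`) for 2×2
frequency tables; Mann-Whitney U (two-sided, via `scipy.stats.mannwhitneyu`)
for continuous comparisons, using the exact null when both groups have
n ≤ 25 and the pooled data are tie-free, and the tie-corrected normal
approximation otherwise; Benjamini-Hochberg q-values (via statsmodels) over
exactly the family of tests passed in one invocation — families are never
merged across calls. Enumeration oracles for all three live in the test
suite, so the library conventions are pinned, not assumed. Pathway
summaries are deterministic alteration fractions over curated canonical
gene sets (p53, PI3K, Wnt, Notch) shipped as a replaceable data file.

## Synthetic-data generator

What it emulates, and what it does not:

- `simulate_reference`: uniform-random A/C/G/T with centromeres at 45–55%
  of length. No GC structure, repeats, or gaps — sufficient for context
  lookup and placement, not for alignment realism.
- `simulate_snv_catalog`: draws each SNV's channel from the requested
  signature mixture and places it at a matching reference context
  (reverse-strand placements emit the purine representation), so the
  catalog builder must reproduce the drawn channel tally exactly. Depths
  are Poisson, alt counts binomial at VAF 0.5; no selection, clustering,
  or regional mutation-rate variation.
- `simulate_indel_set`: rejection-samples deletion placements until the
  package's own detector reports exactly the planted microhomology length
  (0 or a value in the requested range), giving an exact round-trip truth.
- `simulate_segment_profile`: plants LST events as chains of alternating
  *balanced* ≥ 10 Mb states — (2,1) and (4,2) — confined to arm interiors
  so they add transitions without creating allelic imbalance, and NtAI
  events as 5 Mb (3,1) telomeric blocks on arms not used for LST (≥ 3 Mb
  so they survive filtering, < 10 Mb so they add no LST). Sub-3 Mb noise
  segments are carved only where both remnants stay ≥ 3 Mb. Scores are
  therefore exact by construction, which is what makes the scar round-trip
  a real test of the filter/merge logic. Infeasible requests fail loudly
  naming the constraint.
- `simulate_paired_components`: beta-binomial read counts around the
  expected VAF for planted (ccf_A, ccf_B, n) clusters, with a binomial
  sequencing-noise floor (rate 1e-3) for absent mutations. Positions are
  synthetic and evenly spaced; no linkage or copy-number variation unless
  a cn profile is passed.

## Numerical choices

- Expected VAFs inside the clustering likelihood are clipped to
  [1e-3, 1 − 1e-3] so zero-CCF grid points have finite log-likelihood
  (sequencing error keeps real alt fractions off exact zero).
- Categorical sampling uses the Gumbel-max trick on log scores, avoiding
  exponentiation and normalization of large N×K matrices.
- Log-sum-exp is used for the multiplicity marginalization; stick-breaking
  fractions are clipped away from {0, 1} before taking logs.
- All random draws go through `numpy.random.default_rng` with explicit
  seeds; fits and simulations are reproducible given the seed, and the
  co-clustering hard assignment is deterministic given the chain.
- The related/unrelated clonality verdict compares `10^log10(Πq)` to alpha;
  probabilities within floating-point distance of alpha are inherently
  boundary cases, and the tests probe the threshold from both sides rather
  than exactly at it.

## Open design points and limitations

- The signature dictionary is synthetic (see above); exposures are not
  comparable across dictionaries. At small catalog sizes (hundreds of
  SNVs) the near-flat signature 3 is hard to separate from other flat-ish
  columns; the acceptance criterion pins recovery at 5000 SNVs.
- The clonality background model's default gene frequency/length values are
  deliberately conservative placeholders; real use should supply cohort-
  derived tables. The index ignores copy-number context of shared sites.
- The decomposition assumes exactly the components present in the input,
  clonal copy number (one CN_t per site per component), and no subclonal
  copy-number events; multiplicity is marginalized, not estimated per
  mutation.
- Scar scores assume absolute (allele-specific, purity/ploidy-corrected)
  copy-number input; the package does not perform segmentation or purity
  estimation.
- Arm-level smoothing drops sub-3 Mb segments before merging (see Scars);
  alternate orderings exist in the literature and would change edge cases.
- The hypermutation (1000 mutations) and MSI (3.5) cutoffs are calling
  conventions for exome panels, not fitted quantities; both live in
  `RunConfig` for sensitivity analyses.
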