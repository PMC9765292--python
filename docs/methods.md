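# Methods

## The screening model

The pipeline analyses a pooled CRISPRi conditional-knockdown screen.
Each cell carries one constitutively expressed gRNA and an inducible
dCas9; on induction, the gRNA directs transcriptional silencing of its
target. The pool is grown under three conditions — mock (no induction),
Ci (dCas9 induced) and Ci+C (dCas9 plus competence induction) — for G
generations, and guide abundances are read out by amplicon sequencing.
Silencing a gene that is costly under a condition depletes its guides
there; the analysis turns per-guide depletion into per-gene calls and
isolates the genes whose cost is *specific* to competence induction.

## Guide design

Candidate protospacers are every 20-nt window immediately 5' of an NGG
PAM, on both strands, with origin-spanning windows included on circular
replicons. Windows containing any non-ACGT base are dropped (an N can
match nothing at synthesis time). Effective CRISPRi inside a
transcribed feature requires the spacer to base-pair with the coding
(nontemplate) strand; operationally, a candidate overlapping a
CDS-like feature on strand σ by at least one protospacer base is
retained iff its protospacer lies on the opposite strand. Candidates
overlapping no annotated feature are intergenic and retained on either
strand (no strand preference is defensible without knowing the
direction of transcription). Candidates that fail the strand rule for
every overlapped feature and are not wholly intergenic are rejected:
the partial-overlap case is resolved by the any-overlap rule, the
permissive choice that maximizes coverage. rRNA and tRNA loci follow
the CDS rule by default (they are transcribed units with a defined
template strand); this is configurable because annotation practice
varies. Guides passing for several overlapping features are assigned,
for gene-level statistics, to the feature with the largest overlap.

Spacer sequences occurring more than once among retained guides are
flagged multi-target and excluded from all gene-level statistics —
their counts cannot be attributed to a locus — but are kept in the
library file. Library density statistics report the retained-guide
count, genome length / n_guides (mean spacing), and the median guide
count over CDSs including zero-guide CDSs, with the midpoint convention
for even counts.

## Counting and normalization

Spacers are extracted from reads by exact matching of both constant
anchors with exactly 20 nt between them, trying both read orientations;
a per-anchor one-mismatch mode exists but is off by default because
exact matching keeps counting deterministic and the amplicon chemistry
is designed to avoid chimeras. Reads failing extraction or carrying a
spacer absent from the library increment the sample's unassigned tally,
so assigned + unassigned always equals reads processed. Replicates are
pooled by raw-count summation *before* normalization (the contrast is
between pooled condition totals). Size factors are median-of-ratios: the
per-guide geometric mean across samples (over guides nonzero in every
sample) is the reference profile, and each sample's factor is the median
ratio to it. Note a subtlety: scaling one sample's depth by k moves the
geometric-mean reference by k^(1/m), so the normalized matrix is defined
only up to one global factor; every between-sample fold change — the
only quantity used downstream — is exactly depth-invariant, and the
tests assert that form of the invariant.

## Gene scores and significance

Guide lfc uses a pseudocount of 1 in both numerator and denominator
(bounded at zero counts). The signed gene score is the median of its
guides' lfc — a deliberate, documented definition: published screens
often plot an algorithm-internal score whose formula is not stated, and
the median is robust, monotone in the planted effect (expected lfc =
G·s) and directly interpretable. Significance is a robust rank
aggregation: each included guide gets rank percentile u = rank(lfc)/n
(average ranks on ties); for a gene with sorted percentiles u(1) ≤ … ≤
u(k), ρ is the minimum over j with u(j) ≤ α of BetaCDF(u(j); j, k−j+1),
and 1 if no percentile clears α (default α = 0.25 — only the most
depleted quartile of the ranking counts as evidence). The null
re-assigns percentiles from the pooled ranking to gene slots of the same
size, without replacement; p = (1 + #{ρ_perm ≤ ρ_obs})/(B+1) with B =
10,000 by default (1,000 in tests), BH-adjusted within each tail. The
enrichment tail uses reversed percentiles. ρ depends only on ranks, so
it is invariant under monotone transforms of lfc; the permutation
scheme was verified against exhaustive enumeration of all C(20,3)
assignments at k = 3.

## Residual calling

Gene scores of Ci+C-vs-mock (y) are regressed on Ci-vs-mock (x) by OLS
over the inner join on locus tags. Shared fitness effects (essential
genes) fall on the line; competence-specific effects deviate.
Residuals are internally studentized (leverage-corrected) by default —
the statistical convention — with the plain e/σ̂ form available via
config; at screen scale (hundreds to thousands of genes, leverage
h ≈ 1/n) the two differ negligibly, and both are exposed so the
difference can be reported. Classification uses strict inequalities at
±2.5 (ties are neutral), the conventional outlier band. A numerically
perfect fit (R² ≥ 1 − 1e−12) returns all-zero residuals rather than
0/0. Calls are confirmed against the direct Ci-vs-Ci+C contrast: a
depleted (enriched) call is confirmed iff its depletion-tail
(enrichment-tail) FDR there is ≤ 0.05.

## Reporter screen

Specific Lux activity is the sum over the time course of RLU/OD600.
Timepoints below an OD floor of 0.01 are excluded: cultures start at
OD 0.05, so the floor only removes near-blank wells where the ratio
explodes; no blank-well subtraction is applied by default. Clone effect
is log2(specific activity / reference specific activity). Per gene,
distinct selected spacers are counted once (re-isolated clones with the
same spacer average their fold changes into one guide value), the
normalized count divides by the gene's library guide count, and the
antagonist call requires normalized count > 0.02 and mean log2FC > 0.5,
both strict. The 0.02 threshold is the primary published convention; a
footnote variant of 0.01 exists in the source literature, so the cutoff
is configurable. The agonist class mirrors the antagonist rule at mean
log2FC < −0.5 and is labeled an extension, since only the antagonist
cutoffs are published. Transformation rate is
(CFU_selective·dilution_selective)/(CFU_total·dilution_total), with
zero selective colonies encoded as not-detected rather than zero.

## COG profiling

Each gene carries at most one category letter (highest-scoring
assignment, taken as an input table). Per screen and category the
profile reports hits and 100·hits/genome_total — weighting by category
size so large categories do not dominate. Hit admission mirrors the
screens' own selections: all transformation-screen genes, depletion
genes with standardized residual < −2.5, reporter genes passing both
antagonist cutoffs. Unassigned hits form an explicit bucket (undefined
percentage) instead of being dropped.

## Synthetic data generator

The generator produces what the analysis consumes, with ground truth:

- **Genome**: random circular sequence at GC 0.40 (typical for
  salivarius-group streptococci) with non-overlapping CDSs of 400–1400
  bp (mean 900) on alternating strands separated by 60–240 bp gaps.
- **Counts**: guide i of gene g has expected relative abundance
  ∝ a_i·2^(G·(1+s_g+ε_i)) with a_i log-normal (σ = 0.5), ε_i ~ N(0,
  0.02) drawn per guide per condition, G = 12 generations (the screen's
  plate-growth span). Planted classes: neutral (s = 0 everywhere),
  essential (s = −0.30 in both induced conditions), competence_costly
  (s = 0 under Ci, s = −0.25 under Ci+C, so the expected score shift is
  G·s = −3), and optionally competence_required with the same Ci+C
  penalty (the fratricide-style depletion of competence activators) and
  reduced reporter activity. The mock is always neutral (no dCas9).
  Reads are negative-binomial (dispersion 0.01; 0 degrades to
  multinomial) around the multinomial expectation at the configured
  depth, default 5·10⁶ per condition over 4 replicates.
- **Reporter**: OD grows logistically from 0.05 to 1.5; rlu =
  A·factor·od·(1+η), η ~ N(0, 0.05), sampled every 10 min over 8 h.

What the generator does **not** emulate: sequencing errors inside reads
(counting is exact-match, so error tolerance is untested by design),
PCR amplification bias and chimeras, guide-position-dependent CRISPRi
efficacy along the ORF, polar effects on operons, and the spatial
killing dynamics behind the fratricide penalty (only its net fitness
effect is planted). Passing tests therefore demonstrate that the
statistical machinery recovers effects of the modeled form at the
modeled noise; they do not certify robustness to library chemistry
artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the targeted signal dominates counting noise:
designer oracles on 1,000 random genomes ≤ 5 kb; recovery at 1,000
genes × 20 guides, depth 5·10⁶, 3 seeds; neutral uniformity at 500
genes × 20 guides with B = 1,000 permutations; counting on 10⁵ reads.
Neutral-lfc checks use ≥ 2,000 reads/guide because pure Poisson noise
alone gives E|lfc| ≈ sqrt(2/n)/ln2. Permutation p-values are computed
with the +1 convention (never zero); guide ties get average ranks;
guides are emitted in (strand, start, spacer) order and all stochastic
stages take explicit seeds, so every pipeline output is byte-reproducible.

## Known limitations

Exact-match counting undercounts on real reads with sequencing errors
in the anchors (use the one-mismatch mode, at the cost of speed).
Off-target assessment is exact-duplicate flagging only — near-identical
spacers (e.g. in paralogs or IS elements) are not detected. The
rank-aggregation layer models guides as exchangeable within a gene;
systematic efficacy gradients along genes would be absorbed into the
permutation null rather than corrected. Intergenic guides are counted
and exported but excluded from gene-level contrasts, since attributing
them to a regulatory target requires information the pipeline does not
have.
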