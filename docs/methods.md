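# Methods

This note documents the statistical procedures implemented in `sh3kit`, the
parameters they default to, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## 1. Colony-array interaction scoring (`sh3kit.plates`)

Protein-fragment complementation (DHFR-PCA) screens read interaction
strength out as colony size on selective plates. Sizes enter as log2 values
on a long-form plate grid carrying position, strain, border flag and QC
flag.

**Normalization.** Each plate's background is the median log2 size of
QC-passing, non-border positions; it is subtracted from every position.
Border positions carry a constitutive control pair and are used for plate
QC only, never scored. A plate with no usable background (e.g., a bait that
lost all its interactions) can be normalized with the measured background of
a matched plate via `background_override`.

**PCA score.** Replicate values per (bait, prey) pair are pooled across
plates and positions (the default design gives four independent tests: two
plates x two positions). Replicates failing diploid selection are removed
first; pairs with fewer than two surviving replicates are dropped. The PCA
score is the median of the surviving replicate values.

**Interaction calls.** A pair is called when its PCA score reaches the top
`top_quantile` of the pooled score distribution. The deletion-screen
convention is 7.3%; the domain-shuffling convention is 2.75%. The threshold
is a linear-interpolation quantile and threshold ties are included in the
called set, so the realized call rate can deviate from the nominal quantile
by at most the tie granularity (±1/n for continuous scores).

**Dependency classification.** Each pair called in either the WT or the
mutant screen gets one of five classes. Detected in WT only →
`dependent_lost`; in mutant only → `inhibited_gained`. For pairs detected in
both, the score ratio (mutant minus WT score, a log2 size ratio) is compared
with the lower/upper `ratio_quantile` (default 7.3%) of the pooled ratio
distribution: below the lower quantile → `dependent_weaker`, at or above the
upper → `inhibited_stronger`, between them → `independent`.

**Growth scores.** Stress-condition growth assays use the same plate
container at the 74 h reading. Plates are median-centered as above; each
strain's per-plate median over its (default six) replicate positions is
computed for the two plate replicates; strains whose two medians differ by
more than 2 log2 units are removed as discordant; the growth score is the
mean of the two medians. With identical plates the growth score therefore
equals the per-strain median exactly.

## 2. Matrix similarity score (`sh3kit.motif`)

A PWM is a k x 20 column-stochastic frequency matrix. Following the MATCH
convention, position i carries the information weight

    I(i) = sum_b f(i,b) ln(20 f(i,b)),   with 0 ln 0 := 0,

zero for a uniform column and ln 20 for a one-hot column. A window w scores

    MSS(w) = (sum_i I(i) f(i, w_i) − Min) / (Max − Min),

where Min and Max use the per-column minimum and maximum frequencies, so the
consensus scores exactly 1 and the worst window exactly 0. A sequence's
score is the maximum over all windows and over all PWMs assigned to the
domain; windows containing non-standard residues are skipped; ties break
toward the first-scanned window. Scanning is vectorized but exactly
equivalent to window-by-window enumeration (asserted against an independent
oracle in the tests).

**Random-peptide null.** `random_peptide_null` draws n = 10,000 peptides
(default length 100, or an empirical length pool) from a background
amino-acid composition (default: S. cerevisiae proteome frequencies,
renormalized to sum to 1) and records each peptide's max-MSS. The 95th
percentile serves as the "high MSS" threshold.

**Enrichment and reassignment tests.** Domain-dependent vs -independent
prey scores are compared with a one-tailed Mann-Whitney test
(`enrichment_test`). `pwm_reassignment_test` permutes the assignment of PWM
sets to domains, rescores every domain's dependent preys under the shuffled
assignment until at least `n_perm` permuted scores accumulate, and reports a
two-tailed Mann-Whitney p of observed vs permuted scores.

## 3. Deep mutational scanning (`sh3kit.dms`)

Each of the 58 codons of the domain is mutated to all 64 codons (NNN
design). Per condition and replicate:

1. variant frequency = (count + 0.5) / depth — the pseudocount is applied at
   the count level, so zero-count variants stay finite;
2. ratio = log2(selection frequency / reference frequency);
3. DMS score = ratio − median ratio of synonymous codon substitutions
   (codon changes preserving the WT amino acid, WT codon excluded), per
   replicate; scores are then averaged across replicates.

Averaging two individually centered replicates leaves a residual synonymous
median of the order of the sampling noise, so the averaged scores are
re-centered once more on their synonymous median. This makes the invariant
"synonymous median is exactly 0" hold by construction while changing every
score by the same small constant.

**Classification.** Variants strictly below the synonymous distribution's
1st percentile are `deleterious`, strictly above the 99th `improving`, else
`neutral` (linear-interpolation percentiles). By construction roughly 2% of
synonymous variants fall outside their own percentile band.

**Aggregation and categories.** Amino-acid-level scores are the mean over
the codons encoding a substitution, excluding the WT codon; stop codons are
excluded unless requested. Given aa-level scores for two interactions and
each interaction's own synonymous 1st-percentile threshold, substitutions
are assigned to `destabilize_both`, `destabilize_ppi1_only`,
`destabilize_ppi2_only` or `neutral_or_increasing`.

## 4. Profile/sequence dendrogram comparison (`sh3kit.trees`)

Interaction profiles (one row per domain, PCA scores across preys, missing
entries imputed with the post-normalization background 0) are compared under
Euclidean distance; aligned domain sequences under distance = 1 − pairwise
identity (gap-gap columns excluded, gap-residue columns counted as
mismatches). Both matrices are clustered with complete linkage (scipy).
Tree agreement is the cophenetic correlation: Pearson correlation of the two
trees' merge-height distances over all leaf pairs. A tree compared with
itself gives r = 1 exactly.

**Permutation test.** The null randomizes the assignment of domains to
profiles. Relabeling a tree's leaves permutes the rows/columns of its
cophenetic matrix without changing the tree, so each permutation reindexes
the fixed cophenetic matrices rather than re-clustering. One-tailed p with
add-one smoothing: p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm). Under the
null the p values are uniform up to the 1/(n_perm+1) discretization.

## 5. Trajectory metrics (`sh3kit.tracks`)

Endocytic-focus tracks are time-ordered (x, y) positions plus the host-cell
centroid. Tracks shorter than 10 frames are discarded as spurious
detections. Outward excursions after the point of closest approach to the
centroid (mis-linked detections) are trimmed: frames are removed from the
first frame whose centroid distance exceeds the minimum plus 2 px.
Effective internalization distance is e(t) = d(start) − d(t); straightness
is net displacement over path length (a 3-4 right-angle path gives 5/7). A
track is complete when it ends strictly before the final acquisition frame;
t95 is the k-th smallest completed end frame with k = ceil(0.95 n), reported
as NaN when fewer than 95% of tracks complete.

## 6. Synthetic generators (`sh3kit.synth`)

All generators draw from a local `numpy.random.default_rng(seed)`; identical
configuration gives byte-identical outputs. They emulate the *statistical*
structure each scoring stage consumes, not the biology producing it:

- **Plate screens:** background + per-plate offset + planted effect +
  Gaussian noise on a 32x48 grid with a 2-position control border; each prey
  at two randomized, never-adjacent positions per plate, two plates per
  bait. Defaults: background 10 log2 units, plate SD 0.25, noise SD 0.25,
  effect 4 log2, 10% positives. Not modeled: spatial gradients, neighbor
  competition, colony-size saturation.
- **Growth plates:** same container; discordant strains get a +3 log2 shift
  on the second plate only, exceeding the 2 log2 discordance cutoff.
- **Motif sets:** "dependent" sequences carry a PWM-sampled window at a
  recorded position with probability `planted_frac`; everything else is
  background composition. No positional preference or secondary motifs.
- **DMS counts:** reference counts multinomial over the 64 codons at depth
  5000; selection counts multinomial with weights proportional to the
  realized reference count times 2^effect. Effects are keyed by (position,
  codon); synonymous variants have effect 0. No epistasis, no
  sequencing-error model.
- **Coupled profiles:** sequences evolve along a random bifurcating tree;
  the sequence dendrogram's cophenetic (ultrametric) distances are embedded
  exactly into Euclidean coordinates by classical MDS, and profiles =
  coupling x embedding + (1 − coupling) x noise. Because complete linkage
  recovers an ultrametric exactly, coupling 1 yields cophenetic r = 1
  exactly (when n_preys ≥ n_domains − 1); coupling 0 makes profiles
  independent of sequence.
- **Tracks:** inward drift 0.3 px/frame with isotropic noise, geometric
  disassembly hazard, 180 frames at 1 frame/s; optional spurious outward
  tails at 2.5 px/frame emulating mis-linked detections.

## 7. Calibration problem sizes

The acceptance checks that measure statistical calibration use problem
sizes chosen once for runtime: type-I-error rate of the enrichment test
over 200 repeats of 50 + 50 sequences; permutation-p uniformity over
500 draws of 10-leaf trees at n_perm = 200 (Kolmogorov-Smirnov test against
Uniform(0,1)); power at coupling 0.9 over 40 seeds of 30-leaf trees at
n_perm = 300. The Mann-Whitney test is slightly conservative at n = 50 per
group because of rank discreteness, so its empirical rejection rate sits at
the low end of the binomial band around 5%.

## 8. Limitations

- Generators share no covariance structure across data types; a planted
  interaction does not imply a planted motif.
- The MDS profile embedding produces profiles whose *geometry* matches the
  sequence tree; it is not a mechanistic model of binding specificity.
- BLOSUM62-based conservation is min-max normalized over the 20x20 standard
  block (min −4, max 11), so values are comparable across columns but not
  across substitution matrices.
- Relative solvent accessibility uses an empirical maximum-accessibility
  table and is not clamped at 1; values slightly above 1 trigger a warning
  rather than an error.
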