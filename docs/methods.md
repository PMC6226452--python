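# Methods

This note documents the models and procedures implemented in `cnescreen`,
the parameter choices that matter, and what the simulation-based tests do
and do not establish.

## Divergence screen

**Ancestral reconstruction.** Each CNE alignment is reconstructed at the
root of the input tree by per-column marginal maximum likelihood under
Jukes–Cantor (JC69) with the tree's branch lengths, via Felsenstein pruning
with a uniform root prior. Ties are broken in the fixed order A < C < G < T
so the output is deterministic. Gaps are not part of the substitution model:
a column's ancestral presence/absence is decided by Fitch parsimony on the
gap pattern, with ambiguity resolved toward presence (a base is reported
whenever parsimony allows one; an all-gap column is always a gap). N counts
as present but contributes no base information. The reconstruction is
performed on the given alignment; no realignment is attempted. Marginal
reconstruction at the root is exact for the model — the test suite checks it
against brute-force enumeration of all internal state assignments on small
trees.

**Identity and normalization.** Fractional identity is computed over the
columns where the ancestor has a base; columns with an ancestral gap carry
no signal about divergence *from the ancestor* and are excluded. A species
gap (or N) opposite an ancestral base counts as a mismatch, so deletions
register as divergence and identity 0 corresponds to complete loss of the
element. A species with fewer than 30% non-gap columns over a CNE is
treated as missing (the threshold is configurable; some missing-data rule
is needed because fragmentary assemblies would otherwise contribute
near-meaningless identities). Normalized identity is
`seqId = (pid − 1) / d`, where `d` is the sum of branch lengths from the
leaf to the root; it is ≤ 0, 0 only at perfect identity, and comparable
across species with different divergence times.

**Z-scores.** `Z = (max(seqId_loss) − mean(seqId_others)) / sd(seqId_others)`
with the sample (n−1) standard deviation. Using the *maximum* over loss
species makes the screen conservative: the least diverged loss lineage
drives the call, so all loss lineages must be diverged. The same statistic
serves the global comparison (all non-loss species) and the local one (a
configured close-relative subset, guarding against clade-wide relaxation).
A CNE is called when both Z fall strictly below the cutoff (default −3) and
the missing-data requirements hold (all required species present plus at
least 3 others by default). Z is invariant to shifting or positively
scaling all seqIds of a CNE, so the calls do not depend on the overall
identity scale.

**FDR.** Two routes are supported. (1) Simulation: the identical screen is
run on CNEs evolved under constraint in *all* species; with `k` of `m` null
CNEs passing, the false-positive rate `k/m` scaled by the number of screened
real CNEs gives the expected false positives, and dividing by the number of
calls gives the FDR. (2) Sister-lineage bound: the screen is re-run with a
sister lineage of the loss clade cast as the "loss" pair; conservatively
declaring all of its calls false positives bounds the FDR from above. Both
are pure arithmetic on counts and reproduce their published worked examples
exactly. A local-FDR (density-based) estimate is not implemented.

**Independent losses.** When the trait was lost several times, divergence
should co-vary with the phenotype across lineages rather than in one clade.
Implemented as a generalized least squares regression of per-species seqId
on a loss indicator with Brownian-motion covariance derived from the tree
(shared root-to-MRCA path length), one-sided p for the loss coefficient
being negative, BH-adjusted across CNEs. This is a species-level
approximation to per-branch "forward genomics" association: it corrects
for shared ancestry but does not map substitutions onto individual
branches. CNEs missing any loss species are excluded; missing intact
species are dropped per CNE with at least four required.

## Interval rules

Conserved elements become CNEs by subtracting coding intervals expanded by
a 50 bp flank on both sides and keeping remainders of at least 30 bp. For
enrichment testing, CNEs separated by a gap strictly smaller than 50 bp are
merged ("closer than 50 bp" is read as a strict inequality; the boundary
case is pinned by tests). Coordinates are 0-based half-open throughout;
merging never crosses chromosomes.

## Gene association and enrichment

Regulatory domains follow the basal-plus-extension rule: a strand-aware
basal domain of 5 kb upstream / 1 kb downstream of the TSS, with each side
extended up to 300 kb beyond the basal edge, stopping earlier at the
nearest other gene's basal domain or the chromosome boundary. Extensions
never invade a foreign basal domain (basal domains themselves may overlap
when TSSs are close). A CNE is associated with every gene whose domain it
overlaps by ≥ 1 bp.

Enrichment of diverged (foreground) CNEs in a gene set or peak set is a
one-sided Fisher's exact test against the non-diverged background — the
foreground is excluded from the background margin — BH-adjusted across the
batch of sets tested. A complementary Z-score draws 10,000 same-sized
subsets of the full CNE universe (foreground included) without replacement
and standardizes the observed overlap against the subsample counts; those
counts are exactly hypergeometric, which the tests exploit as a closed-form
oracle. The peak-overlap predicate is ≥ 1 bp of intersection (configurable).

## Motif scoring and decay

**Occupancy score.** SWAN-style HMM scoring is replaced by a closed-form
occupancy score: for each 200-bp window (step 100 bp, strand-symmetric
window placement; one window for shorter sequences), every position on both
strands contributes `log2(1 + 2^llr)`, where `llr` is the log2 likelihood
ratio of the site under the PWM (pseudocount 0.01 per cell) versus an
i.i.d. GC-matched background; the sequence score is the maximum over
windows. The softplus keeps strong sites dominant while letting many weak
sites accumulate, makes no assumption about site position, and is exactly
reproducible; positions containing N contribute nothing, and the score is
invariant to reverse complementation.

**GC-binned cutoffs.** For each of 21 GC bins (0, 5, …, 100%, generation
clamped to [1%, 99%] so sequences remain sampleable), 100 random 200-bp
sequences each receive one site sampled column-wise from the PWM at a
uniform position and are scored at the bin's GC. The cutoff is the
empirical 90% quantile taken as the ⌈q·(n+1)⌉-th smallest score (the 91st
of 100): for a continuous score this gives a fresh with-site sequence a
(n+1−k)/(n+1) ≈ 10% chance of scoring at or above the cutoff, matching the
intended calibration exactly rather than the ⌈q·n⌉ convention whose
coverage is 10.9%. The acceptance script re-measures this rate from
scratch. A CNE–motif pair enters the decay analysis only if the
*ancestral* sequence scores strictly above the cutoff of the CNE's nearest
GC bin (ties toward the lower bin). Note this is a deliberately strict
filter — it asks the ancestor to score in the top decile of site-bearing
random sequences — so for low-information motifs few pairs survive it.

**Excess scores.** Per species, `excess = median(foreground scores) −
median(background scores)` with a one-sided Wilcoxon rank-sum test
(normal approximation with tie and continuity corrections), BH-adjusted
across species. The test direction is an explicit parameter (default
`greater`, i.e. foreground motif content preserved); both directions are
exercised in tests. As a null control, motif columns are pooled across the
library, ranked by information content (IC = 2 + Σ p log2 p), partitioned
into 20 equal-frequency bins, and every column replaced by a random column
from its own bin — preserving length and IC profile while destroying base
preferences. Equal-frequency binning is used because it keeps bins
populated regardless of the library's IC distribution.

## Synthetic data

The generator emulates the study conditions at desk scale. Fixture trees
are random ultrametric binary trees; by default the loss species form one
clade nested inside a small near group (single-origin loss; the near group
becomes the local comparison set), or each loss leaf is grafted as sister
to a distinct non-loss leaf (independent losses). The default screening
fixture uses 10 non-loss species, a 2-species loss clade and root-to-tip
depth 0.75 substitutions/site — deep enough that constrained and relaxed
elements separate, small enough to run in seconds.

Sequences evolve by JC69 with per-branch expected substitutions
`branch_length × constrained_rate` (default 0.15, i.e. CNEs evolve at 15%
of the neutral rate — strong purifying selection), multiplied by
`relaxation_factor` on branches whose entire leaf-descendant set lies
within the loss lineages for CNEs labelled relaxed. The default planted
contrast (factor 20 on 100 of 2,100 CNEs) represents complete release from
constraint. CNE lengths are geometric with mean 200 bp truncated to
[30, 1000] bp, echoing the ≥ 30 bp CNE rule; root sequences are i.i.d.
with configurable base composition (uniform by default). Constraint is a
uniform per-CNE rate scaling, not per-site, and alignments are gap-free,
so percent identity reduces to mismatch counting in the simulations —
gap handling is exercised by dedicated unit tests instead. One chromosome
per fixture; genes, peaks and motif libraries are generated with simple
uniform/Dirichlet models and known ground truth.

What the simulations do **not** capture: indels and alignment error,
per-site rate variation and hypermutable contexts, GC-biased gene
conversion, coding/UTR context around CNEs, assembly gaps, and realistic
chromatin. Passing tests therefore demonstrate that the statistics and
their calibration behave as designed under the stated model, not that the
screen is robust to every artefact of real genome alignments.

## Numerical choices and degenerate inputs

Strict inequalities at every cutoff (Z < −3, ancestral score > cutoff,
merge gap < 50 bp); ties in reconstruction broken by fixed base order;
sample (n−1) standard deviations throughout; a comparison set with zero
spread or fewer than two finite values yields a missing Z rather than a
call; singular GLS covariances skip the CNE with a warning; empty Fisher
margins report p = 1 with an undefined odds ratio; the subsampling Z
raises on predicates constant over the universe. All generators and the
pipeline derive per-stage seeds from one master seed (stage-name CRC mixed
in), so every artifact is independently reproducible.

## Problem sizes

Defaults were chosen so the full test suite and the analysis scripts each
run in well under a minute of CPU apiece: screens on 2,000–4,100 simulated
CNEs, 10,000 subsampling draws, motif calibration on batches of 100
with-site sequences with 250–1,000 fresh sequences per measured rate.
These sizes keep binomial/Monte-Carlo error well inside the tolerances the
tests assert.
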