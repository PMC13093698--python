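# Methods

This note documents the models, conventions and numerical choices behind
nanofish, and what the simulator does and does not emulate.

## Amplicon model and simulator

A simulated read is `barcode + MiFish-U-F + insert + revcomp(MiFish-U-R) +
barcode`, reverse-complemented with probability 0.5. The MiFish-U primer
pair (F: `GCCGGTAAAACTCGTGCCAGC`, R: `CATAGTGGGGTATCTAATCCCAGTTTG`) targets
a ~170 bp hypervariable 12S fragment. Barcodes are 24 synthetic 24-mers
with pairwise edit distance ≥ 8, generated once from a fixed internal seed
and exposed as a constant table; 24 is the number of per-sample indices the
multiplexing scheme supports, and designs requesting more samples fail
early.

Errors are independent per base: substitution, insertion and deletion
probabilities (defaults 0.03/0.02/0.02, i.e. a ~7% total error rate typical
of single reads before consensus; the recovery experiments use
0.03/0.01/0.01 = 5%). Quality strings are a constant Phred value per base
because the quality gate only uses an aggregate. Chimeras splice the inserts
of two distinct species at a uniform breakpoint; contaminant reads use the
panel's human record. Every read has a truth row (species, sample, chimera
and contaminant flags).

Synthetic reference panels place all fish species at a controlled pairwise
identity (default 0.80–0.92, the congener-to-confamilial range typical of
12S fragments) by mutating a common ancestor, verifying every pair with the
package's own identity measure and retrying with a fresh substream when a
pair lands outside the window. Optional byte-identical species pairs
emulate congeners that share the fragment. The panel always carries one
human record for contamination control.

What the simulator does **not** emulate: homopolymer-biased or
signal-level Nanopore error structure, quality-score correlation, PCR
amplification bias, tag jumping, or abundance-dependent detection. Passing
tests therefore demonstrate the correctness of the pipeline's logic under
the stated error model, not field-grade performance on real flow cells.

## Read processing

Read quality is −10·log₁₀ of the mean per-base error probability; the
arithmetic mean of Phred values was rejected because it overestimates
quality. The gate keeps reads with quality strictly above 10 and length in
[180, 250] bp. In the orchestrated pipeline the gate runs on
barcode-trimmed reads with primers still attached (~218 bp nominal), the
window that bracket makes sense for; the filter itself is order-agnostic
and can be applied to any stream.

Demultiplexing searches the first and last 150 bases of each read for every
barcode on both strands (edlib infix alignment); identity is
(length − edit distance)/length. A read is assigned only when both ends
pass 0.85 and name the same barcode; equal-identity hits from different
barcodes discard the read as ambiguous. Primer location allows up to 3
edits per primer (~14% of the 21-mer, tolerating Nanopore indels).

## Clustering and consensus

Pairwise identity is the number of identical aligned positions in a global
alignment divided by the shorter length — the convention of greedy
incremental clusterers. Among minimum-edit alignments the one maximizing
matches is used, computed exactly with a single scoring trick: a global
aligner with match +1 and mismatch/gap −1024 yields score = matches −
1024·edits, so the match count is the score modulo 1024. Cheap bounds from
the raw edit distance ((m+n)/2 − d ≤ matches ≤ (m+n−d)/2) short-circuit
most comparisons during clustering.

The greedy pass visits sequences longest-first (ties: decreasing abundance
of the identical sequence, then lexicographic id) and compares queries to
cluster representatives only. Clusters below `min_cluster_size` (default 5,
suppressing singleton noise at desk scale) are discarded and tallied.
Consensus is a per-column majority vote over members aligned to the
representative: insertion columns are kept when at least half the members
carry one, a majority gap deletes the column, and symbol ties break toward
the representative. This replaces the external polisher stack of field
pipelines; at ~170 bp amplicon length a per-column vote over ≥5 members is
an adequate error-reduction step, and it is documented as a
re-implementation, not a claim of bit-compatibility.

The second round re-clusters per-sample consensuses at 97% with no minimum
size (a consensus already carries its read support), sums supports per
sample, and labels OTUs in decreasing total-count order.

**Choosing the first-round threshold.** 97% identity separates species on
near-perfect sequences (consensuses, or reads at ~1% error). At a simulated
5% read error, two same-species reads sit near 90% identity, so the
recovery experiments cluster reads at 0.85 and apply 97% to the polished
consensuses — the stage where the species-resolution argument for 97%
actually applies. Both thresholds are independent parameters.

## Taxonomy and bit scores

Assignment uses exact affine-gap Smith–Waterman (Gotoh) via Biopython's
pairwise aligner with match +2, mismatch −3, gap open 5, extend 2 (a gap of
length k costs 5 + 2k), and Karlin–Altschul normalization
S′ = (λS − ln K)/ln 2 with gapped nucleotide parameters λ = 0.625,
K = 0.41. Under this scheme a perfect 170 bp match scores 340 raw ≈ 307.9
bits, so the 250-bit species cutoff corresponds to roughly 80% of the
perfect score — a meaningful mid-range bar. The source pipeline did not
publish its scoring constants, so the cutoff is reproducible only relative
to these declared constants; all are config-exposed. No E-values are
computed: the curation rule uses bit scores only.

References with byte-identical sequences merge into composite records;
within one genus the label joins the genus once with alphabetically ordered
epithets ("Pomacentrus coelestis-pavo" style), across genera full binomials
are joined. Exact bit-score ties at assignment time produce the same
composite labelling; lineage ranks are kept where the tied records agree
and set to "Unknown" below the first disagreement.

Species aggregation sums OTU rows sharing a label and weights each OTU's
bit score by that OTU's total read count — the only reading of
"weighted by the number of reads" that makes the per-species mean well
defined. Species under 250 mean bits pool into a single "unknown" row.

## Curation

The contaminant score is a one-sided Fisher exact p-value on the 2×2
presence table (blanks × environmental); presence means count ≥ 1. A row
is flagged when the score is below 0.5. This re-implements the prevalence
logic of negative-control decontamination with an exact test instead of the
chi-square variant — exact is preferable at the 1–3 blanks typical of eDNA
designs — so scores are not bit-compatible with the R implementation,
though decisions agree at the default threshold in the regimes tested.
Designs without blanks skip the screen with a warning. Blanks are excluded
from the rarefaction-depth minimum and dropped after screening: they are
controls, not observations.

Rarefaction subsamples each column without replacement (multivariate
hypergeometric draws from a seeded generator) to
floor(0.9 × smallest environmental total); expected-richness curves use the
exact hypergeometric closed form E[S_d] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)).

## Community statistics

PCoA eigendecomposes the Gower-centered squared-distance matrix, returns
only positive-eigenvalue axes (warning with the negative-inertia fraction —
Jaccard matrices are typically slightly non-Euclidean), scales eigenvectors
by √eigenvalue and fixes axis signs deterministically.

PERMANOVA partitions tr(H·G) with sequential (order-of-entry) projection
differences, matching the default term attribution of the formula interface
common in the field; the two-factor design `habitat * season` yields both
mains then the interaction. p-values use free row permutations of the
distance matrix with the add-one convention, so they are never zero;
permutations are vectorized, which keeps the 500-dataset type-I calibration
in seconds. Traces within 1e-12 of zero (relative) are clipped so that
degenerate designs with no residual variation fail loudly rather than with
sign noise. The implementation is cross-checked in the test suite against
R's vegan::adonis2 (df, sums of squares, R²) and against the direct
within/between-group distance identity for the single-factor pseudo-F.

Beta-dispersion embeds samples by PCoA (positive axes only — a known
simplification relative to implementations that track negative axes
separately; at the small negative inertia of Jaccard matrices the effect is
negligible), measures distances to group centroids and permutes group
labels for the F-test. Accumulation curves enumerate sample subsets exactly
for n ≤ 8 and use random orderings otherwise; the effort threshold from
the log fit S = a + b·ln n is the smallest n with b·ln((n+1)/n) < 1, with
slopes at or below 1/ln 2 saturating immediately at n = 1. Kruskal–Wallis
uses the tie-corrected statistic; Dunn z-tests use Holm adjustment (the
adjustment choice was open; Holm is uniformly more powerful than Bonferroni
and assumption-free, and is config-independent here). Mann–Whitney is exact
for tie-free groups of ≤ 8.

Diel ratios count only species with known activity in the denominator
("both" counts in the denominator, never as nocturnal): the ratio is a
statement about known behavior, and trait tables never cover every taxon.

The method comparison partitions taxa by eDNA detection (≥1 non-blank cell)
versus visual record. Composite labels count as their own taxa by default —
the convention under which the aquarium dataset yields 14 eDNA-only taxa —
with composite-aware matching (a visual species matches a composite
containing it) behind a flag. On the aquarium data the shared-taxon mean
relative abundance computes to 5.67%; the eDNA-only mean computes to 0.66%
under the same protocol (averaging each taxon over all six samples with
absences as zero), which is the value the package reports.

## Determinism

One global seed fans out to per-stage seeds by SHA-256 hashing of the stage
name (stable across runs and insertion order), so adding a stage never
perturbs earlier stages' randomness. The clustering modules contain no
randomness at all. Reruns with identical configuration produce
byte-identical artifacts; the manifest records the config hash, seed and
per-stage read accounting (input = kept + every rejection bin).

## Problem sizes

The bundled experiments run at desk scale: recovery uses 10 community
species and three replicates of 5,000 reads; the clustering oracle uses 200
reads; the PERMANOVA calibration uses 500 null datasets of 12 samples with
999 permutations; field-scale analyses simply take the same entry points
with larger inputs.

## Known limitations

- Consensus accuracy degrades below ~5 members per cluster and for inserts
  with long homopolymers (the error model is homopolymer-blind, so this is
  untested territory).
- The prevalence screen assumes presence/absence is informative; it cannot
  use concentration information (frequency-mode decontamination is out of
  scope).
- PERMANOVA assumes exchangeable samples under the null (free permutation);
  restricted permutation schemes for nested designs are not implemented.
- The GLMM-vs-GLM day-effect likelihood-ratio test used in diel analyses of
  field data is out of scope; the diel module stops at ratios and
  rank-based tests.
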