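# Methods

This note records the models, rules and numerical conventions behind
tcskit, the parameters that matter, and what the synthetic-data tests do
and do not demonstrate.

## Signature model and scanning

TCS domains are represented as short degenerate amino-acid patterns
(`X` = any residue), shipped as editable YAML
(`src/tcskit/data/signatures.yaml`). The Hpt motif `XHQXKGSSXS` is the
canonical phosphotransfer signature; the other patterns (HK transmitter
boxes, REC, CHASE, GAF/PHY/PAS, ethylene-binding, CCT, Myb) are
package-curated consensi standing in for the corresponding Pfam domain
models, chosen to be mutually distant so that no pattern matches an
occurrence of another within the mismatch budget. A window matches when it
disagrees with the pattern at no more than `max_mismatch` (default 2)
non-`X` positions. The key catalytic residue — His in the H-box and Hpt,
Asp in REC — is excluded from the mismatch budget and judged exactly into
`conserved`/`substituted`; this single bit is the authentic-vs-pseudo
discriminator throughout. Transmembrane segments use a hydropathy
heuristic (≥ 17 residues with mean Kyte–Doolittle index > 1.6), since TM
annotation has no sequence signature.

With the default budget the Hpt pattern has only six informative
positions, so chance matches in random protein (≈ 1 per ~10⁴ windows) are
expected; the generators therefore rejection-sample backgrounds and
linkers to be signature-free, and scanner precision is measured separately
against raw random decoys.

## Classification tree

First matching rule wins: (1) transmitter — H-box with conserved His plus
≥ 2 other boxes ⇒ HK; boxes present with substituted/missing His ⇒ HKL;
subgroup from sensor domains (CHASE ⇒ cytokinin receptor, ethylene-binding
domain ⇒ ethylene receptor, GAF+PHY ⇒ phytochrome-like, else `other` —
CKI1-like/AHK1-like/PDK-like cannot be separated by architecture alone).
(2) Hpt ⇒ HP, or pseudo-HP when the His is substituted. (3) REC:
substituted Asp defines a pseudo-RR, split by CCT (clock) vs Myb (type-B;
CCT wins if both, neither ⇒ clock with low confidence); conserved Asp with
Myb ⇒ type-B RR; REC-only proteins are type-A if ≤ `typeA_maxlen`
(default 250 aa, reflecting the markedly smaller type-A proteins),
otherwise `RR_typeC_or_A` with **low confidence** — type-A, type-C and
Myb-lost type-B RRs cannot be told apart from architecture, and the tree
flags rather than guesses. (4) otherwise `not_TCS`. The tree is total and
deterministic: every protein receives exactly one family.

External domain tables (e.g. from BLAST/HMMER runs elsewhere) can be
merged before classification; candidate ingestion applies the standard
E-value filters (BLAST ≤ 1e-5; HMM < 0.1, strict) with best-hit
deduplication per query. Proteome redundancy is removed by collapsing
isoform suffixes (`.1`, `.2`, …) and keeping the longest isoform.

## Duplication rules

*Tandem*: two family genes on one chromosome, separated by at most 4
intervening genes (ranks counted over **all** annotated genes), whose
global alignment reaches ≥ 40 % similarity. Similarity is the percentage
of alignment columns whose residue pair scores positively under BLOSUM62
(gap columns count in the denominator); alignment is Needleman–Wunsch with
affine gaps (open 10, extend 0.5). Unrelated proteins score ~22–33 % under
this metric, comfortably below the rule.

*Segmental*: simplified collinearity chaining. High-similarity anchor
pairs are chained when gene ranks increase monotonically on both
chromosomes (either orientation) with per-step rank gaps ≤ `max_rank_gap`
(default 10); chains of ≥ `min_chain` (default 3) anchors form a synteny
block, and family-gene anchors inside a block are segmental duplicates.
Same-chromosome anchors closer than `max_rank_gap` ranks are discarded,
and the survey pipeline additionally collapses tandem components before
chaining — otherwise a tandem array chains along the diagonal and
masquerades as a self-collinear segment.

## Ka/Ks (NG86) and dating

Site counts: per codon position, the synonymous fraction is
`syn / (3 − stops)` — single-base changes creating stop codons are
excluded from the denominator — and the nonsynonymous site count is its
complement, so S + N = 3 × codons exactly. Differences: for codon pairs
differing at k positions, all k! minimal pathways are averaged with equal
weight; pathways through stop codons are excluded, and in the rare case
that every pathway is blocked (only possible at triple substitutions) all
pathways are used rather than dropping the pair. Codons containing
ambiguity codes are dropped pairwise. Rates use the Jukes–Cantor
correction; `p ≥ 3/4` is saturation (rate undefined). Selection is called
purifying when the ratio, rounded to the two decimals used in reports, is
below 1; the ratio is undefined when Ks is 0 or saturated.

Dating uses `T = Ks/(2x)` with `x = 6.5 × 10⁻⁹` synonymous substitutions
per site per year by default (exposed in `ClockConfig`); this is the rate
consistent with the published duplicate table the acceptance surface
reproduces (e.g. Ks 0.68 → 52.31 Mya), which prints a slightly different
rate in its own methods text.

Estimator validation simulates codon pairs from a common ancestor with a
uniform proposal process: candidate single-base changes at an expected `t`
per codon per branch (default 0.3, matching the synonymous divergence
scale Ks ≈ 0.1–0.35 of recent tandem duplicates, where NG86 counting is
most reliable), synonymous changes always accepted, nonsynonymous accepted
with probability ω, stops rejected. Recovery is summarised as the pooled
ratio mean(Ka)/mean(Ks) across replicates with a delta-method standard
error: averaging per-replicate ratios would add a Jensen bias of order
ω·CV²(Ks) (≈ +0.01 at these settings, comparable to the Monte-Carlo SE),
whereas the pooled estimator is unbiased at this divergence.

## Neighbor joining

Saitou–Nei NJ with the standard Q-criterion and branch-length formulas,
terminated at the final three-way join (the conventional unrooted
resolution). Ties break on the lowest index pair; negative branch lengths
are clamped to zero with the deficit moved to the sister edge, so
near-degenerate matrices yield reproducible trees. On additive matrices
the algorithm reproduces the generating tree metric to machine precision
(tested to 1e-9). Distances default to p-distance with pairwise gap
deletion; bootstrap resamples alignment columns with replacement and
reports, per internal edge of the full-data tree, the percentage of
replicates recovering that bipartition.

The survey pipeline builds per-family guide trees from pairwise-alignment
p-distances (it deliberately does not build multiple alignments — feed an
externally aligned FASTA for a bootstrap tree).

## Promoters

The promoter is the `length_bp` (default 1500) bases upstream of the
annotated translation start: for a `+`-strand gene the window ending just
before `start`, for a `−`-strand gene the reverse complement of the window
beginning just after `end`; truncation at contig edges is allowed with a
warning. Scanning is exact IUPAC matching of the packaged consensi
(`src/tcskit/data/cis_elements.yaml`) on both strands; `N` in a promoter
matches nothing; overlapping hits are all reported, and summaries count
both strands and overlaps. Forward-scanning a reverse complement yields the
exact strand-swapped hit set.

## Expression (2^−ΔΔCt)

Replicate Ct values are averaged per (gene, sample) before any
subtraction; ΔCt subtracts the reference gene, ΔΔCt subtracts the control
sample, fold change is 2^−ΔΔCt. The control column is exactly 1 (0 in
log2) by construction, and adding any constant to all Cts of a sample
cancels. Biological replicates are kept as separate columns unless merged
upstream. Heatmap row order comes from average-linkage hierarchical
clustering (Euclidean or correlation distance; constant rows are rejected
by name under correlation).

## Synthetic data: what it shows and what it does not

Generators are pure functions of (parameters, seed). Family proteins are
concatenations of realized signature segments and signature-free random
linkers drawn from an average proteome composition; tandem arrays mutate a
common base protein (15 % of residues, similarity ≈ 80 %), segmental
blocks are mutated in-order copies, promoters are third-order Markov DNA
with elements implanted at recorded offsets/strands (chance occurrences of
the short motifs are unavoidable in kilobase backgrounds and are flagged
in the truth), and Ct tables are built so noiseless recovery is exact.
Per-replicate Ct noise of σ = 0.15 propagates to ≈ 13 % (1σ) on a single
fold estimate, so noisy-recovery checks bound the mean relative error over
the fold plan at 15 % rather than each tuple. The CDS written for
duplicate pairs share ancestors pair-/array-wise but do not encode the
corresponding proteins; Ka/Ks consumes CDS independently of the protein
sequences.

Because the generators build proteins from the same signature config the
scanner reads, classification tests establish internal consistency of the
scan–classify–report chain — perfect recovery on this synthetic genome
does **not** demonstrate Pfam-level sensitivity on real proteomes, where
domain boundaries and divergence are harsher. Genome-scale inventories
(e.g. the 65-member tomato family) and web-service element counts are
outside what desk-scale synthetic data can certify; the published
duplicate table's ratio/dating arithmetic is reproduced exactly instead.

## Problem sizes and determinism

Default validation sizes: 500 codon pairs for the pathway-enumeration
oracle; 200 replicates × 300 codons for ω recovery; 100 random 5–10-taxon
trees for NJ exactness; a ~60-protein proteome spanning all nine families
for classifier recovery; one 6-gene and one 3-gene tandem array plus a
5-anchor segmental block for duplication recovery. All randomness flows
through explicit integer seeds; identical seeds give byte-identical
outputs end to end.

## Known limitations

* Profile-HMM scoring, de-novo motif discovery and MSA construction are
  out of scope; external tools' tabular outputs can be ingested instead.
* The signature patterns are package consensi, not fitted models; retarget
  the YAML config for a new clade before trusting calls on real data.
* NG86 is a counting estimator: at high divergence (Ks ≳ 1) it
  underestimates rates and the ratio becomes unstable; use a
  maximum-likelihood tool for saturated pairs.
* Collinearity chaining is a simplification of whole-genome synteny tools;
  it detects planned block copies but has no E-value model for anchor
  significance.
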