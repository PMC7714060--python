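# Methods

## Coordinates and gene models

All internal coordinates are 0-based, half-open; GFF3 and InterProScan
files (1-based, inclusive) are converted exactly once, at the I/O boundary.
This keeps every off-by-one in one place: the projection code never sees a
1-based number.

Transcript models order exons and CDS segments 5'→3' in transcript
orientation (descending genomic start on the minus strand). The
representative isoform of a gene is the one with the longest protein, ties
broken by lexicographically smallest transcript id so reruns are
deterministic. Splicing trusts the GFF3 phase of the first CDS segment and
trims that many leading bases; a "." phase is treated as 0 (Ensembl-style
annotations always provide phase, and the synthetic generator mirrors
that). Translation uses the standard genetic code only; ambiguous codons
become `X`, a single trailing stop is trimmed, an internal stop flags the
transcript invalid.

The CDS coordinate map pairs genomic blocks with contiguous CDS offsets
0..L. Projecting a genomic interval into protein space returns the
*smallest residue interval whose codons intersect it*, with partial-codon
flags when the interval cuts a codon. The closure is deliberate: domain
overlap questions need a superset of touched residues, not a subset. The
round-trip property (protein → genomic → protein is the identity on
whole-codon intervals, and projected blocks always total 3 nt per residue)
is enforced by property tests over randomized multi-segment transcripts on
both strands.

## Micro-exon definition and typing

A micro-exon is an exon whose **CDS-overlapping portion** is 1–51 nt
(threshold configurable). UTR bases are excluded from the length because
they cannot overlap a protein domain; an exon with 30 nt of CDS and 40 nt
of UTR is therefore called at coding length 30. First and last coding
exons are eligible — the K-box M2 micro-exon sits at the end of the coding
region in many MIKC genes and would vanish under a terminal-exon filter.

Domain assignment overlaps the closed residue projection with the
protein's merged domain hits; the largest overlap wins, ties go to the
N-terminal-most hit, and a single shared residue suffices (the most
permissive reading of "overlaps"). AP2 hits carry repeat labels R1, R2, …
numbered from the N terminus.

Positional types are configuration, defaulting to the four recurrent
AP2-subfamily classes: R1M1 (9 nt), R1M2 (26 nt), R1M3 (31 nt) in the R1
repeat and R2M1 (45 nt) in R2, matched on exact coding length within the
assigned domain context. K-box micro-exons are instead labeled through
tandem detection: maximal runs of consecutive-exon micro-exons of length
≥ 2, labeled M1, M2, … in 5'→3' order when all members lie in the K-box.

Enrichment summaries report, per family, the fraction of micro-exons
(denominator: micro-exons of genes in that family) overlapping the
family's hallmark domain, plus a genome-wide row; empty groups report a
missing fraction rather than 0. Because the exact denominator convention
matters, both the family-restricted and genome-wide views are emitted.

## Family classification

Classification uses only the representative isoform's merged domain hits,
and depends only on the multiset of labels: ≥ 2 AP2 → AP2 subfamily
(repeat duplication defines the subfamily, so three repeats still count);
1 AP2 + B3 → RAV (B3 takes precedence over "other" labels, RAV being the
more specific architecture); 1 AP2 + any other labeled domain → other;
exactly one AP2 → ERF/DREB. MIKC requires both SRF-TF and K-box; SRF-TF
alone (type I MADS genes) is excluded. The default accession map sends
both PF00847 and PF00876 to AP2 — scans in the wild report either — plus
PF02362 → B3, PF00319 → SRF-TF, PF01486 → K-box; unmapped accessions are
retained with label "other". Overlapping same-label hits on one protein
are merged into their union before repeat labeling, since domain scanners
often report split envelopes for one region.

## Ka/Ks

The implemented estimator is Nei–Gojobori (1986) counting with equal
pathway weighting and Jukes–Cantor correction. It is fully specifiable and
therefore verifiable against an exhaustive pathway-enumeration oracle over
all 61×61 sense-codon pairs (an acceptance test does exactly that);
context-dependent estimators (transition/transversion- and
codon-frequency-aware) are a compatible extension point, and the ordinal
micro-exon-vs-domain comparisons this package makes do not depend on the
choice.

Per-codon sites: at each position, the synonymous fraction of the three
single-nucleotide changes, with stop-creating changes excluded from both
numerator and denominator; `n = 3 − s`. Differences: average over all
minimal mutational pathways (1, 2, or 6 orderings), excluding pathways
through stop codons. Codon columns aligned to a gap, containing `N`, or
containing a stop are skipped entirely (complete-codon deletion). Site
counts are averaged between the two sequences, differences summed, and
`Ks = −¾ ln(1 − 4/3·ps)` (likewise `Ka`); the ratio is reported missing
when `Ks = 0` or a proportion reaches the correction's ¾ pole. Windowed
calls restrict to alignment columns, so disjoint windows sum exactly to
their union.

Protein pairs are aligned globally (Needleman–Wunsch, affine gaps, default
BLOSUM62 with open 10 / extend 1) via Biopython's `PairwiseAligner`; among
co-optimal alignments the aligner's deterministic enumeration order fixes
the result. Codons are then back-threaded through the alignment after
verifying that each CDS translates to its protein.

## Wilcoxon signed-rank comparison

Paired micro-exon vs domain ratios are compared one-sided. Pairs with a
missing ratio are dropped first, then zero differences (count reported).
For n ≤ 25 the p-value is exact: the null distribution of the positive-rank
sum is built by dynamic programming over doubled midranks (doubling keeps
tied midranks integral), which equals full enumeration of the 2^n sign
assignments. Beyond that, a normal approximation with continuity
correction and midrank tie variance is used; at n = 25 the two agree to
better than 0.01. The exact path is cross-checked against direct
enumeration and against `scipy.stats.wilcoxon` in the test suite.

## Distances, neighbor joining, bootstrap

Protein distances default to the Poisson correction `−ln(1 − p)` over
both-ungapped columns; saturated pairs (p = 1) are set to a configurable
cap (default 10) and flagged by that value. NJ is the standard Saitou–Nei
agglomeration: Q-matrix minimization with a deterministic smallest-(i,j)
tie-break, branch lengths clamped at 0, and a trifurcating root from the
three-point formula for the final triple — so additive matrices are
recovered exactly (path lengths to 1e-9 in tests, topology checked against
an independent NJ implementation). Bootstrap supports resample alignment
columns with replacement, rebuild distances and the tree per replicate,
and annotate the full-data tree with bipartition frequencies (0–100);
everything is driven by an explicit seed.

Multiple-sequence alignment is intentionally out of scope. Domain sets for
trees are aligned pairwise to the longest member and projected onto its
columns (insertions relative to the reference are dropped); the manifest
records this star-profile strategy. This keeps the alignment stage exactly
verifiable at the cost of ignoring residues absent from the reference — a
reasonable trade for well-conserved domains like AP2 and K-box, but not a
general MSA substitute.

## Synthetic data: what it emulates, and what it does not

The generator plants gene architectures codon-consistently: random
stop-free CDSs are cut into exons so that planted micro-exons of each
class fall inside (or outside) the planted domain residue intervals, with
UTRs on terminal exons, uniform intron/UTR/spacer lengths, both strands,
and an occasional shorter second isoform to exercise representative
selection. Domain tables are emitted for the representative proteins, so
files and ground truth agree by construction. Planted counts are
deterministic, never sampled: a requested in-domain proportion of 0.768
over 250 AP2/ERF micro-exons is planted as exactly 192/250.

Default study conditions mirror a rice-like census: 141 AP2/ERF genes
(113 ERF/DREB — two carrying an in-domain micro-exon — 22 AP2 subfamily,
4 RAV, 2 other) and 31 MIKC genes, most contributing a K-box tandem pair,
giving the characteristic ≈ 2:1 micro-exon-to-MIKC-gene ratio. The
enrichment preset plants 76.8% AP2 / 92.3% K-box in-domain proportions
exactly (92.3 at one-decimal precision: 120 of 130).

`evolve_pair` diverges two lineages from an ancestor by proposing uniform
single-nucleotide substitutions, accepting synonymous ones always,
nonsynonymous ones with probability ω, and stop-creating ones never, until
the realized synonymous divergence reaches the target. Realized divergence
is counted by the per-codon site oracle during simulation — the generator
never consults the estimator under test. Under these conditions
(500 codons, target Ks 0.3, 50 replicates) the NG86 ratio recovers ω to
within ±0.05 for ω ≤ 0.5 and ±0.1 at ω = 1.

What the generator does **not** model: splice-site motifs, indels,
base-composition bias (chromosomes are uniform ACGT), overlapping genes,
trans-splicing, or annotation errors. Passing tests therefore demonstrate
correctness of the coordinate arithmetic, classification logic and
estimators under clean annotations — not robustness to the noise of real
genome projects, where fragmented gene models and inconsistent phase
fields are the dominant failure mode.

## Numerical and degenerate-input choices

- Coordinate conversion is bijective and tested as such; empty or inverted
  intervals are rejected at construction.
- Genes without a valid coding transcript are excluded from the family
  scan with a warning; CDS segments outside any exon flag the transcript
  invalid rather than aborting the run.
- A codon pair with no stop-free pathway cannot occur among standard-code
  sense codons; a defensive fallback (equal weighting over all pathways)
  exists but is unreachable in practice.
- Zero-variance expression rows z-score to all zeros; z scores use the
  sample standard deviation (ddof = 1).
- Pipeline outputs are held in memory and written only after all stages
  succeed, so failures leave no partial report bundle.
- Problem sizes in the test-suite and acceptance runs (hundreds of genes,
  500-codon pairs, tens of bootstrap replicates) are the package's chosen
  desk-scale study conditions; every quantity is recomputed at run time
  from the seed.
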