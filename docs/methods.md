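# Methods

This note records the models, thresholds, and design choices behind
`anchorsmith`, and what the synthetic benchmarks do and do not demonstrate.

## The matching contract

All homology detection — genome scanning, read recruitment, extension —
uses one two-stage gapless contract:

* **Seed**: a window of `seed_window` = 20 bases matches when at least
  `seed_min_matches` = 17 care positions agree (N never matches). The seed
  is a spaced-seed template (`SpacedSeedPattern`); the default is all-care,
  i.e. a contiguous 20-mer with a ≤ 3-mismatch budget, because the original
  spaced template is not published. Arbitrary templates are accepted.
* **Confirmation**: the best gapless window of `confirm_window` = 100 bases
  containing the seed anchor must hold ≥ `confirm_min_matches` = 55
  identities. When the comparable region is shorter than 100 bases the
  threshold scales proportionally (ceil(55·w/100)); when a full window
  fits, only full windows are considered — clipped sub-windows would
  otherwise admit ~54%-identity noise. Two readings of "55 of 100 bp
  consecutive match" exist; both are implemented (`aligned`, the default:
  55 identities in the window; `consecutive`: an exact-match run of 55).

At 55% required identity over 100 bp, a random sequence passes with
probability ~P(Bin(100, 0.25) ≥ 55) < 1e-9, so decoy contigs produce no
targets; homologs at ≤ 15% divergence pass essentially always.

### Anchored search

Evaluating the contract at every (position, diagonal) pair is quadratic and
prohibitive in pure Python, so candidate gapless placements are proposed by
exact shared k-mers (`anchor_k` = 14) voting for diagonals, and the literal
seed + confirmation contract is then applied along each candidate diagonal
(vectorised over the overlap). A true homolog at 15% divergence shares an
expected ~0.85¹⁴ ≈ 10% of its 14-mers with the reference — dozens of
anchors per read — so the prescreen loses nothing in the regime the tool
targets; sensitivity degrades only beyond ~25% divergence, far outside the
anchor concept. Agreement between the anchored engine and the brute-force
contract is asserted in the test suite.

## Target discovery

Reciprocal best-match transcript pairing scores a pair of transcripts by
their number of shared canonical 20-mers (an internal stand-in for an
aligner bit-score; an adapter accepts external score tables). A pair is
emitted only when each member is the other's argmax; ties break
lexicographically and are logged.

Genome scanning validates every candidate diagonal of every reference
against both strands. Validated hits within `target_window` = 10,000 bp of
each other on one contig/strand merge leftmost-first into one locus; the
kept window is 10 kb centred on the hit span, clipped at contig ends. The
labelled reference is the one with most confirmed identities.

## Read processing and assembly

Demultiplexing is exact (no index mismatches). Pair merging searches all
gapless overlaps ≥ 12 bases, accepts mismatch rate ≤ 0.1, takes the
higher-quality base on conflict (merged quality |q1−q2|, max(q1,q2) on
agreement), and trims adapter read-through so the merged read spans exactly
the fragment. Unmerged mates are processed as single reads.

Assembly is a gapless layout: recruited reads carry an offset on the locus
reference axis, and per-site base counts are exact column sums
(indel-bearing reads simply fail confirmation and are not recruited).
Extension iterates: rebuild the majority consensus, rescan the shared
unassigned pool under the same contract, claim passing reads for the
best-matching cluster (ties with incompatible placements are rejected and
logged), until a round adds nothing. The pool is sorted by read id first,
making the result independent of input order; the recruited set grows
monotonically, bounding rounds by the pool size.

## Consensus and the ambiguity rule

A cluster is emitted only when average depth (aligned bases / consensus
length) is **strictly** greater than `min_avg_depth` = 250 — the gate the
enrichment protocol applies to capture data. At each site the majority base
is always retained (a tie retains both); a minority base with count c at
depth n is retained iff the one-sided exact binomial tail
P(X ≥ c | n, p) < α. The protocol states only "a 1% sequencing error":
we take p = 0.01 as the per-base miscall probability toward a specific
base (conservative; a /3 partition is available via
`error_partition_three`) and α = 0.05, both configurable. Uncovered sites
are N. The retained set maps to its IUPAC code.

Simulated panels run at 30× WGS-like coverage (the design-phase regime of
25–65× per species), so pipeline runs on simulated data use a depth gate of
10; the 250 boundary itself is exercised directly on constructed clusters.
At 30× the rule legitimately emits an ambiguity code wherever two reads
carry the same erroneous base (~1% of sites at α = 0.05), which is why the
truth-evaluation metric counts a site correct when the planted base lies
inside the consensus code's base set; strict identity is used everywhere
else (e.g. barcodes).

## Orthology

Consensi (plus the anchor references) are compared by Jaccard distance on
canonical distinct 20-mer sets — the simplest defensible reading of
"20-mer distribution overlap"; a multiplicity-weighted variant sits behind
a flag. Average-linkage agglomerative clustering is cut at
`cluster_cutoff`, and clusters containing a reference become ortholog
groups (duplicate-sample members keep the one nearest the cluster, flagging
the other as a putative paralog).

The cutoff default is 0.999. The calibration is analytic: a 20-mer survives
pairwise divergence p with probability (1−p)²⁰, so orthologs at 10–20%
pairwise divergence share only 1–13% of their k-mers (Jaccard distance
0.94–0.999), while unrelated loci share none (distance exactly 1.0, k-mer
collisions being ~L²/4²⁰). Any appreciable overlap therefore indicates the
same locus, and the cut belongs just below 1.0. A mid-range cutoff such as
0.7 only works below ~3% divergence and would shatter a realistic panel
into singletons.

## Alignment QC

Boundary conventions, each forced by the protocol wording or documented
here: the 50% reliable-site threshold is inclusive; the 14-base
misalignment run is inclusive (≥ 14 masked); "25 sequences required to be
present" is inclusive (24 removed); "loci represented by less than 50% ...
removed" is strict (exactly 50% survives). A "misaligned region" is
operationalised as a maximal run of consecutive reliable sites at which a
sequence disagrees with the site's modal character — agreement, a gap, or
an unreliable site breaks the run — masked in that sequence only. QC never
edits characters; it masks cells or removes sites/loci, and masked cells
are excluded from all site statistics.

Locus dedup removes, from any pair of loci sharing a canonical 20-mer
(gaps stripped), the locus with the smaller total ungapped length
(lexicographically later id on ties), repeating until all retained loci are
pairwise disjoint. Repeat masking computes each sequence's per-position
k-mer coverage in the WGS read profile and masks positions above
`repeat_elevation_factor` = 5 × the per-sequence median ("substantially
elevated" is not quantified in the protocol; the factor is configurable,
and a zero median falls back to the mean). The manual alignment-viewer
inspection steps of the original workflow are replaced by a per-locus QC
report (masked fraction, removed sites) for human review.

Multiple alignment is delegated to an external aligner adapter (command
template, default mafft). The internal fallback is a gapless star
alignment — every member placed against the longest by its best anchored
offset — which is *exact* for the substitution-only generator and is what
the test path uses; real indel-bearing data should use the adapter.

## Probe tiling

Probes of `probe_length` = 120 bp are laid at step round(120/3.5) = 34
along each gap-stripped source, with the final probe right-anchored at
L − 120 so coverage has no terminal gap; interior positions are covered by
⌊3.5⌋ or ⌈3.5⌉ probes and achieved density converges to 3.5 with source
length. The 120 bp length is a capture-kit convention, not printed in the
protocol, and is configurable. Probes touching masked or N positions are
dropped. Step rounding and right-anchoring are this package's choices.

## Synthetic panels: what they emulate, and what they do not

`simulate_panel` plants, per locus, a root of conserved core (default
400 bp, mutated per taxon at half the panel divergence) and variable flanks
(250 bp each side, full divergence), embedded on its own contig with 300 bp
random margins and a random strand, plus a 10 kb background contig with
planted repeat families; two designated taxa contribute transcripts (their
cores). `simulate_reads` draws paired 150 bp reads (fragment 350 ± 50 bp,
matching a 300–500 bp sonication target), uniform 1% per-base error, 8 bp
sample indexes, adapter read-through for short fragments, and optional
50/50 heterozygous sites, with a truth table linking every fragment to its
origin. Defaults (10 taxa, 20 loci, 10% divergence, 30× coverage) mirror
the study regime of a congeneric invertebrate panel.

The mutation model is substitution-only so truth alignments are positional
and every oracle exact; there are no indels, no coalescent genealogies, no
GC or machine-specific error structure, no paralogous anchor families, and
repeat copies are nearly identical. Passing benchmarks therefore
demonstrate the correctness of the matching/assembly/consensus machinery
under the stated divergence and coverage, not robustness to indel-rich or
repeat-saturated genomes — on real data the external aligner and the
configurable thresholds carry that weight.

Benchmark problem sizes (10 × 20 panel, 2 kb decoys, 5 kb tiling sources,
depth grid to 1000×) keep a full study run to a couple of minutes on one
CPU while leaving every threshold at its protocol value.

## Numerical and degenerate-input choices

* Exact binomial tails via `scipy.stats.binom.sf`; the per-depth retention
  threshold is the smallest c with sf(c−1) < α, cached per depth. The test
  suite checks it against an independent `math.comb` tail sum.
* Ties: majority-base ties retain both bases (logged); best-match ties in
  pairing and assignment break lexicographically; the star-alignment centre
  is the longest sequence (id as tie-break).
* Empty profiles: distance between two empty k-mer profiles is 1 with a
  warning; sequences shorter than k get an all-1 distance row.
* Targets shorter than a probe yield a single whole-source probe with a
  warning; an all-zero coverage track masks nothing.
* Intervals are 0-based half-open everywhere internally; BED export
  bit-matches that convention; partition files are 1-based inclusive.

## Known limitations

* Gapless assembly: indel polymorphism within a locus-sample is not
  represented (such reads are simply not recruited); an indel-rich sample
  loses depth rather than gaining wrong bases.
* The reciprocal-pairing score (shared 20-mers) saturates for very long,
  very similar transcripts; the adapter hook exists for external scores.
* Orthology assumes ortholog groups contain a reference-linked member;
  reference-free clusters are reported only in logs.
* `percent_identity`'s unaligned mode is gapless best-overlap; barcodes
  with real indels should be pre-aligned.
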