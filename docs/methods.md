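# Methods

## The REP model

A REP element is modelled as a string over the IUPAC alphabet with the
layout

```
[lead ≤ 1 nt] GT(A/G)G [arm offset ≤ 3 nt] [left arm] [loop 1–7 nt] [right arm] [flank ≤ 4 nt]
```

where the right arm is the *exact* reverse complement of the left arm under
degenerate complementarity: two IUPAC codes pair iff each equals the
base-set complement of the other (R↔Y, M↔K, S↔S, W↔W; partial base-set
overlap never pairs).  The structure finder enumerates every
(lead, arm offset, stem length, loop length) combination within these
bounds and keeps the longest stem, breaking ties toward the smaller arm
offset, then the smaller loop.  The bounds are the smallest box containing
every catalogued consensus; total element length is capped at 26 nt.

Architecture classification follows the two host groups' described
geometries: **SM-like** = stem of 8–9 bp at arm offset ≤ 1 (palindrome
directly adjacent to the tetranucleotide), **PF-like** = stem of 4–7 bp at
arm offset 2–3 (palindrome set off by a 2–3 nt spacer), anything else
**other**.

All 13 SM catalog consensi parse SM-like with stems of exactly 8 or 9 bp.
Because arm pairing is exact, seven PF catalog entries (PF2, PF4, PF11,
PF12, PF20, PF21 without any qualifying stem; PF9 with only a degenerate
4-bp parse) do not yield a PF-like structure: their published palindromes
evidently tolerate internal mismatches.  We deliberately do not relax the
pairing rule — "perfectly complementary" is what the census and the
REPIN concept rest on — and store these entries with no structure and
architecture "other".  They still participate fully in the census, which
uses only the consensus string.

## Perfect-copy census

A copy is a genome window satisfying the consensus position-by-position
(IUPAC base-set membership); a genome `N` satisfies nothing, so ambiguous
bases can never be certified part of a perfect copy.  Both strands are
scanned (the reverse strand via the reverse-complement consensus); a
self-reverse-complementary consensus is counted once per site.  Overlapping
occurrences are all counted as distinct (start, strand) pairs — no
exclusion rule is defensible for exact 20+-mers, and overlaps are
vanishingly rare.  Multi-contig inputs are summed; matches never span
contig boundaries.

REPIN pairing is greedy left-to-right: each match pairs with the nearest
downstream opposite-strand match within a spacer cap (default 100 nt,
config-exposed; the biological description is only "closely spaced"), each
match used at most once.

## RAYT search

Seed proteins are aligned locally (BLOSUM62; gap of length *k* costs
11 + *k*) against all six reading frames (bacterial genetic code, table 11;
codons containing non-ACGT translate to X).  Hits at or above a threshold —
by default 0.4 × the query's self-score, a length-robust fraction rather
than an absolute cutoff — are mapped back to nucleotide coordinates and
extended to the enclosing ORF (nearest upstream methionine not crossing a
stop; through the next in-frame stop).  Found regions are masked and the
frame re-searched, so multiple copies are recovered; overlapping hits from
different queries keep the best score.  The local aligner is
Bio.Align.PairwiseAligner; tests verify score equality against an
independent brute-force affine-gap dynamic program on hundreds of random
pairs.

Motif validation (H-x-H histidine pair plus a downstream tyrosine, both
configurable) only *flags* hits: the family's motif positions vary and no
positional ground truth is available, so failing the rule never discards a
hit.

The packaged seed query is a **synthetic stand-in** protein carrying the
family motifs; it exists so the pipeline and its tests run without any
database access.  Real analyses should supply real RAYT protein FASTAs.

## Classes and orthogroups

Per-strain consensi merge into one cross-strain class when equal length and
position-wise mergeable: per position the union of base sets is encoded as
an IUPAC code, subject to a pairwise Hamming distance ≤ 3 over concrete
positions and at most 4 degenerate positions in the merged consensus (the
maximum observed in the catalog).  Processing order is lexicographic by
consensus string, so the outcome is input-order-free.

RAYT orthology requires (a) reciprocal best global-identity match ≥ 0.6
between the RAYTs of two strains and (b) at least one flanking CDS pair
with identity ≥ 0.7 on the same relative side within 5 genes — an
operational definition of synteny; neither threshold has a published value,
both are config-exposed.  Connected components carrying ≥ 2 distinct REP
classes become orthogroups, numbered with roman numerals in order of first
appearance; everything else is pooled as "NO".

## Phylogeny

Distances: p-distance or Jukes–Cantor −(3/4)·ln(1 − 4p/3) (error on
saturation p ≥ 0.75); sites with a gap or N in either row of a pair are
excluded pairwise, keeping maximal data.  Jukes–Cantor is the default —
the simplest defensible correction; the choice is exposed because the
original analyses' distance model is not recorded.  Neighbor-Joining uses
the standard Q criterion with ties broken toward the lexicographically
smallest pair of cluster representatives, giving bit-reproducible trees;
negative branch lengths are clamped to zero and the final three-cluster
star is resolved exactly.  Bootstrap resamples columns with replacement
under a seeded generator; replicates with undefined distances are skipped
with the support denominator adjusted; an all-identical alignment returns a
star tree with no internal splits.

## Synthetic data: what it establishes

The generator emulates the study regime — ~60% GC genomes, REP classes at
tens to hundreds of copies (thousands are feasible by configuration), REPIN
doublets with short uniform spacers, RAYT CDS flanked by an inverted REP
pair, and mutational decay.  Two design choices make planted truth exact
rather than statistical:

* decay substitutions land only on concrete consensus positions and always
  change the base, so a decayed copy is guaranteed not to census;
* a guard base is forced on each boundary of the RAYT-flanking REP copies
  so ungapped inverted-repeat extension stops exactly at the planted
  element, and independently planted elements are kept ≥ 120 nt apart so
  they can never pair as a spurious doublet.

RAYT coding sequences are produced by most-frequent-codon back-translation
of the seed protein — adequate because the detector is alignment-based.

What passing synthetic tests therefore shows: the counting, pairing,
discovery and trimming machinery is exact under its own model.  What it
does not show: agreement with published genome-scale copy numbers, which
depends on the (unrecorded) counting conventions of the original tooling
and requires the real assemblies; real flanks also contain partially
decayed repeat copies, nested elements and annotation noise absent from
the simulation.

## Problem sizes and numerical choices

Default test and acceptance runs use 30–120 kb genomes, 20–100 planted
copies per class, 10 simulation seeds and 100 bootstrap replicates — sizes
chosen so the whole suite exercises every stage in well under a minute per
module while keeping every assertion exact.  The pipeline itself has no
such limits; the CLI default for bootstrap is 1000 replicates.

Degenerate inputs: empty FASTA, windows ≤ 0, alignments with zero
comparable sites, < 3 taxa for NJ, and merges exceeding the degeneracy
budget all raise immediately with named errors rather than degrading.

## Known limitations

* No mismatch-tolerant census and no probabilistic motif models: "perfect
  copy" is the unit of measurement throughout.
* Frameshifted or truncated RAYTs appear as split or short hits; no
  pseudogene reconstruction is attempted.
* Orthogrouping on real data depends on annotation quality of the flanking
  genes; the packaged catalog carries the published grouping for reference.
* No multiple sequence alignment; phylogeny inputs must be pre-aligned.
* Clade delineation on trees is left to the user.
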