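# repatlas

Comparative genomics of **REP elements** (repetitive extragenic palindromic
sequences), **REPIN** doublets and their putative mobilizers, the **RAYT**
transposases, in bacterial genomes.

## The problem

REPs are short, highly abundant intergenic repeats of many
gammaproteobacteria, defined by a conserved 5′-terminal tetranucleotide
GT(A/G)G followed by a palindromic region (a stem–loop).  Two closely
spaced REPs in inverted orientation form a REPIN, the predominant
arrangement in pseudomonads and stenotrophomonads.  Adjacent to REPs one
often finds *rayt* genes (REP-associated tyrosine transposases,
IS200/IS605-related proteins with a catalytic tyrosine and two
metal-coordinating histidines), the likely drivers of REP proliferation.
Comparing which REP sequence classes a set of related strains carries, in
how many perfect copies, and whether the cognate RAYT is still intact,
reveals the evolutionary dynamics of this repeat/mobilizer system.

`repatlas` implements that analysis as a reusable pipeline:

1. **rayt_finder** — locate RAYT genes by annotation lookup and/or
   six-frame translated Smith–Waterman search against seed proteins
   (BLOSUM62, affine gaps, hits extended to the enclosing ORF), with
   validation of the H-x-H + downstream-Y motif rule.
2. **rep_discovery** — extract the inverted repeats flanking each RAYT,
   parse their architecture (lead base, GT(A/G)G tetranucleotide, stem arms
   under *degenerate complementarity* — R pairs Y, M pairs K — around a
   short loop), and merge slight variants into IUPAC consensi.
3. **rep_census** — count *perfect* copies of each consensus genome-wide on
   both strands (a genome N never matches) and pair inverted doublets into
   REPINs; emit strain × class abundance matrices.
4. **rep_classes** — unify per-strain consensi into cross-strain classes
   and group classes into *orthogroups* via RAYT orthology (reciprocal best
   match + conserved gene neighborhood).
5. **phylo** — p/Jukes–Cantor distances, deterministic Neighbor-Joining
   (Saitou–Nei `Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`), bootstrap
   supports, Newick output, for concatenated *gyrB/rpoB/rpoD* alignments.
6. **synthetic_data** — genomes with planted RAYT cassettes, REP/REPIN
   copies and forced mutational decay, plus an exact ground-truth table.

The package ships a catalog of 35 published REP consensus classes —
PF1–PF22 for the *Pseudomonas fluorescens* species complex and SM1–SM13 for
stenotrophomonads — with orthogroup assignments and cognate-RAYT accessions.

## Worked example

Simulate a 60 kb genome with 60 planted SM1 copies (half as REPIN doublets)
and 20 SM12 copies of which 25% are mutationally decayed, then census it
against the packaged catalog:

```sh
$ cat sim.yaml
genome_length: 60000
gc: 0.6
seed: 42
classes:
  - label: SM1
    consensus: GGTGGGTGCCGACCGTTGGTCGGCAC
    copies: 60
    repin_fraction: 0.5
  - label: SM12
    consensus: GTAGAGTCGAGCTTGCTCGACT
    copies: 20
    decay_fraction: 0.25

$ repatlas simulate --config sim.yaml --out sim_out
$ repatlas census sim_out/synthetic.fasta --out abundance.tsv
```

The nonzero columns of the abundance matrix:

```
           SM1  SM12
strain
synthetic   60    15
```

All 60 SM1 copies census as perfect; of the 20 planted SM12 copies only the
15 undecayed ones do — each decayed copy received a substitution at a
concrete consensus position and no longer counts as a perfect copy.  The
`run` subcommand chains every stage (`repatlas run --config run.yaml`) and
also writes REPIN pairings, a class × strain table with cognate-RAYT status
(present / pseudogene-flagged / absent), and an optional bootstrapped NJ
tree.

From Python, the same operations are plain functions:

```python
from repatlas.catalog import load_packaged_catalog
from repatlas.rep_census import count_matches

catalog = load_packaged_catalog()
sm1 = catalog.get("SM1").consensus       # GGTGGGTGCCGACCGTTGGTCGGCAC
print(sm1.structure.stem_len)            # 9 — perfectly complementary arm
```

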