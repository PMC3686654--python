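"""Candidate REP extraction and structural parsing.

A REP element is defined by two sequence features: a conserved 5'-terminal
tetranucleotide GT(A/G)G, optionally preceded by a single lead base, and a
downstream palindromic region — two arms that pair under *degenerate
complementarity* (two IUPAC codes pair iff each is exactly the base-set
complement of the other, so R pairs Y, M pairs K, S pairs S) around a short
unpaired loop.

Stenotrophomonad-type ("SM-like") elements carry 8–9 perfectly complementary
stem bases directly adjacent to the tetranucleotide; fluorescent-pseudomonad
("PF-like") elements interpose 2–3 spacer bases and carry a shorter stem.

Candidate REPs are pulled from the two flanks of a RAYT gene as inverted
repeats: a segment upstream whose reverse complement recurs downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .seq_core import (
    GenomeRecord,
    base_set,
    code_for_set,
    complement_code,
    reverse_complement,
)

TETRA_RE = re.compile("GT[AG]G")

# Structure-search bounds: the smallest box containing every catalogued
# consensus (lead <=1, arm offset <=3, loop 1..7, total <=26).
MAX_LEAD = 1
MAX_ARM_OFFSET = 3
MAX_LOOP = 7
MIN_LOOP = 1
DEFAULT_MIN_STEM = 4
MAX_REP_LEN = 26
MAX_RIGHT_FLANK = 4
MAX_DEGENERATE = 4


@dataclass(frozen=True)
class RepStructure:
    """Parsed architecture of one REP consensus.

    Layout (positions within the consensus string)::

        [lead_offset][tetranucleotide GT(A/G)G][arm_offset][left arm][loop][right arm][flank]
    """

    lead_offset: int
    tetranucleotide: str
    arm_offset: int
    stem_len: int
    loop_len: int
    total_len: int

    def __post_init__(self) -> None:
        if not _is_tetra(self.tetranucleotide):
            raise ValueError(f"tetranucleotide {self.tetranucleotide!r} does not fit GT[AG]G")
        if self.lead_offset > MAX_LEAD or self.arm_offset > MAX_ARM_OFFSET:
            raise ValueError("lead/arm offset out of range")
        if self.loop_len < MIN_LOOP:
            raise ValueError("loop must contain at least one base")
        if self.lead_offset + 4 + self.arm_offset + 2 * self.stem_len + self.loop_len > self.total_len:
            raise ValueError("structure does not fit in sequence")

    @property
    def stem_end(self) -> int:
        """Index one past the last base of the right stem arm."""
        return self.lead_offset + 4 + self.arm_offset + 2 * self.stem_len + self.loop_len


@dataclass
class RepConsensus:
    """An IUPAC consensus with its parsed architecture and catalog metadata."""

    label: str
    iupac: str
    structure: Optional[RepStructure] = None
    cognate_rayt: Optional[str] = None
    architecture: str = "other"
    orthogroup: str = "NO"

    def __post_init__(self) -> None:
        self.iupac = self.iupac.upper()
        degenerate = sum(1 for c in self.iupac if c not in "ACGT")
        if degenerate > MAX_DEGENERATE:
            raise ValueError(
                f"{self.label}: {degenerate} degenerate positions exceeds budget {MAX_DEGENERATE}"
            )


def _is_tetra(tet: str) -> bool:
    """GT(A/G)G under IUPAC subset semantics (so GTRG qualifies)."""
    if len(tet) != 4:
        return False
    targets = [frozenset("G"), frozenset("T"), frozenset("AG"), frozenset("G")]
    try:
        return all(base_set(c) <= t for c, t in zip(tet, targets))
    except ValueError:
        return False


def _arms_pair(left: str, right: str) -> bool:
    """Degenerate complementarity: right must be exactly the reverse
    complement of left, code for code (partial base-set overlap never pairs)."""
    if len(left) != len(right):
        return False
    return all(
        complement_code(l) == right[len(left) - 1 - i] for i, l in enumerate(left)
    )


class NotARepError(ValueError):
    """Sequence lacks the tetranucleotide or a qualifying stem."""


def find_rep_structure(seq: str, min_stem: int = DEFAULT_MIN_STEM) -> RepStructure:
    """Parse the tetranucleotide/stem/loop architecture of a REP candidate.

    The tetranucleotide must start at position 0 or 1.  Among all placements
    with arm_offset 0..3 and loop 1..7 whose arms pair under degenerate
    complementarity, the longest stem wins; ties break toward the smaller
    arm_offset, then the smaller loop.
    """
    seq = seq.upper()
    if len(seq) < 15:
        raise NotARepError("sequence shorter than 15 nt")
    lead = None
    for cand in range(MAX_LEAD + 1):
        if _is_tetra(seq[cand : cand + 4]):
            lead = cand
            break
    if lead is None:
        raise NotARepError("no GT[AG]G tetranucleotide within the first 2 positions")
    best: Optional[tuple[int, int, int]] = None  # (stem, arm_offset, loop)
    for off in range(MAX_ARM_OFFSET + 1):
        arm_start = lead + 4 + off
        for loop in range(MIN_LOOP, MAX_LOOP + 1):
            max_stem = (len(seq) - arm_start - loop) // 2
            for stem in range(min_stem, max_stem + 1):
                left = seq[arm_start : arm_start + stem]
                right = seq[arm_start + stem + loop : arm_start + 2 * stem + loop]
                if _arms_pair(left, right):
                    key = (stem, off, loop)
                    if best is None or (stem, -off, -loop) > (best[0], -best[1], -best[2]):
                        best = key
    if best is None:
        raise NotARepError(f"no degenerate-complementary stem of length >= {min_stem}")
    stem, off, loop = best
    return RepStructure(
        lead_offset=lead,
        tetranucleotide=seq[lead : lead + 4],
        arm_offset=off,
        stem_len=stem,
        loop_len=loop,
        total_len=len(seq),
    )


def classify_architecture(structure: RepStructure) -> str:
    """SM-like: 8-9 bp stem directly adjacent (arm_offset <= 1).
    PF-like: 4-7 bp stem behind a 2-3 nt spacer.  Anything else: other."""
    if structure.stem_len in (8, 9) and structure.arm_offset <= 1:
        return "SM-like"
    if 4 <= structure.stem_len <= 7 and 2 <= structure.arm_offset <= 3:
        return "PF-like"
    return "other"


# ---------------------------------------------------------------------------
# Flank extraction and inverted-repeat search


def extract_flanks(
    genome: GenomeRecord, start: int, end: int, window: int = 500
) -> tuple[str, str]:
    """Sequence windows immediately upstream/downstream of a gene interval,
    both in forward genome orientation, clipped at contig edges."""
    if window <= 0:
        raise ValueError("window must be positive")
    up = genome.sequence[max(0, start - window) : start]
    down = genome.sequence[end : min(genome.length, end + window)]
    return up, down


def find_inverted_pair(
    upstream: str,
    downstream: str,
    seed_len: int = 12,
    min_len: int = 15,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All maximal segments present in the upstream flank whose reverse
    complement occurs in the downstream flank.

    Seeding by shared k-mers between `upstream` and revcomp(`downstream`),
    ungapped extension to the maximal exact match, pairs shorter than
    `min_len` dropped.  Returned as ((up_start, up_end), (down_start,
    down_end)) interval pairs in each flank's own forward coordinates,
    sorted by length descending then by proximity to the gene (upstream end
    closest to the gene first).
    """
    if seed_len < 8:
        raise ValueError("seed_len must be >= 8")
    up = upstream.upper()
    rcd = reverse_complement(downstream.upper())
    if len(up) < seed_len or len(rcd) < seed_len:
        return []
    kmers: dict[str, list[int]] = {}
    for i in range(len(up) - seed_len + 1):
        kmers.setdefault(up[i : i + seed_len], []).append(i)
    found: set[tuple[int, int, int, int]] = set()
    for j in range(len(rcd) - seed_len + 1):
        for i in kmers.get(rcd[j : j + seed_len], ()):
            a, b = i, j
            while a > 0 and b > 0 and up[a - 1] == rcd[b - 1]:
                a -= 1
                b -= 1
            e_a, e_b = i + seed_len, j + seed_len
            while e_a < len(up) and e_b < len(rcd) and up[e_a] == rcd[e_b]:
                e_a += 1
                e_b += 1
            if e_a - a >= min_len:
                found.add((a, e_a, b, e_b))
    pairs = []
    for a, e_a, b, e_b in found:
        down_iv = (len(downstream) - e_b, len(downstream) - b)
        pairs.append(((a, e_a), down_iv))
    pairs.sort(key=lambda p: (-(p[0][1] - p[0][0]), len(up) - p[0][1], p[1][0]))
    return pairs


def trim_to_rep_unit(candidate: str, min_stem: int = DEFAULT_MIN_STEM) -> str:
    """Trim an inverted-repeat segment to the REP unit proper.

    Orientation is chosen so the tetranucleotide sits near the 5' end; the
    unit starts at most one lead base before GT(A/G)G, ends at the last stem
    base plus at most 4 flanking nt, and never exceeds 26 nt total.
    """
    for seq in (candidate.upper(), reverse_complement(candidate)):
        try:
            structure = find_rep_structure(seq, min_stem=min_stem)
        except NotARepError:
            continue
        end = min(structure.stem_end + MAX_RIGHT_FLANK, len(seq), MAX_REP_LEN)
        return seq[:end]
    raise NotARepError("no orientation yields a tetranucleotide-led stem-loop")


# ---------------------------------------------------------------------------
# Consensus building


def merge_to_consensus(variants: list[str]) -> str:
    """Merge slightly different REP variants into one IUPAC consensus.

    Per position, the union of observed base sets is encoded as an IUPAC
    code.  Guards: all variants equal length; pairwise Hamming distance over
    positions where both variants are concrete must be <= 3; the merged
    consensus may not carry more than 4 degenerate positions.
    """
    if not variants:
        raise ValueError("no variants to merge")
    variants = [v.upper() for v in variants]
    length = len(variants[0])
    if any(len(v) != length for v in variants):
        raise ValueError("variants have unequal lengths")
    for i, a in enumerate(variants):
        for b in variants[i + 1 :]:
            dist = sum(
                1
                for x, y in zip(a, b)
                if x in "ACGT" and y in "ACGT" and x != y
            )
            if dist > 3:
                raise ValueError(f"variants differ at {dist} > 3 concrete positions")
    merged = []
    for pos in range(length):
        union: frozenset[str] = frozenset()
        for v in variants:
            union |= base_set(v[pos])
        merged.append(code_for_set(union))
    consensus = "".join(merged)
    degenerate = [i for i, c in enumerate(consensus) if c not in "ACGT"]
    if len(degenerate) > MAX_DEGENERATE:
        raise ValueError(
            f"merge would create {len(degenerate)} degenerate positions "
            f"(budget {MAX_DEGENERATE}) at {degenerate}"
        )
    return consensus
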