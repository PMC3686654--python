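"""Genome-wide census of perfect REP copies and REPIN doublet detection.

"Perfect copy" means a genome window that satisfies the class consensus
position by position under IUPAC semantics — no mismatches tolerated, and
genome Ns never match.  Both strands are scanned (a reverse-strand copy is a
window matching the reverse complement of the consensus); a consensus that
is its own reverse complement is counted once per site.  Overlapping
occurrences are all counted: distinct (start, strand) pairs.

REPINs — two closely spaced perfect copies in inverted orientation, jointly
able to fold into a long hairpin — are paired greedily left to right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .rep_discovery import RepConsensus
from .seq_core import GenomeRecord, reverse_complement

DEFAULT_MAX_SPACER = 100


@dataclass(frozen=True)
class RepMatch:
    genome_id: str
    start: int
    strand: str
    class_label: str
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Repin:
    left: RepMatch
    right: RepMatch

    @property
    def spacer(self) -> int:
        return self.right.start - self.left.end

    def __post_init__(self) -> None:
        if self.left.start >= self.right.start:
            raise ValueError("REPIN members out of order")
        if self.left.strand == self.right.strand:
            raise ValueError("REPIN members must be on opposite strands")
        if self.spacer < 0:
            raise ValueError("REPIN members overlap")


_IUPAC_TO_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_regex(consensus: str) -> re.Pattern:
    """Overlap-permitting regex for all perfect matches of an IUPAC
    consensus.  Character classes list concrete bases only, so genome Ns
    can never satisfy any position."""
    body = "".join(_IUPAC_TO_CLASS[c] for c in consensus.upper())
    return re.compile(f"(?=({body}))")


def count_matches(
    genome: GenomeRecord, consensus: RepConsensus
) -> tuple[int, list[RepMatch]]:
    """Count and locate all perfect copies of a consensus on both strands."""
    motif = consensus.iupac
    matches: list[RepMatch] = []
    for m in iupac_regex(motif).finditer(genome.sequence):
        matches.append(
            RepMatch(genome.id, m.start(), "+", consensus.label, len(motif))
        )
    rc = reverse_complement(motif)
    if rc != motif:  # palindromic consensus: one count per site
        for m in iupac_regex(rc).finditer(genome.sequence):
            matches.append(
                RepMatch(genome.id, m.start(), "-", consensus.label, len(motif))
            )
    matches.sort(key=lambda x: (x.start, x.strand))
    return len(matches), matches


def detect_repins(
    matches: Sequence[RepMatch], max_spacer: int = DEFAULT_MAX_SPACER
) -> list[Repin]:
    """Greedy left-to-right pairing of inverted doublets.

    Each match pairs with the nearest downstream opposite-strand match whose
    spacer is within [0, max_spacer]; every match is used at most once,
    unpaired matches remain singletons.
    """
    ordered = sorted(matches, key=lambda m: m.start)
    used = [False] * len(ordered)
    repins: list[Repin] = []
    for i, left in enumerate(ordered):
        if used[i]:
            continue
        for j in range(i + 1, len(ordered)):
            if used[j]:
                continue
            right = ordered[j]
            spacer = right.start - left.end
            if spacer > max_spacer:
                break
            if spacer < 0 or right.strand == left.strand:
                continue
            used[i] = used[j] = True
            repins.append(Repin(left, right))
            break
    return repins


def build_abundance_matrix(
    counts: dict[str, dict[str, int]], class_order: Sequence[str]
) -> pd.DataFrame:
    """Strain x class copy-number matrix, zero-filled, columns in catalog
    order (PF1..PF22 / SM1..SM13 style)."""
    strains = list(counts)
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain id")
    df = pd.DataFrame(0, index=strains, columns=list(class_order), dtype=int)
    for strain, per_class in counts.items():
        for label, n in per_class.items():
            if label not in df.columns:
                raise KeyError(f"class {label} not in catalog order")
            df.loc[strain, label] = int(n)
    df.index.name = "strain"
    return df


def write_abundance_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def matches_to_gff3(
    matches: Iterable[RepMatch], repins: Optional[Sequence[Repin]] = None
):
    """Matches (and REPIN pairings, via shared ID attributes) as GFF3 rows."""
    from .seq_core import Gff3Record

    partner: dict[RepMatch, str] = {}
    for k, rep in enumerate(repins or ()):
        partner[rep.left] = f"repin{k:05d}"
        partner[rep.right] = f"repin{k:05d}"
    out = []
    for i, m in enumerate(sorted(matches, key=lambda x: (x.genome_id, x.start))):
        attrs = {"ID": f"rep{i:06d}", "class": m.class_label}
        if m in partner:
            attrs["repin"] = partner[m]
        out.append(
            Gff3Record(
                seqid=m.genome_id,
                source="repatlas",
                type="repeat_region",
                start=m.start,
                end=m.end,
                strand=m.strand,
                attributes=attrs,
            )
        )
    return out
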