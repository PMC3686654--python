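"""Sequence containers, IUPAC algebra and plain-text format I/O.

Everything downstream of this module works with a single coordinate
convention: 0-based, half-open intervals on the forward strand.  The only
place 1-based inclusive coordinates appear is the GFF3 writer.

The IUPAC ambiguity algebra here is what makes degenerate REP consensus
sequences (e.g. ``GTRG``, ``GTAGMGCCGGGYTCTRCCCGGCK``) first-class citizens:
every code maps to a base set, complements act on base sets, and a consensus
position matches a genome base iff the base is in the set.  An ``N`` in the
*genome* never matches anything — a copy cannot be certified perfect over an
ambiguous base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# IUPAC algebra

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

IUPAC_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


def base_set(code: str) -> frozenset[str]:
    """Base set of a single IUPAC code (uppercase)."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise ValueError(f"not an IUPAC code: {code!r}") from None


def code_for_set(bases: Iterable[str]) -> str:
    """Inverse of :func:`base_set`: the IUPAC code for a set of bases."""
    key = frozenset(bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def complement_code(code: str) -> str:
    """Complement of an IUPAC code via base-set complementation (R<->Y, M<->K...)."""
    try:
        return IUPAC_COMPLEMENT[code]
    except KeyError:
        raise ValueError(f"not an IUPAC code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    seq = seq.upper()
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"not an IUPAC code: {exc.args[0]!r}") from None


def iupac_match(consensus_char: str, genome_char: str) -> bool:
    """True iff the genome base satisfies the consensus position.

    The genome character must be one of A, C, G, T, N; N never matches any
    consensus code (including consensus N), so only unambiguous genome bases
    can contribute to a perfect copy.
    """
    if genome_char == "N":
        return False
    if genome_char not in "ACGT":
        raise ValueError(f"genome character must be A/C/G/T/N, got {genome_char!r}")
    return genome_char in base_set(consensus_char.upper())


def matches_consensus(consensus: str, window: str) -> bool:
    """Position-wise IUPAC match of an equal-length genome window."""
    if len(consensus) != len(window):
        return False
    return all(iupac_match(c, g) for c, g in zip(consensus.upper(), window))


# ---------------------------------------------------------------------------
# Containers


@dataclass
class GenomeRecord:
    """One contig/replicon: id plus an uppercase A/C/G/T/N sequence."""

    id: str
    sequence: str
    source_path: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """An annotated CDS: 0-based half-open interval plus optional product/protein."""

    genome_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad CDS interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.protein is not None and (self.end - self.start) < 3 * len(self.protein):
            raise ValueError("CDS interval too short for its protein translation")


# ---------------------------------------------------------------------------
# FASTA


def _normalize_genome_seq(raw: str, name: str) -> str:
    """Uppercase, U->T, map non-ACGTN ambiguity codes to N, reject non-IUPAC.

    Error positions are reported 1-based, as users will look them up in the
    source file.
    """
    seq = raw.upper().replace("U", "T")
    out = []
    for i, c in enumerate(seq):
        if c in "ACGTN":
            out.append(c)
        elif c in IUPAC_SETS:
            out.append("N")
        else:
            raise ValueError(f"record {name}: illegal character {c!r} at position {i + 1}")
    return "".join(out)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (uppercased, U->T, validated)."""
    path = Path(path)
    records = [
        GenomeRecord(
            id=rec.id,
            sequence=_normalize_genome_seq(str(rec.seq), rec.id),
            source_path=str(path),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path: str | Path) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a GenBank flat file: genome sequence plus CDS features.

    CDS locations arrive from Biopython already converted to 0-based
    half-open; /product and /translation are captured when present.
    Malformed CDS features are skipped with a warning.
    """
    path = Path(path)
    rec = next(SeqIO.parse(str(path), "genbank"), None)
    if rec is None:
        raise ValueError(f"no GenBank record in {path}")
    seq = str(rec.seq)
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise ValueError(f"GenBank record {rec.id} has no sequence")
    genome = GenomeRecord(
        id=rec.id, sequence=_normalize_genome_seq(seq, rec.id), source_path=str(path)
    )
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        try:
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            product = (feat.qualifiers.get("product") or [""])[0]
            translation = (feat.qualifiers.get("translation") or [None])[0]
            features.append(
                GeneFeature(
                    genome_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    protein=translation,
                )
            )
        except (ValueError, TypeError, AttributeError) as exc:
            logger.warning("skipping malformed CDS in %s: %s", path, exc)
    return genome, features


# ---------------------------------------------------------------------------
# Translation (bacterial code, table 11)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE11.stop_codons})


def translate(seq: str) -> str:
    """Translate a DNA string under the bacterial code; any codon containing
    a non-ACGT character becomes 'X'; trailing partial codon dropped."""
    seq = seq.upper()
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(aa)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six reading frames, keyed +1,+2,+3 (forward) and -1,-2,-3
    (reverse complement), stops rendered as '*'."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(seq)
    return {
        +1: translate(seq),
        +2: translate(seq[1:]),
        +3: translate(seq[2:]),
        -1: translate(rc),
        -2: translate(rc[1:]),
        -3: translate(rc[2:]),
    }


# ---------------------------------------------------------------------------
# Feature writers (GFF3 is the only 1-based surface)


@dataclass
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int  # 0-based half-open in memory
    end: int
    score: str = "."
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(records: Iterable[Gff3Record], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={v}" for k, v in r.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [
                        r.seqid,
                        r.source,
                        r.type,
                        str(r.start + 1),  # 1-based inclusive
                        str(r.end),
                        r.score,
                        r.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(records: Iterable[Gff3Record], path: str | Path) -> None:
    """BED (0-based half-open) companion writer."""
    with open(path, "w") as fh:
        for r in records:
            name = r.attributes.get("ID", r.type)
            fh.write(f"{r.seqid}\t{r.start}\t{r.end}\t{name}\t{r.score}\t{r.strand}\n")
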