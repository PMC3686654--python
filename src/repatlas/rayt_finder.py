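"""Locating RAYT (REP-associated tyrosine transposase) genes.

Two routes into a genome: trusting existing CDS annotations (product-name
match), or a translated homology search — all six reading frames of the
genome locally aligned against seed RAYT proteins, hits mapped back to
nucleotide coordinates and extended to the enclosing ORF.

RAYTs belong to the IS200/IS605 transposase family and carry a catalytic
tyrosine plus two metal-coordinating histidines; `validate_rayt` checks a
configurable motif rule (H-x-H followed by a downstream Y).  Failing the
rule only flags a hit, it never discards one: motif positions vary across
the family and the rule is a heuristic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_core import GeneFeature, GenomeRecord, six_frame_translate, translate

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_MIN_SCORE_FRACTION = 0.4
DEFAULT_NAME_PATTERNS = ("RAYT", "REP-associated tyrosine transposase")

# The packaged seed query is a synthetic stand-in RAYT-like protein carrying
# the family motifs; real seed proteins can be supplied as any FASTA.
_SEED_RESOURCE = "synthetic_rayt_seed.faa"


@dataclass
class MotifConfig:
    """Motif rule for RAYT validation: a histidine-pair regex and a residue
    required downstream of it."""

    hxh_pattern: str = "H.H"
    downstream_residue: str = "Y"


@dataclass
class RaytHit:
    genome_id: str
    start: int
    end: int
    strand: str
    protein: str
    score: float = 0.0
    identity_fraction: float = 0.0
    frame: Optional[int] = None
    source: str = "homology"
    motif_ok: bool = False
    motif_flags: dict = field(default_factory=dict)
    query_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit interval empty")


def load_seed_proteins(path: str | Path | None = None) -> dict[str, str]:
    """Seed RAYT query proteins from FASTA; defaults to the packaged
    synthetic stand-in."""
    if path is None:
        ref = resources.files("repatlas").joinpath("data", _SEED_RESOURCE)
        with resources.as_file(ref) as p:
            return {r.id: str(r.seq) for r in SeqIO.parse(str(p), "fasta")}
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Local alignment


def make_aligner(
    mode: str = "local",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAligner:
    """Affine-gap protein aligner: BLOSUM62, gap of length k costs
    open + k*extend (so PairwiseAligner open_gap_score = -(open+extend))."""
    aligner = PairwiseAligner(mode=mode)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    query: str,
    target: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, tuple[int, int]]:
    """Optimal local alignment score of query vs target and the aligned
    target interval (0-based half-open).  Score 0 with an empty interval
    when no positive-scoring alignment exists."""
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = make_aligner("local", gap_open, gap_extend)
    score = aligner.score(target, query)
    if score <= 0:
        return 0.0, (0, 0)
    aln = aligner.align(target, query)[0]
    blocks = aln.aligned[0]
    return float(score), (int(blocks[0][0]), int(blocks[-1][1]))


def self_score(protein: str) -> float:
    """Alignment score of a protein against itself (sum of diagonal
    substitution values)."""
    matrix = substitution_matrices.load("BLOSUM62")
    return float(sum(matrix[c, c] for c in protein))


def _alignment_identity(aln) -> float:
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    return counts.identities / aligned if aligned else 0.0


# ---------------------------------------------------------------------------
# Annotation route


def find_rayts_by_annotation(
    genome: GenomeRecord,
    features: Sequence[GeneFeature],
    name_patterns: Sequence[str] = DEFAULT_NAME_PATTERNS,
    motif_config: MotifConfig | None = None,
) -> list[RaytHit]:
    """RAYT hits from annotated CDS whose /product matches any pattern
    (case-insensitive substring)."""
    patterns = [p.lower() for p in name_patterns]
    hits = []
    for feat in features:
        if not any(p in feat.product.lower() for p in patterns):
            continue
        protein = feat.protein
        if protein is None:
            cds = genome.sequence[feat.start : feat.end]
            if feat.strand == "-":
                from .seq_core import reverse_complement

                cds = reverse_complement(cds)
            protein = translate(cds).rstrip("*")
        hit = RaytHit(
            genome_id=genome.id,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
            protein=protein,
            source="annotation",
        )
        validate_rayt(hit, motif_config)
        hits.append(hit)
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# Six-frame homology route


def _frame_to_genome(frame: int, aa_start: int, aa_end: int, length: int) -> tuple[int, int, str]:
    """Map an amino-acid interval in one reading frame back to forward-strand
    nucleotide coordinates."""
    offset = abs(frame) - 1
    nt_start = offset + 3 * aa_start
    nt_end = offset + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end, "+"
    return length - nt_end, length - nt_start, "-"


def _extend_to_orf(prot: str, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Extend an aligned amino-acid interval to the enclosing ORF.

    Start: the nearest methionine at or left of the alignment start, not
    crossing a stop.  End: through the next in-frame stop when one exists.
    """
    start = aa_start
    i = aa_start
    while i >= 0 and prot[i] != "*":
        if prot[i] == "M":
            start = i
            break
        i -= 1
    stop = prot.find("*", aa_end)
    end = stop + 1 if stop != -1 else aa_end  # include the stop codon
    return start, end


def scan_six_frames(
    genome: GenomeRecord,
    queries: dict[str, str],
    min_score: float | None = None,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    max_hits_per_frame: int = 50,
    motif_config: MotifConfig | None = None,
) -> list[RaytHit]:
    """Translated homology search: each query vs all six reading frames.

    Hits scoring at least `min_score` (default: `min_score_fraction` of the
    query self-score, length-robust where an absolute cutoff is not) are
    mapped to genomic coordinates and extended to the enclosing ORF.
    Within a frame, found regions are masked and the search repeated, so
    multiple RAYT copies are recovered.  Hits from different queries that
    overlap on the genome are merged keeping the best score.
    """
    if not queries:
        raise ValueError("at least one query protein required")
    frames = six_frame_translate(genome.sequence)
    aligner = make_aligner("local", gap_open, gap_extend)
    raw_hits: list[RaytHit] = []
    for qid, query in queries.items():
        threshold = min_score if min_score is not None else min_score_fraction * self_score(query)
        if threshold <= 0:
            raise ValueError("min_score must be positive")
        for frame, prot in frames.items():
            if len(prot) == 0:
                continue
            masked = prot
            for _ in range(max_hits_per_frame):
                score = aligner.score(masked, query)
                if score < threshold:
                    break
                aln = aligner.align(masked, query)[0]
                blocks = aln.aligned[0]
                aa_start, aa_end = int(blocks[0][0]), int(blocks[-1][1])
                orf_start, orf_end = _extend_to_orf(masked, aa_start, aa_end)
                nt_start, nt_end, strand = _frame_to_genome(
                    frame, orf_start, orf_end, genome.length
                )
                raw_hits.append(
                    RaytHit(
                        genome_id=genome.id,
                        start=nt_start,
                        end=nt_end,
                        strand=strand,
                        protein=masked[orf_start:orf_end].rstrip("*"),
                        score=float(score),
                        identity_fraction=_alignment_identity(aln),
                        frame=frame,
                        source="homology",
                        query_id=qid,
                    )
                )
                masked = masked[:aa_start] + "*" * (aa_end - aa_start) + masked[aa_end:]
    merged = _merge_overlapping(raw_hits)
    for hit in merged:
        validate_rayt(hit, motif_config)
    merged.sort(key=lambda h: h.start)
    return merged


def _merge_overlapping(hits: list[RaytHit]) -> list[RaytHit]:
    """Keep the best-scoring hit among genomically overlapping ones."""
    kept: list[RaytHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start)):
        if any(h.start < hit.end and hit.start < h.end for h in kept):
            continue
        kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Motif validation


def validate_rayt(hit: RaytHit, config: MotifConfig | None = None) -> bool:
    """Check RAYT-characteristic motifs: an H-x-H histidine pair with at
    least one tyrosine downstream of it.  Sets `motif_ok`/`motif_flags` on
    the hit and returns the verdict."""
    if not hit.protein:
        raise ValueError("hit has no protein sequence")
    config = config or MotifConfig()
    match = re.search(config.hxh_pattern, hit.protein)
    hxh = match is not None
    downstream = hxh and config.downstream_residue in hit.protein[match.end() :]
    hit.motif_flags = {"hxh": hxh, "downstream_y": bool(downstream)}
    hit.motif_ok = hxh and bool(downstream)
    return hit.motif_ok
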