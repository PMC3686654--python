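"""Synthetic bacterial genomes with planted REP/REPIN/RAYT content.

The generator emulates the data regime of the real comparative analysis:
0.1–5 Mb genomes around 60% GC, REP classes planted at tens to thousands of
perfect copies, a configurable fraction of copies arranged as REPIN inverted
doublets with short spacers, RAYT genes flanked by an inverted REP pair, and
mutational decay of a configurable fraction of copies.

Two choices make planted truth *exact* rather than probabilistic:

* decay substitutions land only on positions where the class consensus is
  concrete (A/C/G/T) and always change the base, so a decayed copy is
  guaranteed not to census as perfect;
* one guard base is forced just outside each RAYT-flanking REP copy so that
  ungapped inverted-repeat extension cannot drift past the planted element
  by chance.

All randomness flows from a single seeded numpy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .seq_core import (
    GenomeRecord,
    Gff3Record,
    base_set,
    complement_code,
    reverse_complement,
    write_fasta,
    write_gff3,
)

# Most-frequent-codon back-translation table (bacterial code); the RAYT
# detector is alignment-based, so naive back-translation is adequate.
BACK_TRANSLATION = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
    "*": "TAA",
}


@dataclass
class ClassSpec:
    consensus: str
    copies: int
    repin_fraction: float = 0.0
    spacer_range: tuple[int, int] = (20, 80)
    decay_fraction: float = 0.0
    decay_subs_per_copy: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if not self.label:
            self.label = self.consensus
        if not 0 <= self.repin_fraction <= 1:
            raise ValueError("repin_fraction outside [0,1]")
        if not 0 <= self.decay_fraction <= 1:
            raise ValueError("decay_fraction outside [0,1]")
        if self.decay_subs_per_copy < 1:
            raise ValueError("decay_subs_per_copy must be >= 1")


@dataclass
class RaytSpec:
    protein: str
    flanked_by: str  # class label
    flank_distance: int = 60
    rayt_id: str = "rayt1"
    strand: str = "+"


@dataclass
class SimConfig:
    genome_length: int = 200_000
    gc: float = 0.6
    seed: int = 0
    classes: list[ClassSpec] = field(default_factory=list)
    rayts: list[RaytSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        # 240 nt per planted interval accounts for the anti-adjacency margin
        footprint = sum(
            c.copies * (len(c.consensus) + c.spacer_range[1] + 240)
            for c in self.classes
        )
        if footprint > 0.5 * self.genome_length:
            raise ValueError("planted content would crowd the genome; enlarge it")


@dataclass
class PlantedCopy:
    copy_id: str
    class_label: str
    start: int
    strand: str
    sequence: str  # realized sequence actually present (post-decay)
    decayed: bool
    repin_partner: Optional[str] = None

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class PlantedRayt:
    rayt_id: str
    start: int
    end: int
    strand: str


@dataclass
class TruthTable:
    copies: list[PlantedCopy] = field(default_factory=list)
    rayts: list[PlantedRayt] = field(default_factory=list)

    def expected_perfect(self, label: str) -> int:
        return sum(1 for c in self.copies if c.class_label == label and not c.decayed)

    def expected_repins(self, label: str) -> int:
        """Planted doublets whose two members both remain perfect copies."""
        intact = {
            c.copy_id for c in self.copies
            if c.class_label == label and not c.decayed
        }
        return sum(
            1
            for c in self.copies
            if c.class_label == label
            and c.repin_partner
            and c.copy_id < c.repin_partner
            and c.copy_id in intact
            and c.repin_partner in intact
        )


# ---------------------------------------------------------------------------


def random_genome(length: int, gc: float, seed: int | np.random.Generator) -> GenomeRecord:
    """I.i.d. random genome with P(G)=P(C)=gc/2; deterministic given seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at = (1 - gc) / 2
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc / 2, gc / 2, at])
    return GenomeRecord(id="synthetic", sequence="".join(bases))


def realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """A concrete instance of an IUPAC consensus: degenerate positions drawn
    uniformly from their base sets."""
    out = []
    for c in consensus.upper():
        bases = sorted(base_set(c))
        out.append(bases[0] if len(bases) == 1 else bases[rng.integers(len(bases))])
    return "".join(out)


def _decay(sequence: str, consensus: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitutions at concrete consensus positions, each guaranteed to
    break the match."""
    concrete = [i for i, c in enumerate(consensus) if c in "ACGT"]
    if len(concrete) < n_subs:
        raise ValueError("more substitutions requested than concrete positions")
    positions = rng.choice(len(concrete), size=n_subs, replace=False)
    seq = list(sequence)
    for k in positions:
        i = concrete[k]
        alternatives = [b for b in "ACGT" if b != consensus[i]]
        seq[i] = alternatives[rng.integers(3)]
    return "".join(seq)


class _Placer:
    """Uniform non-overlapping interval placement with bounded retries.

    The margin between reserved intervals exceeds the default REPIN spacer
    cap, so independently planted elements can never be close enough to pair
    as a spurious doublet.
    """

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 120):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.intervals: list[tuple[int, int]] = []

    def reserve(self, span: int, max_tries: int = 200) -> int:
        for _ in range(max_tries):
            start = int(self.rng.integers(self.margin, self.length - span - self.margin))
            lo, hi = start - self.margin, start + span + self.margin
            if all(hi <= a or b <= lo for a, b in self.intervals):
                self.intervals.append((lo, hi))
                return start
        raise ValueError("genome too small for requested planted content")


def back_translate(protein: str) -> str:
    return "".join(BACK_TRANSLATION[aa] for aa in protein)


def plant(
    genome: GenomeRecord, config: SimConfig, rng: np.random.Generator
) -> tuple[GenomeRecord, TruthTable]:
    """Insert the configured RAYT cassettes and REP copies into a genome."""
    seq = list(genome.sequence)
    placer = _Placer(len(seq), rng)
    truth = TruthTable()
    class_by_label = {c.label: c for c in config.classes}

    def write_at(start: int, fragment: str) -> None:
        seq[start : start + len(fragment)] = list(fragment)

    def guard(pos: int, must_not_complement: str) -> None:
        """Force seq[pos] to break complementarity with a given base."""
        if not 0 <= pos < len(seq):
            return
        banned = complement_code(must_not_complement)
        options = [b for b in "ACGT" if b != banned]
        seq[pos] = options[rng.integers(3)]

    # RAYT cassettes: upstream REP (forward) .. CDS .. downstream inverted REP
    for rayt in config.rayts:
        cls = class_by_label.get(rayt.flanked_by)
        if cls is None:
            raise ValueError(f"RAYT flanked_by unknown class {rayt.flanked_by!r}")
        cds = back_translate(rayt.protein) + BACK_TRANSLATION["*"] \
            if not rayt.protein.endswith("*") else back_translate(rayt.protein)
        rep = realize_consensus(cls.consensus, rng)
        L = len(rep)
        span = L + rayt.flank_distance + len(cds) + rayt.flank_distance + L
        start = placer.reserve(span + 2)  # +2 for the guard bases
        up_start = start + 1
        cds_start = up_start + L + rayt.flank_distance
        down_start = cds_start + len(cds) + rayt.flank_distance
        down_rep = reverse_complement(rep)
        write_at(up_start, rep)
        write_at(cds_start, cds if rayt.strand == "+" else reverse_complement(cds))
        write_at(down_start, down_rep)
        # guards: stop inverted-repeat extension exactly at the planted copy,
        # on both the outer and the gene-facing boundaries
        guard(down_start + L, seq[up_start - 1])
        guard(up_start + L, seq[down_start - 1])
        truth.rayts.append(
            PlantedRayt(rayt.rayt_id, cds_start, cds_start + len(cds), rayt.strand)
        )
        uid = f"{rayt.rayt_id}_up"
        did = f"{rayt.rayt_id}_down"
        truth.copies.append(
            PlantedCopy(uid, cls.label, up_start, "+", rep, False, None)
        )
        truth.copies.append(
            PlantedCopy(did, cls.label, down_start, "-", down_rep, False, None)
        )

    # free-standing REP copies and REPIN doublets
    for cls in config.classes:
        L = len(cls.consensus)
        n_pairs = int(round(cls.repin_fraction * cls.copies)) // 2
        n_single = cls.copies - 2 * n_pairs
        planted: list[PlantedCopy] = []
        for k in range(n_pairs):
            spacer = int(rng.integers(cls.spacer_range[0], cls.spacer_range[1] + 1))
            rep = realize_consensus(cls.consensus, rng)
            start = placer.reserve(2 * L + spacer)
            left_id = f"{cls.label}_p{k}a"
            right_id = f"{cls.label}_p{k}b"
            left_fwd = bool(rng.integers(2))
            left_seq = rep if left_fwd else reverse_complement(rep)
            right_seq = reverse_complement(rep) if left_fwd else rep
            write_at(start, left_seq)
            write_at(start + L + spacer, right_seq)
            planted.append(
                PlantedCopy(left_id, cls.label, start, "+" if left_fwd else "-",
                            left_seq, False, right_id)
            )
            planted.append(
                PlantedCopy(right_id, cls.label, start + L + spacer,
                            "-" if left_fwd else "+", right_seq, False, left_id)
            )
        for k in range(n_single):
            rep = realize_consensus(cls.consensus, rng)
            strand = "+" if rng.integers(2) else "-"
            placed = rep if strand == "+" else reverse_complement(rep)
            start = placer.reserve(L)
            write_at(start, placed)
            planted.append(
                PlantedCopy(f"{cls.label}_s{k}", cls.label, start, strand,
                            placed, False, None)
            )
        # decay
        n_decay = int(round(cls.decay_fraction * len(planted)))
        decay_idx = rng.choice(len(planted), size=n_decay, replace=False) if n_decay else []
        for idx in decay_idx:
            copy = planted[idx]
            oriented = copy.sequence if copy.strand == "+" else reverse_complement(copy.sequence)
            decayed = _decay(oriented, cls.consensus, cls.decay_subs_per_copy, rng)
            placed = decayed if copy.strand == "+" else reverse_complement(decayed)
            write_at(copy.start, placed)
            planted[idx] = PlantedCopy(
                copy.copy_id, copy.class_label, copy.start, copy.strand,
                placed, True, copy.repin_partner,
            )
        truth.copies.extend(planted)

    new_genome = GenomeRecord(id=genome.id, sequence="".join(seq),
                              source_path=genome.source_path)
    return new_genome, truth


def simulate(config: SimConfig) -> tuple[GenomeRecord, TruthTable]:
    """random_genome + plant under one seeded generator."""
    rng = np.random.default_rng(config.seed)
    genome = random_genome(config.genome_length, config.gc, rng)
    return plant(genome, config, rng)


# ---------------------------------------------------------------------------
# Config + truth I/O


def load_config(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    classes = [
        ClassSpec(
            consensus=c["consensus"],
            copies=int(c["copies"]),
            repin_fraction=float(c.get("repin_fraction", 0.0)),
            spacer_range=tuple(c.get("spacer_range", (20, 80))),
            decay_fraction=float(c.get("decay_fraction", 0.0)),
            decay_subs_per_copy=int(c.get("decay_subs_per_copy", 1)),
            label=c.get("label", ""),
        )
        for c in raw.get("classes", [])
    ]
    rayts = [
        RaytSpec(
            protein=r["protein"],
            flanked_by=r["flanked_by"],
            flank_distance=int(r.get("flank_distance", 60)),
            rayt_id=r.get("rayt_id", f"rayt{k + 1}"),
        )
        for k, r in enumerate(raw.get("rayts", []))
    ]
    return SimConfig(
        genome_length=int(raw.get("genome_length", 200_000)),
        gc=float(raw.get("gc", 0.6)),
        seed=int(raw.get("seed", 0)),
        classes=classes,
        rayts=rayts,
    )


def emit(
    genome: GenomeRecord, truth: TruthTable, outdir: str | Path, stem: str = "synthetic"
) -> dict[str, Path]:
    """Write genome FASTA, truth TSV and truth GFF3; the TSV round-trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{stem}.fasta"
    tsv = outdir / f"{stem}.truth.tsv"
    gff = outdir / f"{stem}.truth.gff3"
    write_fasta([genome], fasta)
    rows = [
        {
            "copy_id": c.copy_id,
            "class": c.class_label,
            "start": c.start,
            "strand": c.strand,
            "sequence": c.sequence,
            "decayed": int(c.decayed),
            "repin_partner": c.repin_partner or "",
        }
        for c in truth.copies
    ]
    pd.DataFrame(
        rows, columns=["copy_id", "class", "start", "strand", "sequence",
                       "decayed", "repin_partner"]
    ).to_csv(tsv, sep="\t", index=False)
    gff_rows = [
        Gff3Record(
            seqid=genome.id, source="repatlas-sim", type="repeat_region",
            start=c.start, end=c.end, strand=c.strand,
            attributes={"ID": c.copy_id, "class": c.class_label,
                        "decayed": str(int(c.decayed))},
        )
        for c in truth.copies
    ] + [
        Gff3Record(
            seqid=genome.id, source="repatlas-sim", type="CDS",
            start=r.start, end=r.end, strand=r.strand,
            attributes={"ID": r.rayt_id},
        )
        for r in truth.rayts
    ]
    write_gff3(gff_rows, gff)
    return {"fasta": fasta, "truth_tsv": tsv, "truth_gff3": gff}


def read_truth_tsv(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    copies = [
        PlantedCopy(
            copy_id=row["copy_id"],
            class_label=row["class"],
            start=int(row["start"]),
            strand=row["strand"],
            sequence=row["sequence"],
            decayed=bool(int(row["decayed"])),
            repin_partner=row["repin_partner"] or None,
        )
        for _, row in df.iterrows()
    ]
    return TruthTable(copies=copies)
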