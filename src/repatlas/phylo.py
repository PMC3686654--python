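"""Distance-based phylogenetics for concatenated housekeeping-gene alignments.

The host phylogeny behind the REP/RAYT comparison is a Neighbor-Joining
(Saitou & Nei) tree of concatenated gyrB/rpoB/rpoD nucleotide alignments,
with bootstrap support from column resampling.  Multiple sequence alignment
itself is out of scope — inputs must be pre-aligned.

Distances: p-distance (proportion of mismatching sites) or its Jukes-Cantor
correction -(3/4)ln(1 - 4p/3).  Sites with a gap or N in either row of a
pair are excluded pairwise, not listwise.

The NJ agglomeration is deterministic: ties in the Q criterion break toward
the lexicographically smallest pair of cluster representatives (each cluster
represented by its smallest leaf label), and negative branch lengths are
clamped to zero.  Trees are dendropy objects; Newick output round-trips
through dendropy's reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

_GOOD = set("ACGT")


@dataclass
class Alignment:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def read_alignment(path: str | Path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def concatenate(gene_alignments: Sequence[Alignment], taxa: Sequence[str]) -> Alignment:
    """Row-wise concatenation over a fixed gene order; every taxon must be
    present in every gene alignment."""
    rows = []
    for taxon in taxa:
        parts = []
        for k, aln in enumerate(gene_alignments):
            if taxon not in aln.taxa:
                raise ValueError(f"taxon {taxon!r} missing from gene alignment {k}")
            parts.append(aln.row(taxon))
        rows.append("".join(parts))
    return Alignment(list(taxa), rows)


# ---------------------------------------------------------------------------
# Distances


def distance(a: str, b: str, model: str = "JC") -> float:
    """Pairwise distance between two aligned rows under the p or JC model."""
    if len(a) != len(b):
        raise ValueError("rows have unequal lengths")
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _GOOD and y in _GOOD:
            compared += 1
            if x != y:
                mismatches += 1
    if compared == 0:
        raise ValueError("zero comparable sites")
    p = mismatches / compared
    if model == "p":
        return p
    if model == "JC":
        if p >= 0.75:
            raise ValueError("saturation: p >= 0.75 has no Jukes-Cantor distance")
        return -0.75 * math.log(1 - 4 * p / 3)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not fit taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("negative distance")


def distance_matrix(alignment: Alignment, model: str = "JC") -> DistanceMatrix:
    n = len(alignment.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = distance(alignment.rows[i], alignment.rows[j], model)
    return DistanceMatrix(list(alignment.taxa), d)


# ---------------------------------------------------------------------------
# Neighbor-Joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining with deterministic tie-breaking.

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); the pair minimizing
    Q joins first, ties resolved toward the lexicographically smallest
    (representative_i, representative_j) pair.  Negative branch lengths are
    clamped to zero.  The final three clusters join at an unresolved
    (degree-3) root, i.e. the tree is unrooted.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    taxon_ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # smallest leaf label per cluster, for tie-breaking
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(name)
        nodes.append(node)
        keys.append(name)
    d = dm.values.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and best is not None and pair_key < best[1]
                ):
                    best_q = q
                    best = ((i, j), pair_key)
        (i, j), _ = best
        vi = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = max(0.0, vi)
        nj_.edge.length = max(0.0, vj)
        # distances to the new cluster
        row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([d, row])
        col = np.append(row, 0.0)
        d = np.column_stack([d, col])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        new_index = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]
    # resolve the final 3-cluster star exactly
    a, b, c = active
    root = dendropy.Node()
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, v)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def star_tree(taxa: Sequence[str]) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(list(taxa))
    root = dendropy.Node()
    for name in taxa:
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(name)
        root.add_child(leaf)
        leaf.edge.length = 0.0
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def internal_splits(tree: dendropy.Tree) -> dict:
    """Internal bipartitions as canonical frozensets of leaf labels (the
    side not containing the alphabetically first taxon), mapped to nodes."""
    all_taxa = sorted(t.label for t in tree.taxon_namespace)
    ref = all_taxa[0]
    splits = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        if ref in side:
            side = frozenset(all_taxa) - side
        splits[side] = node
    return splits


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap(
    alignment: Alignment,
    b: int = 1000,
    seed: int = 0,
    model: str = "JC",
) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap support percentages.

    `b` column resamples with replacement; each replicate yields distances
    and an NJ tree; an internal bipartition's support is the percentage of
    replicates containing it.  Replicates with a saturated or undefined
    distance are skipped and the denominator adjusted.  Deterministic for a
    given seed.
    """
    if b < 1:
        raise ValueError("need at least one bootstrap replicate")
    full_dm = distance_matrix(alignment, model)
    if np.allclose(full_dm.values, 0):
        # identical rows: no split has any signal, return the star tree
        return star_tree(sorted(alignment.taxa))
    tree = nj_tree(full_dm)
    splits = internal_splits(tree)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    cols = np.array([list(r) for r in alignment.rows])
    valid = 0
    for _ in range(b):
        idx = rng.integers(0, alignment.length, size=alignment.length)
        rows = ["".join(row) for row in cols[:, idx]]
        try:
            dm = distance_matrix(Alignment(list(alignment.taxa), rows), model)
        except ValueError:
            continue
        valid += 1
        rep_splits = internal_splits(nj_tree(dm))
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        support = 100.0 * counts[s] / valid if valid else 0.0
        node.label = str(int(round(support)))
    return tree


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: dendropy.Tree, path: Optional[str | Path] = None) -> str:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source: str | Path) -> dendropy.Tree:
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        return dendropy.Tree.get(path=str(source), schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")
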