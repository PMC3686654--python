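"""Cross-strain REP classes and RAYT orthogroups.

Per-strain REP consensi that are compatible (equal length, positions
mergeable within the degeneracy budget) collapse into one cross-strain
class.  Classes whose cognate RAYT genes are orthologous — reciprocal best
protein match plus conserved gene neighborhood (synteny) — are gathered
into orthogroups, the unit within which REP classes replace each other over
evolutionary time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .rayt_finder import make_aligner
from .rep_discovery import RepConsensus, merge_to_consensus

DEFAULT_IDENTITY_THRESHOLD = 0.6
DEFAULT_NEIGHBOR_IDENTITY = 0.7
DEFAULT_SYNTENY_DEPTH = 5


@dataclass
class RepClass:
    label: str
    consensus: RepConsensus
    member_strains: set[str] = field(default_factory=set)
    cognate_rayts: list[str] = field(default_factory=list)  # RaytContext ids


@dataclass
class OrthoGroup:
    label: str  # roman numeral
    class_labels: list[str]


@dataclass
class RaytContext:
    """A RAYT gene with up to `synteny_depth` neighboring CDS proteins per
    side, the raw material for the orthology test."""

    strain: str
    rayt_id: str
    protein: str
    upstream_neighbors: list[str] = field(default_factory=list)
    downstream_neighbors: list[str] = field(default_factory=list)

    @property
    def node(self) -> tuple[str, str]:
        return (self.strain, self.rayt_id)


# ---------------------------------------------------------------------------
# Class deduplication


def _try_merge(a: RepConsensus, b_iupac: str) -> Optional[str]:
    if len(a.iupac) != len(b_iupac):
        return None
    try:
        return merge_to_consensus([a.iupac, b_iupac])
    except ValueError:
        return None


def deduplicate_classes(
    consensi: Sequence[tuple[str, RepConsensus]],
) -> list[RepClass]:
    """Collapse per-strain (strain, consensus) pairs into cross-strain classes.

    Processing order is lexicographic by IUPAC string, so the outcome is
    independent of input order.  A consensus joins the first existing class
    it can merge with; the class consensus becomes the merged union.
    """
    ordered = sorted(consensi, key=lambda sc: (sc[1].iupac, sc[0]))
    classes: list[RepClass] = []
    for strain, cons in ordered:
        for cls in classes:
            merged = _try_merge(cls.consensus, cons.iupac)
            if merged is not None:
                cls.consensus.iupac = merged
                cls.member_strains.add(strain)
                if cons.cognate_rayt:
                    cls.cognate_rayts.append(cons.cognate_rayt)
                break
        else:
            new = RepClass(
                label=cons.label or f"class{len(classes) + 1}",
                consensus=RepConsensus(
                    label=cons.label,
                    iupac=cons.iupac,
                    structure=cons.structure,
                    architecture=cons.architecture,
                    orthogroup=cons.orthogroup,
                    cognate_rayt=cons.cognate_rayt,
                ),
                member_strains={strain},
                cognate_rayts=[cons.cognate_rayt] if cons.cognate_rayt else [],
            )
            classes.append(new)
    return classes


# ---------------------------------------------------------------------------
# RAYT orthology


def global_identity(a: str, b: str) -> float:
    """Identity fraction of the optimal global alignment (matches over
    aligned, non-gap columns)."""
    if not a or not b:
        return 0.0
    aligner = make_aligner("global")
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches
    return counts.identities / aligned if aligned else 0.0


def rayt_orthology(
    contexts: Sequence[RaytContext],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    neighbor_identity: float = DEFAULT_NEIGHBOR_IDENTITY,
) -> nx.Graph:
    """Orthology graph over RAYT genes of different strains.

    Edge iff (a) the two RAYTs are reciprocal best matches (by global
    protein identity, at least `identity_threshold`) among all RAYTs of
    their two strains, and (b) at least one pair of flanking CDS proteins on
    the same relative side reaches `neighbor_identity` — the synteny check.
    RAYTs with no neighbor context are excluded from (b) and flagged.
    """
    graph = nx.Graph()
    for ctx in contexts:
        graph.add_node(
            ctx.node,
            strain=ctx.strain,
            no_context=not (ctx.upstream_neighbors or ctx.downstream_neighbors),
        )
    by_strain: dict[str, list[RaytContext]] = {}
    for ctx in contexts:
        by_strain.setdefault(ctx.strain, []).append(ctx)
    strains = sorted(by_strain)
    for i, s1 in enumerate(strains):
        for s2 in strains[i + 1 :]:
            _add_strain_pair_edges(
                graph, by_strain[s1], by_strain[s2], identity_threshold, neighbor_identity
            )
    return graph


def _add_strain_pair_edges(graph, group1, group2, identity_threshold, neighbor_identity):
    ident = {
        (a.node, b.node): global_identity(a.protein, b.protein)
        for a in group1
        for b in group2
    }
    for a in group1:
        best_b = max(group2, key=lambda b: ident[(a.node, b.node)])
        score = ident[(a.node, best_b.node)]
        if score < identity_threshold:
            continue
        # reciprocal?
        best_a = max(group1, key=lambda x: ident[(x.node, best_b.node)])
        if best_a.node != a.node:
            continue
        if _synteny_conserved(a, best_b, neighbor_identity):
            graph.add_edge(a.node, best_b.node, identity=score)


def _synteny_conserved(a: RaytContext, b: RaytContext, threshold: float) -> bool:
    for side_a, side_b in (
        (a.upstream_neighbors, b.upstream_neighbors),
        (a.downstream_neighbors, b.downstream_neighbors),
    ):
        for p in side_a:
            for q in side_b:
                if global_identity(p, q) >= threshold:
                    return True
    return False


# ---------------------------------------------------------------------------
# Orthogroup assignment

_ROMAN = [
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def to_roman(n: int) -> str:
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def assign_orthogroups(
    classes: Sequence[RepClass], graph: nx.Graph
) -> tuple[list[OrthoGroup], dict[str, str]]:
    """Group REP classes by the orthology components of their cognate RAYTs.

    Components carrying at least two distinct classes become orthogroups,
    labeled with roman numerals in order of first appearance over the given
    class order.  Classes with no RAYT, or whose RAYTs sit in a singleton
    component, fall into the ungrouped "NO" pool.  A class whose RAYTs span
    two components is contradictory and raises.
    """
    node_component: dict = {}
    for k, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            node_component[node] = k
    class_component: dict[str, Optional[int]] = {}
    component_classes: dict[int, set[str]] = {}
    for cls in classes:
        comps = {
            node_component[r] for r in cls.cognate_rayts if r in node_component
        }
        if len(comps) > 1:
            raise ValueError(
                f"class {cls.label} linked to RAYTs in {len(comps)} different "
                "orthology components"
            )
        comp = comps.pop() if comps else None
        class_component[cls.label] = comp
        if comp is not None:
            component_classes.setdefault(comp, set()).add(cls.label)
    groups: list[OrthoGroup] = []
    assignment: dict[str, str] = {}
    comp_label: dict[int, str] = {}
    for cls in classes:
        comp = class_component[cls.label]
        if comp is None or len(component_classes.get(comp, ())) < 2:
            assignment[cls.label] = "NO"
            continue
        if comp not in comp_label:
            comp_label[comp] = to_roman(len(comp_label) + 1)
            groups.append(OrthoGroup(label=comp_label[comp], class_labels=[]))
        label = comp_label[comp]
        assignment[cls.label] = label
        next(g for g in groups if g.label == label).class_labels.append(cls.label)
    return groups, assignment
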