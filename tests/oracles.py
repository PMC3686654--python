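"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and coded from first principles —
plain dynamic programming, exhaustive enumeration, all-windows scans — and
shares no code path with the package internals it checks.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    out = []
    for c in reversed(seq.upper()):
        bases = IUPAC[c]
        comp = frozenset(COMP[b] for b in bases)
        code = next(k for k, v in IUPAC.items() if frozenset(v) == comp)
        out.append(code)
    return "".join(out)


# ---------------------------------------------------------------------------
# Local alignment: Gotoh affine-gap DP, score only


def sw_score(query: str, target: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps; a gap of length k costs
    open + k*extend.  O(nm) triple-matrix recurrence, no vectorization."""
    n, m = len(query), len(target)
    NEG = -math.inf
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (along target)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            sub = _BLOSUM62[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# REP structure: exhaustive enumeration


def enumerate_structure(seq: str, min_stem: int = 4):
    """All-combination search for the best (lead, arm_offset, stem, loop).

    Returns (lead, arm_offset, stem, loop) or None.  Best = longest stem,
    ties to smaller arm_offset then smaller loop.
    """
    seq = seq.upper()
    if len(seq) < 15:
        return None
    lead = None
    for cand in (0, 1):
        tet = seq[cand : cand + 4]
        if len(tet) == 4 and all(
            set(IUPAC[c]) <= set(t) for c, t in zip(tet, ("G", "T", "AG", "G"))
        ):
            lead = cand
            break
    if lead is None:
        return None
    candidates = []
    for off in range(4):
        for loop in range(1, 8):
            arm = lead + 4 + off
            for stem in range(min_stem, len(seq)):
                left = seq[arm : arm + stem]
                right = seq[arm + stem + loop : arm + 2 * stem + loop]
                if len(left) < stem or len(right) < stem:
                    break
                if naive_revcomp(left) == right:
                    candidates.append((stem, off, loop))
    if not candidates:
        return None
    stem, off, loop = max(candidates, key=lambda c: (c[0], -c[1], -c[2]))
    return (lead, off, stem, loop)


# ---------------------------------------------------------------------------
# Census: all-windows scan on both strands


def naive_count(genome: str, consensus: str) -> list[tuple[int, str]]:
    """Every window tested against the consensus and, unless palindromic,
    its reverse complement."""
    consensus = consensus.upper()
    k = len(consensus)
    patterns = [(consensus, "+")]
    rc = naive_revcomp(consensus)
    if rc != consensus:
        patterns.append((rc, "-"))
    out = []
    for i in range(len(genome) - k + 1):
        window = genome[i : i + k]
        for motif, strand in patterns:
            if all(
                g in "ACGT" and g in IUPAC[c] for c, g in zip(motif, window)
            ):
                out.append((i, strand))
    return sorted(out)


# ---------------------------------------------------------------------------
# Trees: random additive instances and split extraction


def random_additive_tree(rng, n_leaves: int):
    """A random unrooted binary tree with branch lengths in [0.1, 1.0].

    Returns (distance matrix as dict of dicts, set of non-trivial splits as
    frozensets of labels over the full leaf set).
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # build by sequential attachment: start from a 3-leaf star
    # adjacency: node -> list of (node, length)
    adj: dict = {}
    counter = [0]

    def new_internal():
        counter[0] += 1
        return f"int{counter[0]}"

    def add_edge(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def blen():
        return 0.1 + 0.9 * rng.random()

    center = new_internal()
    for leaf in labels[:3]:
        add_edge(center, leaf, blen())
    edges = [(center, leaf) for leaf in labels[:3]]
    for leaf in labels[3:]:
        a, b = edges[rng.integers(len(edges))]
        w = dict(adj[a])[b]
        mid = new_internal()
        adj[a] = [(x, y) for x, y in adj[a] if x != b]
        adj[b] = [(x, y) for x, y in adj[b] if x != a]
        w1 = w * (0.2 + 0.6 * rng.random())
        add_edge(a, mid, w1)
        add_edge(mid, b, w - w1)
        add_edge(mid, leaf, blen())
        edges.remove((a, b) if (a, b) in edges else (b, a))
        edges += [(a, mid), (mid, b), (mid, leaf)]
    # all-pairs path lengths by BFS/DFS from each leaf
    def dists_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen

    dmat = {a: {} for a in labels}
    for a in labels:
        da = dists_from(a)
        for b in labels:
            dmat[a][b] = da[b]
    # splits: remove each internal edge, collect leaf sides
    splits = set()
    ref = sorted(labels)[0]
    for u in adj:
        for v, _ in adj[u]:
            if u.startswith("int") and v.startswith("int") and u < v:
                side = set()
                stack2 = [u]
                seen = {u, v}
                while stack2:
                    x = stack2.pop()
                    if not x.startswith("int"):
                        side.add(x)
                        continue
                    for y, _ in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack2.append(y)
                if 2 <= len(side) <= len(labels) - 2:
                    canonical = frozenset(side) if ref not in side else frozenset(labels) - frozenset(side)
                    splits.add(canonical)
    return labels, dmat, splits
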