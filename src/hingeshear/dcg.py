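"""Dynamic contact graphs and their decomposition into elemental contact changes.

A dynamic contact graph (DCG) is a directed bipartite multigraph over the
residues of domains A and B: an edge runs A->B when the pair is in
contact in conformation 1 (a "forward" edge) and B->A when it is in
contact in conformation 2 (a "backward" edge). Any DCG decomposes into
four elemental motifs:

maintained
    the same (a, b) pair in contact in both conformations
    (one forward and one backward edge on the same pair);
exchanged-partner
    one forward and one backward edge sharing exactly one residue —
    a residue swapping partners, the sliding signature;
exchanged-pair
    one forward and one backward edge sharing no residue — the
    see-saw signature;
new
    a single unpaired edge — a contact present in only one conformation.

The counts N = (N_maint, N_exchpart, N_exchpair, N_new) are the feature
vector of the hinge/shear classifier.

Counting rule. Maintained extraction is forced by the definition; the
remaining forward-only and backward-only edges are matched one-to-one to
maximize, lexicographically, first the number of exchanged-partner
elements and then the number of exchanged-pair elements, with unmatched
edges counted as new. The exchanged-partner maximum is a
maximum-cardinality bipartite matching between forward-only and
backward-only edges (adjacent when they share exactly one residue),
solved exactly by augmenting paths. Because every leftover pair after
such a matching shares no residue (otherwise the matching could be
extended), the exchanged-pair count is simply
min(remaining forward, remaining backward); the total number of
exchanged elements is therefore matching-independent and the counts are
invariant across optimal matchings. An exhaustive-search oracle
(:func:`decompose_bruteforce`) verifies this on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .contacts import ContactSet
from .structure_io import ResidueKey

__all__ = [
    "Edge",
    "DynamicContactGraph",
    "ElementalCounts",
    "Element",
    "Decomposition",
    "build_dcg",
    "decompose",
    "decompose_bruteforce",
    "dcg_to_text",
    "dcg_from_text",
    "decomposition_report",
    "dcg_to_dot",
]

Edge = tuple[ResidueKey, ResidueKey]  # always (residue in A, residue in B)

BRUTE_FORCE_EDGE_LIMIT = 14


@dataclass
class DynamicContactGraph:
    """Directed bipartite contact-change graph of a two-conformation pair."""

    nodes_a: frozenset[ResidueKey]
    nodes_b: frozenset[ResidueKey]
    forward_edges: frozenset[Edge]  # contacts of conformation 1
    backward_edges: frozenset[Edge]  # contacts of conformation 2

    @property
    def n_edges(self) -> int:
        return len(self.forward_edges) + len(self.backward_edges)


@dataclass(frozen=True)
class ElementalCounts:
    """The 4-vector N of elemental contact-change counts."""

    n_maint: int
    n_exchpart: int
    n_exchpair: int
    n_new: int

    def __post_init__(self) -> None:
        for name in ("n_maint", "n_exchpart", "n_exchpair", "n_new"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_maint, self.n_exchpart, self.n_exchpair, self.n_new)

    @property
    def total_contacts(self) -> int:
        """Number of edges accounted for: 2*(maint+exchpart+exchpair)+new."""
        return 2 * (self.n_maint + self.n_exchpart + self.n_exchpair) + self.n_new

    def is_zero(self) -> bool:
        return self.total_contacts == 0

    def __str__(self) -> str:
        return (
            f"N = ({self.n_maint}, {self.n_exchpart}, "
            f"{self.n_exchpair}, {self.n_new})"
        )


@dataclass(frozen=True)
class Element:
    """One elemental subgraph of a decomposition.

    ``kind`` is one of maintained / exchanged-partner / exchanged-pair /
    new; ``forward`` and ``backward`` list the edges it consumes.
    """

    kind: str
    forward: tuple[Edge, ...]
    backward: tuple[Edge, ...]


@dataclass
class Decomposition:
    counts: ElementalCounts
    elements: list[Element] = field(default_factory=list)


def build_dcg(contacts_1: ContactSet, contacts_2: ContactSet) -> DynamicContactGraph:
    """Build the DCG from the contact sets of the two conformations."""
    fwd = frozenset((p.a, p.b) for p in contacts_1.pairs)
    bwd = frozenset((p.a, p.b) for p in contacts_2.pairs)
    nodes_a = frozenset(a for a, _ in fwd | bwd)
    nodes_b = frozenset(b for _, b in fwd | bwd)
    return DynamicContactGraph(nodes_a, nodes_b, fwd, bwd)


def _share_exactly_one(e: Edge, f: Edge) -> bool:
    return (e[0] == f[0]) != (e[1] == f[1])


def _kuhn_matching(
    fo: Sequence[Edge], bo: Sequence[Edge]
) -> dict[int, int]:
    """Maximum-cardinality matching fo-index -> bo-index via augmenting paths.

    Deterministic: vertices are processed in the (sorted) order given.
    """
    adj: list[list[int]] = [
        [j for j, b in enumerate(bo) if _share_exactly_one(f, b)] for f in fo
    ]
    match_b: list[int | None] = [None] * len(bo)

    def try_augment(i: int, visited: set[int]) -> bool:
        for j in adj[i]:
            if j in visited:
                continue
            visited.add(j)
            if match_b[j] is None or try_augment(match_b[j], visited):
                match_b[j] = i
                return True
        return False

    for i in range(len(fo)):
        try_augment(i, set())
    return {i: j for j, i in enumerate(match_b) if i is not None}


def decompose(graph: DynamicContactGraph) -> Decomposition:
    """Canonical decomposition of a DCG into elemental contact changes.

    Deterministic: edges are considered in residue-key order, so the same
    graph always yields the same assignments. The counts satisfy edge
    conservation, |F| + |B| = 2*(N_maint + N_exchpart + N_exchpair) + N_new.
    """
    maintained = sorted(graph.forward_edges & graph.backward_edges)
    fo = sorted(graph.forward_edges - graph.backward_edges)
    bo = sorted(graph.backward_edges - graph.forward_edges)

    elements = [Element("maintained", (e,), (e,)) for e in maintained]

    match = _kuhn_matching(fo, bo)
    matched_b = set(match.values())
    for i in sorted(match):
        elements.append(Element("exchanged-partner", (fo[i],), (bo[match[i]],)))

    left_f = [e for i, e in enumerate(fo) if i not in match]
    left_b = [e for j, e in enumerate(bo) if j not in matched_b]
    n_pair = min(len(left_f), len(left_b))
    for f, b in zip(left_f[:n_pair], left_b[:n_pair]):
        elements.append(Element("exchanged-pair", (f,), (b,)))
    for f in left_f[n_pair:]:
        elements.append(Element("new", (f,), ()))
    for b in left_b[n_pair:]:
        elements.append(Element("new", (), (b,)))

    counts = ElementalCounts(
        n_maint=len(maintained),
        n_exchpart=len(match),
        n_exchpair=n_pair,
        n_new=len(left_f) + len(left_b) - 2 * n_pair,
    )
    assert counts.total_contacts == graph.n_edges
    return Decomposition(counts, elements)


def decompose_bruteforce(graph: DynamicContactGraph) -> Decomposition:
    """Exhaustive-search decomposition oracle for small graphs.

    Enumerates every complete set of one-to-one pairings between the
    forward-only and backward-only edges and returns the optimum under
    the same lexicographic priority (maximize exchanged-partner, then
    exchanged-pair). Intended for testing only; refuses graphs with more
    than ~14 edges.
    """
    if graph.n_edges > BRUTE_FORCE_EDGE_LIMIT:
        raise ValueError(
            f"graph has {graph.n_edges} edges; the exhaustive oracle is "
            f"limited to {BRUTE_FORCE_EDGE_LIMIT} — use decompose() instead"
        )
    maintained = sorted(graph.forward_edges & graph.backward_edges)
    fo = sorted(graph.forward_edges - graph.backward_edges)
    bo = sorted(graph.backward_edges - graph.forward_edges)

    best: tuple[int, int] | None = None
    best_pairing: list[tuple[int, int | None]] | None = None

    def search(
        i: int,
        used_b: set[int],
        pairing: list[tuple[int, int | None]],
        n_part: int,
        n_any: int,
    ) -> None:
        nonlocal best, best_pairing
        if i == len(fo):
            n_cross = n_any - n_part
            # leftover backward edges may still pair with nothing; pairing
            # leftovers among themselves is impossible, so score is final
            score = (n_part, n_cross)
            if best is None or score > best:
                best = score
                best_pairing = list(pairing)
            return
        # bound: even pairing every remaining edge as exchanged-partner
        remaining = len(fo) - i
        if best is not None and (n_part + remaining, len(bo)) < best:
            return
        for j in range(len(bo)):
            if j in used_b:
                continue
            used_b.add(j)
            pairing.append((i, j))
            search(
                i + 1,
                used_b,
                pairing,
                n_part + (1 if _share_exactly_one(fo[i], bo[j]) else 0),
                n_any + 1,
            )
            pairing.pop()
            used_b.remove(j)
        pairing.append((i, None))
        search(i + 1, used_b, pairing, n_part, n_any)
        pairing.pop()

    search(0, set(), [], 0, 0)
    assert best is not None and best_pairing is not None

    elements = [Element("maintained", (e,), (e,)) for e in maintained]
    used_b: set[int] = set()
    n_part = n_pair = 0
    for i, j in best_pairing:
        if j is None:
            elements.append(Element("new", (fo[i],), ()))
            continue
        used_b.add(j)
        if _share_exactly_one(fo[i], bo[j]):
            elements.append(Element("exchanged-partner", (fo[i],), (bo[j],)))
            n_part += 1
        else:
            elements.append(Element("exchanged-pair", (fo[i],), (bo[j],)))
            n_pair += 1
    for j, b in enumerate(bo):
        if j not in used_b:
            elements.append(Element("new", (), (b,)))

    counts = ElementalCounts(
        n_maint=len(maintained),
        n_exchpart=n_part,
        n_exchpair=n_pair,
        n_new=(len(fo) + len(bo)) - 2 * (n_part + n_pair),
    )
    assert counts.total_contacts == graph.n_edges
    return Decomposition(counts, elements)


# ---------------------------------------------------------------- serialization


def dcg_to_text(graph: DynamicContactGraph) -> str:
    """Edge-list serialization: 'F a b' / 'B a b' lines, sorted."""
    lines = [f"F {a} {b}" for a, b in sorted(graph.forward_edges)]
    lines += [f"B {a} {b}" for a, b in sorted(graph.backward_edges)]
    return "\n".join(lines) + ("\n" if lines else "")


def dcg_from_text(text: str) -> DynamicContactGraph:
    fwd: set[Edge] = set()
    bwd: set[Edge] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tag, a_txt, b_txt = line.split()
        edge = (ResidueKey.parse(a_txt), ResidueKey.parse(b_txt))
        if tag == "F":
            fwd.add(edge)
        elif tag == "B":
            bwd.add(edge)
        else:
            raise ValueError(f"unknown edge tag {tag!r}")
    nodes_a = frozenset(a for a, _ in fwd | bwd)
    nodes_b = frozenset(b for _, b in fwd | bwd)
    return DynamicContactGraph(nodes_a, nodes_b, frozenset(fwd), frozenset(bwd))


def decomposition_report(decomp: Decomposition) -> str:
    """Tab-separated element listing plus the N summary line."""
    lines = []
    for el in decomp.elements:
        edges = [f"F:{a}-{b}" for a, b in el.forward]
        edges += [f"B:{a}-{b}" for a, b in el.backward]
        lines.append(f"{el.kind}\t{' '.join(edges)}")
    lines.append(str(decomp.counts))
    return "\n".join(lines) + "\n"


def dcg_to_dot(graph: DynamicContactGraph) -> str:
    """Graphviz DOT export (filled squares = domain A, open = domain B)."""
    lines = ["digraph DCG {", "  rankdir=LR;", "  node [shape=box];"]
    for a in sorted(graph.nodes_a):
        lines.append(f'  "A_{a}" [label="{a}", style=filled, fillcolor=black, fontcolor=white];')
    for b in sorted(graph.nodes_b):
        lines.append(f'  "B_{b}" [label="{b}"];')
    for a, b in sorted(graph.forward_edges):
        lines.append(f'  "A_{a}" -> "B_{b}";')
    for a, b in sorted(graph.backward_edges):
        lines.append(f'  "B_{b}" -> "A_{a}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
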