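"""The contig connection graph: a bidirected string graph over contigs.

Nodes are contigs; edges are exact suffix/prefix overlaps between oriented
contigs, so every edge can be traversed equally from the reverse-complement
direction. Long-range paired-end links (Plinks) with an estimated gap
distance annotate the graph for scaffolding but do not participate in
partitioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .formats import PairedAlignment, revcomp
from .mixture import MixtureModel, fit_mixture

log = logging.getLogger(__name__)

FLIP = {"+": "-", "-": "+"}


@dataclass
class Contig:
    id: str
    sequence: str
    depth: float = 0.0
    source: str = "meta-O"

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError(f"contig {self.id}: negative depth")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def oriented(self, orient: str) -> str:
        return self.sequence if orient == "+" else revcomp(self.sequence)


@dataclass(frozen=True)
class OverlapEdge:
    from_id: str
    from_orient: str
    to_id: str
    to_orient: str
    overlap_len: int
    circular: bool = False

    def mirror(self) -> "OverlapEdge":
        return OverlapEdge(
            self.to_id, FLIP[self.to_orient],
            self.from_id, FLIP[self.from_orient],
            self.overlap_len, self.circular,
        )

    def canonical(self) -> "OverlapEdge":
        m = self.mirror()
        a = (self.from_id, self.from_orient, self.to_id, self.to_orient)
        b = (m.from_id, m.from_orient, m.to_id, m.to_orient)
        return self if a <= b else m


@dataclass(frozen=True)
class PLink:
    a_id: str
    a_orient: str
    b_id: str
    b_orient: str
    distance_mean: float
    support: int

    def mirror(self) -> "PLink":
        return PLink(
            self.b_id, FLIP[self.b_orient],
            self.a_id, FLIP[self.a_orient],
            self.distance_mean, self.support,
        )


class ContigConnectionGraph:
    """Bidirected overlap graph with optional Plink annotations.

    ``out[(id, orient)]`` lists ``(to_id, to_orient, overlap_len)`` steps:
    traversing ``id`` in ``orient`` can be followed by ``to_id`` in
    ``to_orient`` with the stated exact overlap.
    """

    def __init__(self, contigs: dict | None = None):
        self.contigs: dict[str, Contig] = dict(contigs or {})
        self.edges: set[OverlapEdge] = set()
        self.plinks: set[PLink] = set()
        self.out: dict[tuple, list] = {}

    def add_edge(self, edge: OverlapEdge) -> None:
        edge = edge.canonical()
        if edge in self.edges:
            return
        if edge.from_id not in self.contigs or edge.to_id not in self.contigs:
            raise KeyError(f"edge endpoints missing from graph: {edge}")
        self.edges.add(edge)
        for e in (edge, edge.mirror()):
            self.out.setdefault((e.from_id, e.from_orient), []).append(
                (e.to_id, e.to_orient, e.overlap_len)
            )
            # keep adjacency deterministic
            self.out[(e.from_id, e.from_orient)].sort()

    def remove_edge(self, edge: OverlapEdge) -> None:
        edge = edge.canonical()
        if edge not in self.edges:
            return
        self.edges.discard(edge)
        for e in (edge, edge.mirror()):
            lst = self.out.get((e.from_id, e.from_orient), [])
            step = (e.to_id, e.to_orient, e.overlap_len)
            if step in lst:
                lst.remove(step)

    def out_edges(self, cid: str, orient: str) -> list:
        return list(self.out.get((cid, orient), []))

    def degree(self, cid: str) -> int:
        return len(self.out.get((cid, "+"), [])) + len(self.out.get((cid, "-"), []))

    def add_plink(self, plink: PLink) -> None:
        m = plink.mirror()
        a = (plink.a_id, plink.a_orient, plink.b_id, plink.b_orient)
        b = (m.a_id, m.a_orient, m.b_id, m.b_orient)
        self.plinks.add(plink if a <= b else m)


def _overlap_lengths(s: str, t: str, min_overlap: int, longest_only: bool = True):
    """Lengths l >= min_overlap with s[-l:] == t[:l].

    Candidate lengths are located by scanning for occurrences of t's
    min_overlap-prefix inside s (C-speed find), then verified exactly.
    """
    pat = t[:min_overlap]
    lmax = min(len(s), len(t))
    hits = []
    p = s.find(pat)
    while p != -1:
        l = len(s) - p
        if min_overlap <= l <= lmax and s[p:] == t[:l]:
            hits.append(l)
        p = s.find(pat, p + 1)
    hits.sort(reverse=True)
    return hits[:1] if longest_only else hits


def build_ccg(contigs, min_overlap: int = 40) -> ContigConnectionGraph:
    """Build the bidirected overlap graph from contigs.

    An edge is created for the longest exact suffix/prefix match of length
    >= min_overlap for each of the four orientation pairings of each contig
    pair. Self-overlaps are allowed only as + to + (circular contig) and are
    flagged on the edge.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_id = {}
    for c in contigs:
        if c.id in by_id:
            raise ValueError(f"duplicate contig id {c.id!r}")
        by_id[c.id] = c
    graph = ContigConnectionGraph(by_id)

    oriented = {}
    prefix_index: dict[str, list] = {}
    for cid, c in by_id.items():
        if c.length < min_overlap:
            continue
        for o in "+-":
            s = c.oriented(o)
            oriented[(cid, o)] = s
            prefix_index.setdefault(s[:min_overlap], []).append((cid, o))

    for (cid, o), s in oriented.items():
        for did, od in prefix_index.get(s[-min_overlap:], ()):
            if cid == did:
                if not (o == "+" and od == "+"):
                    continue  # self-overlap only as + to +
                t = oriented[(did, od)]
                for l in _overlap_lengths(s, t, min_overlap, longest_only=False):
                    if l < len(s):  # full self-identity is not an overlap
                        graph.add_edge(OverlapEdge(cid, o, did, od, l, circular=True))
                        break
                continue
            t = oriented[(did, od)]
            for l in _overlap_lengths(s, t, min_overlap):
                graph.add_edge(OverlapEdge(cid, o, did, od, l))
                break
    return graph


def compute_depths(graph: ContigConnectionGraph, alignments) -> ContigConnectionGraph:
    """Set contig depths to total aligned bases / contig length."""
    totals = {cid: 0 for cid in graph.contigs}
    for a in alignments:
        for cid, alen in ((a.contig_a, a.aligned_len_a), (a.contig_b, a.aligned_len_b)):
            if cid not in totals:
                log.warning("alignment to unknown contig %s skipped", cid)
                continue
            totals[cid] += alen
    for cid, total in totals.items():
        graph.contigs[cid].depth = total / graph.contigs[cid].length
    return graph


def _innie_distance(a: PairedAlignment) -> float | None:
    """Outer span of an innie pair mapped to a single contig, else None."""
    if a.contig_a != a.contig_b or a.orient_a == a.orient_b:
        return None
    if a.orient_a == "+":
        left, right = (a.pos_a, a.pos_b + a.aligned_len_b)
    else:
        left, right = (a.pos_b, a.pos_a + a.aligned_len_a)
    if right <= left:
        return None
    return float(right - left)


def estimate_insert_size(
    alignments,
    sd_floor: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> MixtureModel:
    """Estimate the insert-size distribution from same-contig innie pairs.

    A Gaussian mixture (K chosen among 1..3 by BIC) is fitted by EM; the
    dominant (max-weight) component is the library insert size.
    """
    distances = [d for a in alignments if (d := _innie_distance(a)) is not None]
    if len(distances) < 50:
        raise ValueError(
            f"only {len(distances)} usable same-contig pairs (< 50); "
            "configure the insert size explicitly instead"
        )
    return fit_mixture(distances, sd_floor=sd_floor, max_iter=max_iter, tol=tol)


def add_plinks(
    graph: ContigConnectionGraph,
    alignments,
    model: MixtureModel,
    min_support: int = 3,
) -> ContigConnectionGraph:
    """Create Plinks from read pairs whose mates map to different contigs.

    The per-pair gap estimate is insert mean minus the two mate tail lengths
    (bases from each mate to the contig end the fragment exits through).
    """
    insert_mean = model.dominant[1]
    groups: dict[tuple, list] = {}
    for a in alignments:
        if a.contig_a == a.contig_b:
            continue
        if a.contig_a not in graph.contigs or a.contig_b not in graph.contigs:
            continue
        ca, cb = graph.contigs[a.contig_a], graph.contigs[a.contig_b]
        # fragment exits contig A through the end mate A points at
        oa = a.orient_a
        tail_a = ca.length - a.pos_a if oa == "+" else a.pos_a + a.aligned_len_a
        # fragment enters contig B against mate B's orientation (FR library)
        ob = FLIP[a.orient_b]
        tail_b = a.pos_b + a.aligned_len_b if ob == "+" else cb.length - a.pos_b
        dist = insert_mean - tail_a - tail_b
        key = (a.contig_a, oa, a.contig_b, ob)
        mirror = (a.contig_b, FLIP[ob], a.contig_a, FLIP[oa])
        groups.setdefault(min(key, mirror), []).append(
            dist if key <= mirror else dist
        )
    for (aid, oa, bid, ob), dists in sorted(groups.items()):
        if len(dists) < min_support:
            continue
        graph.add_plink(
            PLink(aid, oa, bid, ob, sum(dists) / len(dists), len(dists))
        )
    return graph


@dataclass
class Partition:
    component_of: dict
    removed_edges: set


def _reachable_within(graph, start_step, w_conv: int) -> set:
    """Contig ids reachable following one outward edge, with total appended
    length (node length minus overlap at each step) <= w_conv."""
    best: dict[tuple, int] = {}
    nid, no, ol = start_step
    first_cost = max(graph.contigs[nid].length - ol, 0)
    if first_cost > w_conv:
        return set()
    stack = [((nid, no), first_cost)]
    best[(nid, no)] = first_cost
    reached = {nid}
    while stack:
        (cid, o), cost = stack.pop()
        if best.get((cid, o), 1 << 60) < cost:
            continue
        for tid, to, tol in graph.out_edges(cid, o):
            ncost = cost + max(graph.contigs[tid].length - tol, 0)
            if ncost <= w_conv and ncost < best.get((tid, to), 1 << 60):
                best[(tid, to)] = ncost
                reached.add(tid)
                stack.append(((tid, to), ncost))
    return reached


def partition_ccg(
    graph: ContigConnectionGraph,
    w_conv: int = 400,
    strict_gt2: bool = False,
) -> Partition:
    """Split the graph at ambiguous junctions and return its components.

    A node side with out-degree at the trigger (>= 2, or > 2 when
    ``strict_gt2``) keeps its outward edges only if some node is reachable
    from every outward edge within ``w_conv`` appended bases; otherwise all
    outward edges of that side are removed. Repeats to a fixpoint, then
    components are the connected components of the remaining edges.
    """
    trigger = 3 if strict_gt2 else 2
    removed: set[OverlapEdge] = set()
    changed = True
    while changed:
        changed = False
        for cid in sorted(graph.contigs):
            for o in "+-":
                steps = graph.out_edges(cid, o)
                if len(steps) < trigger:
                    continue
                sets = [_reachable_within(graph, s, w_conv) - {cid} for s in steps]
                common = set.intersection(*sets) if sets else set()
                if not common:
                    for tid, to, tol in steps:
                        e = OverlapEdge(cid, o, tid, to, tol).canonical()
                        removed.add(e)
                        graph.remove_edge(e)
                    changed = True

    # connected components of the remainder (orientation-blind)
    parent = {cid: cid for cid in graph.contigs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in graph.edges:
        ra, rb = find(e.from_id), find(e.to_id)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    component_of = {}
    labels = {}
    for cid in sorted(graph.contigs):
        root = find(cid)
        labels.setdefault(root, f"comp{len(labels):04d}")
        component_of[cid] = labels[root]
    return Partition(component_of, removed)
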