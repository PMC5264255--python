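"""Three-step recovery of a target genome from the metagenome graph.

Starting from a partial genome bin, the *increase* step recovers candidate
target contigs with an SVM on codon-usage signatures, the *decrease* step
filters them with a Gaussian-mixture model of seed-contig sequencing depth,
and the *connection* step walks the contig connection graph between the
accepted landmarks, simplifies the resulting target graph (tips, bubbles)
and emits scaffolds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .binning import GenomeBin, tnf_profile, _rank_vector
from .formats import revcomp
from .graph import FLIP, ContigConnectionGraph, OverlapEdge
from .kmers import KmerIndex, covered_fraction
from .mixture import MixtureModel, fit_mixture

log = logging.getLogger(__name__)

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_STOPS = {48, 50, 56}  # TAA, TAG, TGA
_ATG = 14


@dataclass
class CodonUsageVector:
    values: np.ndarray  # 64 triplet frequencies, sum 1
    contig_id: str
    orf_based: bool


@dataclass
class TrainingSets:
    positive_ids: set
    negative_ids: set
    test_ids: set


def _codon_codes(seq: str) -> np.ndarray:
    codes = np.fromiter((_BASE.get(b, 4) for b in seq), dtype=np.int64, count=len(seq))
    m = len(codes) // 3
    if m == 0:
        return np.empty(0, dtype=np.int64)
    tri = codes[: 3 * m].reshape(m, 3)
    vals = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    vals[(tri >= 4).any(axis=1)] = -1  # codons touching N are breaks
    return vals


def _longest_orf(seq: str, min_orf: int = 300):
    """(codon code array of the best ORF, bp length) or (None, 0).

    An ORF runs from an ATG to the next in-frame stop (stop included),
    scanned over all six frames.
    """
    best = (None, 0)
    for strand in (seq, revcomp(seq)):
        for frame in range(3):
            codons = _codon_codes(strand[frame:])
            if codons.size == 0:
                continue
            boundaries = np.flatnonzero((codons == -1) | np.isin(codons, list(_STOPS)))
            prev = -1
            for b in boundaries.tolist():
                if codons[b] == -1:
                    prev = b
                    continue
                seg = codons[prev + 1 : b]
                starts = np.flatnonzero(seg == _ATG)
                if starts.size:
                    a = prev + 1 + int(starts[0])
                    length_bp = (b - a + 1) * 3
                    if length_bp > best[1]:
                        best = (codons[a : b + 1], length_bp)
                prev = b
    if best[1] >= min_orf:
        return best
    return (None, 0)


def codon_usage(
    sequence: str, contig_id: str = "", min_len: int = 300, orf_frame: bool = False
):
    """Codon-usage feature vector, or None for contigs below ``min_len``.

    Unannotated metagenome contigs carry no reliable reading frame, so the
    default profile is overlapping triplet frequencies over the whole
    contig (frame-free, uses every base). With ``orf_frame=True`` the frame
    is taken from the longest ORF of at least 300 bp over six frames
    (non-overlapping codons; flagged ``orf_based=True``), falling back to
    the frame-free profile when no such ORF exists.
    """
    if len(sequence) < min_len:
        return None
    if orf_frame:
        orf, _ = _longest_orf(sequence)
        if orf is not None:
            counts = np.bincount(orf[orf >= 0], minlength=64).astype(float)
            return CodonUsageVector(counts / counts.sum(), contig_id, True)
    codes = np.fromiter((_BASE.get(b, 4) for b in sequence), dtype=np.int64)
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4)
    tri = (c0 * 16 + c1 * 4 + c2)[valid]
    if tri.size == 0:
        return None
    counts = np.bincount(tri, minlength=64).astype(float)
    return CodonUsageVector(counts / counts.sum(), contig_id, False)


def build_training_sets(
    bin_sequences: dict,
    meta_o,
    min_contig: int = 300,
    min_positive: int = 5,
    negative_rule: str = "mean2sd",
) -> TrainingSets:
    """Split meta-O contigs into positive / negative / test sets.

    Positives are the bin members. The intra-bin footrule-distance
    distribution (mean mu, sd sigma over pairwise TNF distances of bin
    members >= 1 kb) defines the negative rule: a contig whose mean distance
    to the bin exceeds mu + 2 sigma is negative, the remainder is the test
    set. ``negative_rule='literal'`` uses d > 2 sigma instead.
    """
    large = {cid: s for cid, s in bin_sequences.items() if len(s) >= 1000}
    if len(large) < min_positive:
        raise ValueError(
            f"bin has {len(large)} members >= 1 kb (< {min_positive}); "
            "provide more seed sequence"
        )
    # distance statistics over all usable members: short members contribute
    # their genuine TNF noise, which keeps the negative cut realistic
    usable = {cid: s for cid, s in bin_sequences.items() if len(s) >= min_contig}
    ranks = {cid: _rank_vector(tnf_profile(s, cid).values) for cid, s in sorted(usable.items())}
    ids = sorted(ranks)
    mat = np.vstack([ranks[i] for i in ids]).astype(float)
    dists = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dists.append(np.abs(mat[i] - mat[j]).sum())
    mu_in = float(np.mean(dists))
    sd_in = float(np.std(dists))
    cut = mu_in + 2.0 * sd_in if negative_rule == "mean2sd" else 2.0 * sd_in

    positives = set(bin_sequences)
    negatives, test = set(), set()
    for c in meta_o:
        if c.id in positives or c.length < min_contig:
            continue
        r = _rank_vector(tnf_profile(c.sequence, c.id).values).astype(float)
        d = float(np.abs(mat - r).sum(axis=1).mean())
        (negatives if d > cut else test).add(c.id)
    return TrainingSets(positives, negatives, test)


def svm_increase(
    train: TrainingSets,
    features: dict,
    seed: int = 0,
    c: float = 10.0,
    gamma="scale",
) -> list:
    """Predict candidate target contigs among the test set.

    A soft-margin RBF SVM is trained on standardized codon-usage vectors of
    the positive vs negative sets; returns test contigs predicted positive,
    sorted, deterministic for a given seed.
    """
    pos = sorted(i for i in train.positive_ids if i in features)
    neg = sorted(i for i in train.negative_ids if i in features)
    test = sorted(i for i in train.test_ids if i in features)
    if len(pos) < 5 or len(neg) < 5:
        raise ValueError(
            f"class starvation: {len(pos)} positives / {len(neg)} negatives with features"
        )
    x = np.vstack([features[i].values for i in pos + neg])
    y = np.array([1] * len(pos) + [0] * len(neg))
    scaler = StandardScaler().fit(x)
    clf = SVC(C=c, gamma=gamma, kernel="rbf", class_weight="balanced", random_state=seed)
    clf.fit(scaler.transform(x), y)
    if not test:
        return []
    xt = scaler.transform(np.vstack([features[i].values for i in test]))
    pred = clf.predict(xt)
    return [i for i, p in zip(test, pred) if p == 1]


def seed_contigs(
    bin_sequences: dict,
    meta_o,
    k: int = 31,
    coverage: float = 0.9,
) -> set:
    """Meta-O contigs covered by the bin's k-mers, the depth reference set.

    Contigs of at least 300 bp qualify at >= ``coverage`` fraction covered;
    shorter contigs must be fully covered — on a short contig even a single
    unmatched window is a genuine divergence signal, not an edge effect.
    """
    index = KmerIndex(dict(sorted(bin_sequences.items())), k=k)
    seeds = set()
    for c in meta_o:
        if c.length < k:
            continue
        frac = covered_fraction(c.sequence, index)
        if (c.length >= 300 and frac >= coverage) or frac >= 1.0:
            seeds.add(c.id)
    if not seeds:
        raise ValueError("no seed contigs: bin cannot seed a depth model")
    return seeds


@dataclass
class DepthModel:
    components: list  # (weight, mean, sd)
    dominant_index: int

    @property
    def mu(self) -> float:
        return self.components[self.dominant_index][1]

    @property
    def sigma(self) -> float:
        return self.components[self.dominant_index][2]


def fit_depth_model(
    seeds,
    depths: dict,
    lengths: dict,
    sd_floor: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DepthModel:
    """Length-weighted Gaussian-mixture fit of seed sequencing depths.

    The representative (dominant) component is the lowest-mean component
    among those carrying substantial weight (>= 0.25): sequence shared with
    other genomes or repeats only ever inflates depth, so the target
    genome's intrinsic depth is the lowest substantial mode, not necessarily
    the heaviest one.
    """
    seeds = sorted(seeds)
    if len(seeds) < 10:
        raise ValueError(f"only {len(seeds)} seeds (< 10); cannot fit a depth model")
    x = [depths[s] for s in seeds]
    w = [float(lengths[s]) for s in seeds]
    fit = fit_mixture(x, weights=w, sd_floor=sd_floor, max_iter=max_iter, tol=tol)
    substantial = [i for i, (wt, _, _) in enumerate(fit.components) if wt >= 0.25]
    if substantial:
        dom = min(substantial, key=lambda i: fit.components[i][1])
    else:
        dom = fit.dominant_index
    return DepthModel(fit.components, dom)


def depth_decrease(candidates, depths: dict, model: DepthModel, n_sd: float = 2.0):
    """Keep candidates within ``n_sd`` standard deviations of the model mean."""
    kept = sorted(
        c for c in candidates if abs(depths[c] - model.mu) <= n_sd * model.sigma
    )
    return kept


# --------------------------------------------------------------------------
# Connection step


class TargetContigGraph(ContigConnectionGraph):
    """Landmark-annotated subgraph of the contig connection graph."""

    def __init__(self, contigs=None):
        super().__init__(contigs)
        self.landmarks: set = set()
        self.removed_walks: list = []  # (bubble_id, walk node list, mean depth)

    def remove_node(self, cid: str) -> None:
        for e in [e for e in self.edges if cid in (e.from_id, e.to_id)]:
            self.remove_edge(e)
        self.contigs.pop(cid, None)
        self.out.pop((cid, "+"), None)
        self.out.pop((cid, "-"), None)


def _bounded_distance_map(graph, cid, step_limit, span_limit):
    """Pareto (edge count, appended span) frontier per oriented state
    reachable from either side of a landmark node."""
    pareto: dict[tuple, list] = {}
    best_span: dict[tuple, float] = {(cid, "+"): 0.0, (cid, "-"): 0.0}
    frontier = {(cid, "+"): 0.0, (cid, "-"): 0.0}
    for e in range(1, step_limit + 1):
        nxt: dict[tuple, float] = {}
        for (nid, o), span in frontier.items():
            for tid, to, tol in graph.out_edges(nid, o):
                nspan = span + max(graph.contigs[tid].length - tol, 0)
                if nspan > span_limit:
                    continue
                state = (tid, to)
                if nspan >= best_span.get(state, float("inf")):
                    continue
                cur = nxt.get(state)
                if cur is None or nspan < cur:
                    nxt[state] = nspan
        for state, span in nxt.items():
            best_span[state] = span
            pareto.setdefault(state, []).append((e, span))
        frontier = nxt
        if not frontier:
            break
    return pareto


def _pairwise_feasible(entries, step_limit, span_limit):
    """True if two entries from distinct landmarks combine within bounds.

    entries: list of (landmark, edges, span).
    """
    entries = sorted(entries, key=lambda t: t[1])
    # prefix minima of span over entries with edges <= bound, tracking the
    # best and second-best from distinct landmarks
    best: list = []  # running (span, landmark) best/second-best
    run = []
    b1 = (float("inf"), None)
    b2 = (float("inf"), None)
    for lm, e, s in entries:
        if s < b1[0]:
            if lm != b1[1]:
                b2 = b1
            b1 = (s, lm)
        elif s < b2[0] and lm != b1[1]:
            b2 = (s, lm)
        run.append((e, b1, b2))
    import bisect

    edges_list = [r[0] for r in run]
    for lm, e, s in entries:
        limit = step_limit - e
        idx = bisect.bisect_right(edges_list, limit) - 1
        if idx < 0:
            continue
        _, b1i, b2i = run[idx]
        partner = b1i if b1i[1] != lm else b2i
        if partner[1] is not None and s + partner[0] <= span_limit:
            return True
    return False


def connect_landmarks(
    ccg: ContigConnectionGraph,
    landmarks,
    step_limit: int = 30,
    span_limit: int = 15000,
) -> TargetContigGraph:
    """Recover every node lying on a bounded path between two landmarks.

    Bounded breadth-first maps are computed from each landmark; a node is
    admitted when forward and backward bounds from two distinct landmarks
    combine within the step and span limits. Landmarks themselves are always
    admitted.
    """
    landmarks = sorted(set(landmarks))
    missing = [l for l in landmarks if l not in ccg.contigs]
    if missing:
        raise KeyError(f"landmarks not in graph: {missing[:5]}")
    state_entries: dict[tuple, list] = {}
    for lm in landmarks:
        pmap = _bounded_distance_map(ccg, lm, step_limit, span_limit)
        for state, plist in pmap.items():
            for e, s in plist:
                state_entries.setdefault(state, []).append((lm, e, s))

    admitted = set(landmarks)
    lmset = set(landmarks)
    for (nid, o), entries in state_entries.items():
        if nid in admitted:
            continue
        flip_entries = state_entries.get((nid, FLIP[o]), [])
        combined = entries + flip_entries
        # quick accept: the node is itself reachable from two landmarks whose
        # forward/backward bounds meet here
        if _pairwise_feasible(combined, step_limit, span_limit):
            admitted.add(nid)

    tg = TargetContigGraph({cid: ccg.contigs[cid] for cid in sorted(admitted)})
    tg.landmarks = lmset
    for e in ccg.edges:
        if e.from_id in admitted and e.to_id in admitted:
            tg.add_edge(e)
    return tg


def trim_tips(
    tg: TargetContigGraph, max_tip_nodes: int = 3, max_tip_len: int = 1000
) -> TargetContigGraph:
    """Remove short dead-end chains that carry no landmark, to a fixpoint."""
    changed = True
    while changed:
        changed = False
        for cid in sorted(tg.contigs):
            dplus = len(tg.out_edges(cid, "+"))
            dminus = len(tg.out_edges(cid, "-"))
            if min(dplus, dminus) != 0 or max(dplus, dminus) == 0:
                continue  # not a dead end (or isolated)
            # walk inwards from the dead end
            o = "+" if dplus else "-"
            chain = [cid]
            total = tg.contigs[cid].length
            cur, cur_o = cid, o
            ok = False
            while len(chain) <= max_tip_nodes:
                steps = tg.out_edges(cur, cur_o)
                if len(steps) != 1:
                    break
                nid, no, _ = steps[0]
                back = tg.out_edges(nid, FLIP[no])
                if len(back) > 1 or tg.degree(nid) > 2:
                    ok = True  # chain attaches to the rest of the graph here
                    break
                chain.append(nid)
                total += tg.contigs[nid].length
                cur, cur_o = nid, no
            if (
                ok
                and len(chain) <= max_tip_nodes
                and total < max_tip_len
                and not any(n in tg.landmarks for n in chain)
            ):
                for n in chain:
                    tg.remove_node(n)
                changed = True
    return tg


@dataclass
class Bubble:
    bubble_id: str
    entry: tuple  # (node id, orientation)
    exit: tuple
    walks: list  # list of walks; each walk is a list of (node id, orientation)
                 # for the interior only (may be empty)
    uniform_nodes: set
    divergent_nodes: set


def _convergence_candidates(tg, start, step_limit, span_limit):
    """States reached by every out-branch of ``start``, nearest first."""
    branches = tg.out_edges(*start)
    reach: dict[tuple, set] = {}
    dist: dict[tuple, int] = {}
    for bi, (tid, to, tol) in enumerate(branches):
        if tid == start[0]:
            continue
        frontier = {(tid, to): max(tg.contigs[tid].length - tol, 0)}
        seen_span = dict(frontier)
        for state, span in frontier.items():
            reach.setdefault(state, set()).add(bi)
            dist.setdefault(state, 1)
        d = 1
        while frontier and d < step_limit:
            d += 1
            nxt = {}
            for (nid, o), span in frontier.items():
                for tid2, to2, tol2 in tg.out_edges(nid, o):
                    if tid2 == start[0]:
                        continue
                    nspan = span + max(tg.contigs[tid2].length - tol2, 0)
                    if nspan > span_limit:
                        continue
                    state = (tid2, to2)
                    if nspan >= seen_span.get(state, float("inf")):
                        continue
                    seen_span[state] = nspan
                    nxt[state] = nspan
                    reach.setdefault(state, set()).add(bi)
                    dist.setdefault(state, d)
            frontier = nxt
    full = set(range(len(branches)))
    cands = [s for s, r in reach.items() if r == full]
    cands.sort(key=lambda s: (dist[s], s))
    return cands


def _states_reaching(tg, target, step_limit):
    """States with a directed path to ``target`` within ``step_limit`` edges.

    Predecessors of (n, o) are read off the mirror adjacency: every edge
    (n, flip o) -> (m, om) mirrors (m, flip om) -> (n, o).
    """
    can = {target}
    frontier = [target]
    for _ in range(step_limit):
        nxt = []
        for nid, o in frontier:
            for mid, mo, _ in tg.out_edges(nid, FLIP[o]):
                pred = (mid, FLIP[mo])
                if pred not in can:
                    can.add(pred)
                    nxt.append(pred)
        if not nxt:
            break
        frontier = nxt
    return can


def _paths_to(tg, start, target, step_limit, span_limit, max_walks, max_expansions=50000):
    """Simple paths from ``start`` to ``target`` state (exclusive of both),
    bounded; None when more than ``max_walks`` paths exist or the search
    budget is exhausted. The DFS only enters states that can still reach
    the target."""
    can_reach = _states_reaching(tg, target, step_limit)
    walks = []
    stack = [(start, [], frozenset({start[0]}), 0)]
    expansions = 0
    while stack:
        expansions += 1
        if expansions > max_expansions:
            return None
        state, path, seen, span = stack.pop()
        if len(path) >= step_limit:
            continue
        for tid, to, tol in tg.out_edges(*state):
            if tid in seen:
                continue
            nspan = span + max(tg.contigs[tid].length - tol, 0)
            if nspan > span_limit:
                continue
            if (tid, to) == target:
                if path not in walks:
                    walks.append(path)
                    if len(walks) > max_walks:
                        return None
                continue
            if tid == target[0] or (tid, to) not in can_reach:
                continue
            stack.append(((tid, to), path + [(tid, to)], seen | {tid}, nspan))
    return walks


def find_bubbles(
    tg: TargetContigGraph,
    step_limit: int = 30,
    span_limit: int = 15000,
    max_walks: int = 16,
    max_candidates: int = 5,
) -> list[Bubble]:
    """Detect bubbles: walk sets sharing an entry and exit node.

    For every state with out-degree >= 2 the nearest node u reachable from
    all out-branches is sought; the walk set is all bounded simple paths to
    u. A bubble is reported when no interior node connects outside the walk
    set. Interior nodes shared by >= 2 walks are uniform, walk-private
    nodes divergent. Bubbles are reported innermost-first and deduplicated
    against their reverse-complement mirror.
    """
    bubbles = []
    seen_keys = set()
    for cid in sorted(tg.contigs):
        for o in "+-":
            start = (cid, o)
            if len(tg.out_edges(cid, o)) < 2:
                continue
            found = None
            for u in _convergence_candidates(tg, start, step_limit, span_limit)[:max_candidates]:
                walks = _paths_to(tg, start, u, step_limit, span_limit, max_walks)
                if walks is None or len(walks) < 2:
                    continue
                first_steps = {w[0] for w in walks if w} | (
                    {u} if [] in walks else set()
                )
                if len(first_steps) < len(tg.out_edges(cid, o)):
                    continue
                interior = {n for w in walks for (n, _) in w}
                allowed = interior | {cid, u[0]}
                if all(
                    tid in allowed
                    for n in interior
                    for oo in "+-"
                    for tid, _, _ in tg.out_edges(n, oo)
                ):
                    found = (u, walks, interior)
                    break
            if found is None:
                continue
            u, walks, interior = found
            key = (frozenset({start, (u[0], FLIP[u[1]])}), frozenset(interior))
            if key in seen_keys:
                continue
            seen_keys.add(key)
            counts = {}
            for w in walks:
                for n, _ in w:
                    counts[n] = counts.get(n, 0) + 1
            uniform = {n for n, c in counts.items() if c >= 2}
            divergent = {n for n, c in counts.items() if c == 1}
            bubbles.append(
                Bubble(
                    f"bub{len(bubbles):05d}", start, u,
                    sorted(walks, key=lambda w: [n for n, _ in w]),
                    uniform, divergent,
                )
            )
    bubbles.sort(key=lambda b: (sum(tg.contigs[n].length for n in b.divergent_nodes | b.uniform_nodes), b.entry))
    for i, b in enumerate(bubbles):
        b.bubble_id = f"bub{i:05d}"
    return bubbles


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns (+1/-1/-2)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    aln = _aligner.align(a, b)[0]
    c = aln.counts()
    total = c.gaps + c.identities + c.mismatches
    return c.identities / total if total else 0.0


def walk_divergent_sequence(tg, bubble: Bubble, walk) -> str:
    return "".join(
        tg.contigs[n].oriented(o) for (n, o) in walk if n in bubble.divergent_nodes
    )


def walk_depth(tg, bubble: Bubble, walk, default: float) -> float:
    """Length-weighted mean depth over the walk's private (divergent) nodes."""
    nodes = [(n, o) for (n, o) in walk if n in bubble.divergent_nodes] or list(walk)
    if not nodes:
        return default
    total = sum(tg.contigs[n].length for n, _ in nodes)
    return sum(tg.contigs[n].depth * tg.contigs[n].length for n, _ in nodes) / total


def bubble_identities(tg, bubble: Bubble) -> list:
    """Pairwise identities of the walks' concatenated divergent sequences."""
    seqs = [walk_divergent_sequence(tg, bubble, w) for w in bubble.walks]
    out = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            out.append(pairwise_identity(seqs[i], seqs[j]))
    return out


def merge_bubbles(
    tg: TargetContigGraph,
    bubbles,
    depth_model: DepthModel,
    identity_threshold: float = 0.95,
) -> TargetContigGraph:
    """Pop variant-like bubbles, keeping the walk nearest the genome depth.

    When all pairwise divergent-sequence identities reach the threshold the
    bubble is a variant, not a repeat: the walk whose depth is closest to
    the depth-model mean is retained and the other walks recorded in
    ``removed_walks`` and removed from the graph. Low-identity bubbles are
    left intact.
    """
    removed_nodes = set()
    for b in bubbles:
        if any(n in removed_nodes for n in b.uniform_nodes | b.divergent_nodes):
            continue  # nested within an already-simplified bubble
        idents = bubble_identities(tg, b)
        if not idents or min(idents) < identity_threshold:
            continue
        depths = [walk_depth(tg, b, w, depth_model.mu) for w in b.walks]
        keep = min(
            range(len(b.walks)),
            key=lambda i: (abs(depths[i] - depth_model.mu), [n for n, _ in b.walks[i]]),
        )
        kept_nodes = {n for n, _ in b.walks[keep]}
        for i, w in enumerate(b.walks):
            if i == keep:
                continue
            tg.removed_walks.append((b.bubble_id, [n for n, _ in w], depths[i]))
            for n, _ in w:
                if n not in kept_nodes and n not in removed_nodes:
                    tg.remove_node(n)
                    removed_nodes.add(n)
    return tg


@dataclass
class Scaffold:
    id: str
    parts: list  # ordered (contig id, orientation)
    gaps: list  # N-gap after each junction (0 for exact-overlap joins)
    sequence: str
    offsets: list = field(default_factory=list)  # start of each part in sequence


def _chains(tg: TargetContigGraph):
    """Maximal unbranched chains as lists of (node, orient, overlap_with_prev)."""
    visited = set()
    chains = []

    def extend(cid, o):
        path = [(cid, o, 0)]
        cur, cur_o = cid, o
        while True:
            steps = tg.out_edges(cur, cur_o)
            if len(steps) != 1:
                break
            nid, no, ol = steps[0]
            if nid in visited or len(tg.out_edges(nid, FLIP[no])) != 1 or nid == cid:
                break
            path.append((nid, no, ol))
            visited.add(nid)
            cur, cur_o = nid, no
        return path

    for cid in sorted(tg.contigs):
        if cid in visited:
            continue
        dplus = len(tg.out_edges(cid, "+"))
        dminus = len(tg.out_edges(cid, "-"))
        start = None
        if dplus == 1 and dminus == 1:
            continue  # interior; will be picked up from an endpoint
        visited.add(cid)
        if dplus <= 1 and dminus != 1:
            start = (cid, "+")
        elif dminus <= 1:
            start = (cid, "-")
        else:
            chains.append([(cid, "+", 0)])  # branching node: singleton
            continue
        chains.append(extend(*start))
    # cycles of interior nodes
    for cid in sorted(tg.contigs):
        if cid not in visited:
            visited.add(cid)
            chains.append(extend(cid, "+"))
    return chains


def build_scaffolds(
    tg: TargetContigGraph,
    plinks=(),
    insert_model: MixtureModel | None = None,
    min_support: int = 3,
    min_gap: int = 10,
) -> list[Scaffold]:
    """Assemble the simplified target graph into scaffolds.

    Maximal unbranched chains are collapsed over their exact overlaps; chain
    ends joined by a consistent Plink are concatenated with a gap of
    max(min_gap, estimated distance) Ns. Total contig bases are conserved.
    """
    chains = _chains(tg)

    # index chain endpoints for plink joining: (node, orient pointing out)
    head = {}  # (node, orient of entry when traversed forward) handled below
    joined: dict[int, dict] = {
        i: {"parts": ch, "prev": None, "next": None} for i, ch in enumerate(chains)
    }
    ends = {}
    for i, ch in enumerate(chains):
        first, last = ch[0], ch[-1]
        ends[(last[0], last[1])] = ("tail", i)
        ends[(first[0], FLIP[first[1]])] = ("head_rc", i)

    links = sorted(
        (p for p in plinks if p.support >= min_support),
        key=lambda p: (-p.support, p.a_id, p.b_id),
    )
    used_tail, used_head = set(), set()
    for p in links:
        a = ends.get((p.a_id, p.a_orient))
        b_entry = (p.b_id, p.b_orient)
        # joining requires the link to leave a chain tail and enter a chain head
        b = None
        for j, ch in joined.items():
            first = ch["parts"][0]
            if (first[0], first[1]) == b_entry:
                b = ("head", j)
                break
            last = ch["parts"][-1]
            if (last[0], FLIP[last[1]]) == b_entry:
                b = ("tail_rc", j)
                break
        if a is None or b is None:
            continue
        ai, bj = a[1], b[1]
        if ai == bj or a[0] != "tail":
            log.info("plink %s-%s skipped: inconsistent orientation", p.a_id, p.b_id)
            continue
        if ai in used_tail or bj in used_head:
            continue
        if b[0] == "tail_rc":
            joined[bj]["parts"] = [
                (n, FLIP[o], 0) for (n, o, _) in reversed(joined[bj]["parts"])
            ]
            # recompute overlaps lost by reversal: conservative, use gap join only
        gap = max(min_gap, int(round(p.distance_mean)))
        joined[ai]["next"] = (bj, gap)
        joined[bj]["prev"] = ai
        used_tail.add(ai)
        used_head.add(bj)

    scaffolds = []
    for i in sorted(joined):
        if joined[i]["prev"] is not None:
            continue
        parts, gaps, seq, offsets = [], [], [], []
        pos = 0
        j = i
        while j is not None:
            ch = joined[j]["parts"]
            for idx, (n, o, ol) in enumerate(ch):
                s = tg.contigs[n].oriented(o)
                if idx == 0:
                    offsets.append(pos)
                    seq.append(s)
                    pos += len(s)
                else:
                    gaps.append(0)
                    offsets.append(pos - ol)
                    seq.append(s[ol:])
                    pos += len(s) - ol
                parts.append((n, o))
            nxt = joined[j]["next"]
            if nxt is not None:
                jn, gap = nxt
                gaps.append(gap)
                seq.append("N" * gap)
                pos += gap
                j = jn
            else:
                j = None
        scaffolds.append(
            Scaffold(f"scaffold{len(scaffolds):04d}", parts, gaps, "".join(seq), offsets)
        )
    return scaffolds
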