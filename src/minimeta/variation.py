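"""De novo strain-level variation from assembly-graph bubbles.

Bubbles surviving an identity filter (repeat-like bubbles are dissimilar)
and a depth filter (error-like walks are shallow) are treated as variant
sites. Components of the target graph are summarized by bubble density and
mean bubble identity; a logistic model on those summaries classifies
genomes as strain-variation-containing; per-bubble variant abundances come
from a weighted non-negative least squares fit of walk and uniform-node
depths, summarized by Shannon alpha diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .recovery import Bubble, bubble_identities, walk_depth


def filter_variant_bubbles(
    tg,
    bubbles,
    identity_threshold: float = 0.95,
    min_walk_depth: float = 2.0,
    max_walks: int = 3,
):
    """Keep the bubbles attributable to genetic variants.

    Repeat-like bubbles (any divergent identity below the threshold) are
    dropped; walks shallower than ``min_walk_depth`` fold are removed as
    likely sequencing error; bubbles left with fewer than 2 or more than
    ``max_walks`` walks are discarded.
    """
    kept = []
    for b in bubbles:
        idents = bubble_identities(tg, b)
        if not idents or min(idents) < identity_threshold:
            continue
        walks = [
            w
            for w in b.walks
            if walk_depth(tg, b, w, default=min_walk_depth) >= min_walk_depth
        ]
        if len(walks) < 2 or len(walks) > max_walks:
            continue
        counts: dict[str, int] = {}
        for w in walks:
            for n, _ in w:
                counts[n] = counts.get(n, 0) + 1
        kept.append(
            Bubble(
                b.bubble_id, b.entry, b.exit, walks,
                {n for n, c in counts.items() if c >= 2},
                {n for n, c in counts.items() if c == 1},
            )
        )
    return kept


@dataclass
class ComponentMetrics:
    component_id: str
    bubble_count: int
    density: float
    mean_identity: float
    no_bubble: bool  # mean_identity is the 1.0 convention, not a measurement
    uniform_count: int
    divergent_lengths: list
    uniform_lengths: list
    mismatch_count: int


def component_metrics(tg, component_nodes, bubbles, component_id: str = "comp") -> ComponentMetrics:
    """Bubble density and identity of one target-graph component.

    Density is the divergent fraction of component bases,
    sum(LD) / (sum(LD) + sum(LU)); identity is the mean over the component's
    variant bubbles of their alignment identity (matches / columns). A
    component without bubbles reports density 0 and identity 1.0, flagged.
    """
    nodes = set(component_nodes)
    comp_bubbles = [
        b for b in bubbles if (b.divergent_nodes | b.uniform_nodes) & nodes or b.entry[0] in nodes
    ]
    divergent = set()
    for b in comp_bubbles:
        divergent |= b.divergent_nodes & nodes
    ld = [tg.contigs[n].length for n in sorted(divergent)]
    uniform = sorted(nodes - divergent)
    lu = [tg.contigs[n].length for n in uniform]
    total = sum(ld) + sum(lu)
    density = (sum(ld) / total) if (ld and total) else 0.0

    idents = []
    mismatches = 0
    for b in comp_bubbles:
        pair_idents = bubble_identities(tg, b)
        if pair_idents:
            idents.append(float(np.mean(pair_idents)))
            arm_len = max(
                (sum(tg.contigs[n].length for n, _ in w if n in b.divergent_nodes) for w in b.walks),
                default=0,
            )
            mismatches += int(round((1.0 - min(pair_idents)) * arm_len))
    no_bubble = not idents
    m = 1.0 if no_bubble else float(np.mean(idents))
    return ComponentMetrics(
        component_id, len(comp_bubbles), density, m, no_bubble,
        len(uniform), ld, lu, mismatches,
    )


@dataclass
class BubbleDistanceSet:
    component_id: str
    distances: list


def bubble_distances(tg, component_nodes, bubbles, component_id: str = "comp") -> BubbleDistanceSet:
    """Uniform-sequence lengths between adjacent bubbles of a component.

    All divergent nodes are deleted; every remaining maximal chain that was
    flanked by bubbles on both sides contributes its accumulated contig
    length. Terminal chains (pendant on the component boundary) are
    excluded.
    """
    nodes = set(component_nodes)
    divergent = set()
    for b in bubbles:
        divergent |= b.divergent_nodes
    remaining = nodes - divergent
    if not any((b.divergent_nodes | b.uniform_nodes) & nodes or b.entry[0] in nodes for b in bubbles):
        return BubbleDistanceSet(component_id, [])

    # adjacency restricted to remaining nodes
    adj: dict[str, set] = {n: set() for n in remaining}
    for n in remaining:
        for o in "+-":
            for tid, _, _ in tg.out_edges(n, o):
                if tid in remaining and tid != n:
                    adj[n].add(tid)
    # flag nodes that used to touch a divergent (bubble) node
    touches_bubble = {}
    for n in remaining:
        t = False
        for o in "+-":
            for tid, _, _ in tg.out_edges(n, o):
                if tid in divergent:
                    t = True
        touches_bubble[n] = t

    seen = set()
    distances = []
    for n in sorted(remaining):
        if n in seen or len(adj[n]) > 1:
            continue
        # walk the chain from this end
        chain = [n]
        seen.add(n)
        cur = n
        while True:
            nxts = [x for x in adj[cur] if x not in seen]
            if len(nxts) != 1:
                break
            cur = nxts[0]
            seen.add(cur)
            chain.append(cur)
        flanked = touches_bubble[chain[0]] and touches_bubble[chain[-1]]
        if len(chain) == 1:
            flanked = touches_bubble[chain[0]] and sum(
                1
                for o in "+-"
                for tid, _, _ in tg.out_edges(chain[0], o)
                if tid in divergent
            ) >= 2
        if flanked:
            distances.append(sum(tg.contigs[c].length for c in chain))
    return BubbleDistanceSet(component_id, sorted(distances))


# --------------------------------------------------------------------------
# Strain classification


@dataclass
class StrainModel:
    theta: np.ndarray  # (intercept, weight_m, weight_k)
    trained: bool = False
    history: list = field(default_factory=list)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def genome_identity_summary(metrics_list) -> float:
    """Average component identity with single-pass +-3 sd outlier removal."""
    idents = np.array([m.mean_identity for m in metrics_list], dtype=float)
    if idents.size == 0:
        raise ValueError("genome has no components")
    mu, sd = idents.mean(), idents.std()
    if sd > 0:
        keep = np.abs(idents - mu) <= 3.0 * sd
        if keep.any():
            idents = idents[keep]
    return float(idents.mean())


def fit_strain_model(
    training,
    lr: float = 0.5,
    iters: int = 5000,
) -> StrainModel:
    """Logistic regression on (m, k) by batch gradient descent.

    ``training`` is a list of (m, k, y) with y in {0, 1}; parameters start
    at zero and the cross-entropy loss is minimized with a fixed learning
    rate, so the fit is fully deterministic.
    """
    ys = {y for _, _, y in training}
    if ys != {0, 1}:
        raise ValueError("training data must contain both classes")
    x = np.array([[1.0, m, k] for m, k, _ in training])
    y = np.array([float(yy) for _, _, yy in training])
    theta = np.zeros(3)
    history = []
    n = len(y)
    for _ in range(iters):
        p = _sigmoid(x @ theta)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        history.append(loss)
        grad = x.T @ (p - y) / n
        theta -= lr * grad
    return StrainModel(theta, True, history)


def predict_strain_variation(model: StrainModel, m: float, n_components: int):
    """Probability that a genome contains strain-level variation.

    Features are m (average component identity) and k = log(m / n) with n
    the component count; the label is probability >= 0.5.
    """
    if not model.trained:
        raise ValueError("model not trained")
    if n_components <= 0:
        raise ValueError("genome has no components")
    k = math.log(m / n_components)
    p = float(_sigmoid(model.theta @ np.array([1.0, m, k])))
    return p, p >= 0.5


# --------------------------------------------------------------------------
# Variant abundances and alpha diversity


def length_weight(x: float) -> float:
    """Depth-confidence weight of a contig of length x: w = 1 - e^(-x*0.5/100)."""
    return 1.0 - math.exp(-x * 0.5 / 100.0)


@dataclass
class VariantSite:
    bubble_id: str
    walks: list  # per-allele walks (lists of (node, orient))
    walk_depths: list
    uniform_depths: list
    weights: list  # per design row, from length_weight
    abundances: np.ndarray  # Pi, on the simplex
    alpha: float
    allele_seqs: list = None  # divergent sequence per walk ('N' when empty)


def variant_abundances(
    tg,
    bubble: Bubble,
    uniform_nodes=None,
) -> VariantSite:
    """Per-variant abundances for one bubble by weighted NNLS.

    Rows of the design are one indicator row per walk (its private depth
    observation) and one all-ones row per uniform node (all variants pass
    through); observations are the depths, weighted by the length-confidence
    w(x). Abundances are the normalized non-negative solution.
    """
    walks = bubble.walks
    if not walks:
        raise ValueError("bubble has no walks")
    k = len(walks)
    rows, obs, weights = [], [], []
    for i, w in enumerate(walks):
        private = [(n, o) for (n, o) in w if n in bubble.divergent_nodes]
        nodes = private or w
        if not nodes:
            continue
        length = sum(tg.contigs[n].length for n, _ in nodes)
        depth = sum(tg.contigs[n].depth * tg.contigs[n].length for n, _ in nodes) / length
        row = np.zeros(k)
        row[i] = 1.0
        rows.append(row)
        obs.append(depth)
        weights.append(length_weight(length))
    uniform = sorted(uniform_nodes if uniform_nodes is not None else bubble.uniform_nodes)
    uniform_depths = []
    for n in uniform:
        rows.append(np.ones(k))
        obs.append(tg.contigs[n].depth)
        uniform_depths.append(tg.contigs[n].depth)
        weights.append(length_weight(tg.contigs[n].length))
    if not rows:
        raise ValueError("bubble has no depth observations")
    a = np.vstack(rows)
    d = np.array(obs)
    if not np.any(d > 0):
        raise ValueError("all-zero depths; cannot estimate abundances")
    sw = np.sqrt(np.array(weights))
    coef, _ = nnls(a * sw[:, None], d * sw)
    total = coef.sum()
    if total <= 0:
        coef = np.ones(k)
        total = float(k)
    pi = coef / total
    walk_depths = list(d[:k]) if len(d) >= k else list(d)
    from .recovery import walk_divergent_sequence

    seqs = [walk_divergent_sequence(tg, bubble, w) or "N" for w in walks]
    return VariantSite(
        bubble.bubble_id, walks, walk_depths, uniform_depths,
        list(weights), pi, alpha_diversity(pi), seqs,
    )


def alpha_diversity(pi) -> float:
    """Shannon entropy H = -sum Pi ln Pi of variant abundances (0 ln 0 = 0)."""
    p = np.asarray(pi, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {p.sum():.6f}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())
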