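"""Composition-based binning of mini-metagenome contigs and bin merging.

Contigs are profiled by canonical tetranucleotide frequency (TNF, 136
strand-independent features), compared with the Spearman footrule distance
on frequency ranks, and clustered by deterministic average linkage. Bins
are then anchored onto the metagenome contig connection graph and merged
when joined by an end-to-end overlap on a shared node or by a unique
unambiguous path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .formats import revcomp
from .kmers import KmerIndex, covered_fraction

# 136 canonical tetramers: reverse-complement pairs pooled, palindromes kept once
_ALL4 = ["".join(p) for p in product("ACGT", repeat=4)]
CANONICAL_TETRAMERS = sorted({min(k, revcomp(k)) for k in _ALL4})
_CANON_POS = {k: i for i, k in enumerate(CANONICAL_TETRAMERS)}
FOLD_INDEX = np.array(
    [_CANON_POS[min(k, revcomp(k))] for k in _ALL4], dtype=np.intp
)
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

N_FEATURES = len(CANONICAL_TETRAMERS)  # 136


@dataclass
class TNFVector:
    values: np.ndarray  # 136 canonical tetranucleotide frequencies, sum 1
    contig_id: str
    contig_len: int


@dataclass
class GenomeBin:
    bin_id: str
    member_contig_ids: set
    provenance: str = "meta-S"


def tnf_profile(sequence: str, contig_id: str = "") -> TNFVector:
    """Canonical TNF of a sequence (windows containing N are skipped)."""
    codes = _BASE_CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    if len(codes) < 4:
        raise ValueError(f"sequence too short for TNF: {len(codes)} < 4")
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
    if not valid.any():
        raise ValueError("no N-free tetranucleotide window in sequence")
    win = (
        c0.astype(np.int64) * 64
        + c1.astype(np.int64) * 16
        + c2.astype(np.int64) * 4
        + c3.astype(np.int64)
    )[valid]
    counts = np.bincount(win, minlength=256).astype(float)
    folded = np.zeros(N_FEATURES)
    np.add.at(folded, FOLD_INDEX, counts)
    folded /= folded.sum()
    return TNFVector(folded, contig_id, len(sequence))


def _rank_vector(values: np.ndarray) -> np.ndarray:
    """Descending-frequency ranks, ties broken by canonical lexicographic order."""
    order = np.lexsort((np.arange(len(values)), -values))
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(len(values))
    return ranks


def footrule_distance(p: TNFVector, q: TNFVector) -> int:
    """Spearman footrule: sum of absolute rank displacements between profiles."""
    if len(p.values) != len(q.values):
        raise ValueError("TNF dimensionality mismatch")
    return int(np.abs(_rank_vector(p.values) - _rank_vector(q.values)).sum())


def cluster_meta_s(
    contigs,
    min_len: int = 1000,
    cutoff: float = 6000.0,
    metric: str = "footrule",
) -> list[GenomeBin]:
    """Cluster contigs into bins by average-linkage on TNF distances.

    Contigs shorter than ``min_len`` are assigned afterwards to the nearest
    bin centroid if within the cut distance, else left unbinned. Input order
    does not affect the result.
    """
    contigs = sorted(contigs, key=lambda c: c.id)
    large = [c for c in contigs if c.length >= min_len]
    if not large:
        raise ValueError(f"no contig of length >= {min_len}; cannot cluster")
    profiles = [tnf_profile(c.sequence, c.id) for c in large]

    if len(large) == 1:
        assignment = {large[0].id: 1}
        n_bins = 1
    else:
        if metric == "footrule":
            feats = np.vstack([_rank_vector(p.values) for p in profiles]).astype(float)
            dist = pdist(feats, "cityblock")
        elif metric == "euclidean":
            feats = np.vstack([p.values for p in profiles])
            dist = pdist(feats, "euclidean")
        else:
            raise ValueError(f"unknown clustering metric {metric!r}")
        z = linkage(dist, method="average")
        flat = fcluster(z, t=cutoff, criterion="distance")
        assignment = {c.id: int(lbl) for c, lbl in zip(large, flat)}
        n_bins = len(set(flat))

    members: dict[int, set] = {}
    for cid, lbl in assignment.items():
        members.setdefault(lbl, set()).add(cid)

    # centroids in TNF space for the small-contig rescue pass
    by_id = {p.contig_id: p for p in profiles}
    centroids = {}
    for lbl, ids in members.items():
        centroids[lbl] = TNFVector(
            np.mean([by_id[i].values for i in sorted(ids)], axis=0), f"bin{lbl}", 0
        )
    for c in contigs:
        if c.length >= min_len or c.length < 4:
            continue
        try:
            prof = tnf_profile(c.sequence, c.id)
        except ValueError:
            continue
        if metric == "footrule":
            dists = {lbl: footrule_distance(prof, cen) for lbl, cen in centroids.items()}
        else:
            dists = {
                lbl: float(np.linalg.norm(prof.values - cen.values))
                for lbl, cen in centroids.items()
            }
        lbl, d = min(dists.items(), key=lambda kv: (kv[1], kv[0]))
        if d <= cutoff:
            members[lbl].add(c.id)

    bins = []
    for i, lbl in enumerate(sorted(members, key=lambda l: min(members[l]))):
        bins.append(GenomeBin(f"bin{i:04d}", members[lbl], "meta-S"))
    return bins


# --------------------------------------------------------------------------
# Anchoring bins on the contig connection graph


@dataclass
class AnchorMap:
    """Per bin: meta-O node -> (matched fraction, end-to-end overlap length)."""

    anchors: dict  # bin_id -> {node_id: (fraction, end_overlap_len)}
    threshold: float

    def bins_on_node(self, node_id: str) -> set:
        return {
            b
            for b, nodes in self.anchors.items()
            if node_id in nodes and nodes[node_id][0] >= self.threshold
        }

    def anchored_nodes(self, bin_id: str) -> set:
        return {
            n
            for n, (frac, _) in self.anchors.get(bin_id, {}).items()
            if frac >= self.threshold
        }


def _end_overlap(node_seq: str, bin_seqs, min_len: int = 40) -> int:
    """Longest exact end-to-end overlap between the node and any bin sequence."""
    from .graph import _overlap_lengths

    best = 0
    for o in (node_seq, revcomp(node_seq)):
        for b in bin_seqs:
            if len(b) < min_len:
                continue
            for s, t in ((o, b), (b, o)):
                hits = _overlap_lengths(s, t, min_len)
                if hits:
                    best = max(best, hits[0])
    return best


def anchor_bins(
    bins,
    meta_s_contigs: dict,
    ccg,
    k: int = 31,
    fraction_threshold: float = 0.5,
    end_overlap_min: int = 40,
) -> AnchorMap:
    """Locate bins on the graph by exact shared k-mers.

    For each meta-O node, the matched fraction against each bin is the share
    of node bases covered by k-mers present in the bin; a node is anchored
    when that fraction reaches the threshold. End-to-end overlaps between
    node ends and bin sequence ends (>= 40 bp) are recorded for merging.
    """
    anchors: dict[str, dict] = {}
    for b in bins:
        seqs = {cid: meta_s_contigs[cid] for cid in sorted(b.member_contig_ids)}
        index = KmerIndex(seqs, k=k)
        node_map = {}
        bin_seqs = list(seqs.values())
        for nid in sorted(ccg.contigs):
            node_seq = ccg.contigs[nid].sequence
            frac = covered_fraction(node_seq, index)
            if frac <= 0.0:
                continue
            eo = _end_overlap(node_seq, bin_seqs, end_overlap_min)
            node_map[nid] = (frac, eo)
        anchors[b.bin_id] = node_map
    return AnchorMap(anchors, fraction_threshold)


@dataclass
class BinLinkGraph:
    nodes: list
    edges: dict  # frozenset{bin_a, bin_b} -> justification string


def _unique_path_between(ccg, from_nodes, to_nodes, forbidden, max_len: int,
                         max_expansions: int = 20000):
    """Return the single bounded path from a from-node to a to-node, or None.

    Path interior must avoid ``forbidden`` nodes; if zero or more than one
    distinct path exists the criterion fails. When the search budget is
    exhausted the region is too ambiguous to certify a unique path, which
    also fails the criterion.
    """
    found = []
    to_set = set(to_nodes)
    expansions = 0
    for start in sorted(from_nodes):
        for o in "+-":
            stack = [((start, o), [start], 0)]
            while stack:
                expansions += 1
                if expansions > max_expansions:
                    return None
                (cid, orient), path, span = stack.pop()
                for tid, torient, tol in ccg.out_edges(cid, orient):
                    if tid in path:
                        continue
                    cost = span + max(ccg.contigs[tid].length - tol, 0)
                    if cost > max_len:
                        continue
                    if tid in to_set:
                        cand = path + [tid]
                        if cand not in found:
                            found.append(cand)
                            if len(found) > 1:
                                return None
                        continue
                    if tid in forbidden:
                        continue
                    stack.append(((tid, torient), path + [tid], cost))
    return found[0] if len(found) == 1 else None


def link_and_merge(
    bins,
    anchor_map: AnchorMap,
    ccg,
    end_overlap_min: int = 40,
    max_path_len: int = 10000,
) -> list[GenomeBin]:
    """Merge bins connected on the graph; unlinked bins pass through.

    Two bins are linked when (1) both have an end-to-end overlap of at least
    ``end_overlap_min`` with the same node, or (2) exactly one bounded path
    joins them and no path-interior node is anchored to any other bin.
    """
    by_id = {b.bin_id: b for b in bins}
    link_edges: dict[frozenset, str] = {}

    bins_with_end_overlap: dict[str, set] = {}
    for bid, nodes in anchor_map.anchors.items():
        for nid, (_, eo) in nodes.items():
            if eo >= end_overlap_min:
                bins_with_end_overlap.setdefault(nid, set()).add(bid)
    for nid, bids in sorted(bins_with_end_overlap.items()):
        for a in sorted(bids):
            for b in sorted(bids):
                if a < b:
                    link_edges.setdefault(frozenset((a, b)), f"end-overlap@{nid}")

    anchored = {b.bin_id: anchor_map.anchored_nodes(b.bin_id) for b in bins}
    bin_ids = sorted(by_id)
    for i, a in enumerate(bin_ids):
        for b in bin_ids[i + 1 :]:
            if frozenset((a, b)) in link_edges:
                continue
            if not anchored[a] or not anchored[b]:
                continue
            forbidden = set()
            for other in bin_ids:
                if other not in (a, b):
                    forbidden |= anchored[other]
            path = _unique_path_between(
                ccg, anchored[a], anchored[b] - anchored[a], forbidden, max_path_len
            )
            if path is not None:
                link_edges[frozenset((a, b))] = f"path:{'-'.join(path)}"

    # merged bins = connected components of the bin link graph
    parent = {bid: bid for bid in by_id}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in link_edges:
        a, b = sorted(pair)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, set] = {}
    for bid in by_id:
        groups.setdefault(find(bid), set()).add(bid)
    merged = []
    for i, root in enumerate(sorted(groups)):
        ids = set()
        for bid in groups[root]:
            ids |= by_id[bid].member_contig_ids
        provenance = "merged" if len(groups[root]) > 1 else by_id[root].provenance
        merged.append(GenomeBin(f"target{i:04d}", ids, provenance))
    return merged
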