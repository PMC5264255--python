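"""Synthetic mock communities with ground truth for every pipeline stage.

Genomes are drawn from per-genome order-3 Markov models (Dirichlet-drawn
context distributions rescaled to a target GC), share a library of short
interspersed repeats that tangles the assembly graph, and may carry strain
partners at a controlled ANI. Contigs are the unitigs of a compacted de
Bruijn graph over the genomes, so the overlap structure (k-1 exact
overlaps) matches what the contig connection graph expects, and every
contig base is traceable to its source genomes.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .formats import PairedAlignment, revcomp
from .graph import Contig, OverlapEdge
from .kmers import match_blocks, reference_coverage

_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MockGenome:
    id: str
    sequence: str
    gc_target: float
    depth: float = 0.0
    strain_group: str | None = None
    true_ani: float | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MockCommunity:
    genomes: list
    repeats: list
    contigs: list = field(default_factory=list)  # graph.Contig
    truth: dict = field(default_factory=dict)  # contig id -> [(genome, start, orient)]
    walks: dict = field(default_factory=dict)  # genome id -> [(contig id, orient)]
    edges: set = field(default_factory=set)
    k: int = 41

    def genome(self, gid: str) -> MockGenome:
        return next(g for g in self.genomes if g.id == gid)

    def sources(self, contig_id: str) -> set:
        return {g for g, _, _ in self.truth.get(contig_id, ())}


def _markov_model(rng, gc: float, concentration: float = 1.5):
    """Order-3 context distributions with every context rescaled to gc.

    The Dirichlet draw gives each genome a distinctive oligonucleotide
    signature; the rescaling pins the stationary GC to the target exactly.
    The default concentration puts between-genome composition divergence in
    the species-level regime the mock emulates (where composition-based
    binning is informative), well above within-genome variation.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    probs = rng.dirichlet(base * concentration, size=64)
    probs = np.maximum(probs, 1e-4)
    for ctx in range(64):
        p = probs[ctx]
        at = p[0] + p[3]
        cg = p[1] + p[2]
        p[0] *= (1 - gc) / at
        p[3] *= (1 - gc) / at
        p[1] *= gc / cg
        p[2] *= gc / cg
    return np.cumsum(probs, axis=1)


def _markov_sequence(rng, cum, length: int) -> str:
    u = rng.random(length)
    out = []
    ctx = 0
    cum_list = cum.tolist()
    for i in range(length):
        row = cum_list[ctx]
        x = u[i]
        b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out.append(_BASES[b])
        ctx = ((ctx << 2) | b) & 63
    return "".join(out)


def generate_community(
    n_genomes: int = 20,
    length: int = 200000,
    n_strain_pairs: int = 2,
    ani: float = 0.98,
    repeat_count: int = 60,
    repeat_length: int = 150,
    seed: int = 0,
) -> MockCommunity:
    """Build a mock community: genomes, shared repeats, strain pairs.

    ``n_genomes`` counts all genomes; the first ``n_strain_pairs`` base
    genomes are founders whose partners (point substitutions at rate
    1 - ani) are appended. Fully deterministic from the seed.
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if not (0.9 < ani < 1.0):
        raise ValueError(f"ani {ani} outside (0.9, 1.0)")
    if n_strain_pairs * 2 > n_genomes:
        raise ValueError("too many strain pairs for the community size")
    rng = np.random.default_rng(seed)
    n_base = n_genomes - n_strain_pairs

    repeat_rng = np.random.default_rng(rng.integers(1 << 31))
    neutral = _markov_model(repeat_rng, 0.5, concentration=50.0)
    repeats = [
        _markov_sequence(repeat_rng, neutral, repeat_length) for _ in range(repeat_count)
    ]

    genomes = []
    for i in range(n_base):
        gc = float(rng.uniform(0.30, 0.65))
        cum = _markov_model(rng, gc)
        seq = _markov_sequence(rng, cum, length)
        genomes.append(MockGenome(f"g{i:03d}", seq, gc))

    # splice each repeat into up to 3 genomes at 2 positions each
    inserts: dict[int, list] = {i: [] for i in range(n_base)}
    for rep in repeats:
        targets = rng.choice(n_base, size=min(3, n_base), replace=False)
        for t in targets:
            for _ in range(2):
                inserts[int(t)].append((int(rng.integers(0, length)), rep))
    for i, ins in inserts.items():
        seq = genomes[i].sequence
        for pos, rep in sorted(ins, reverse=True):
            seq = seq[:pos] + rep + seq[pos:]
        genomes[i].sequence = seq

    for p in range(n_strain_pairs):
        founder = genomes[p]
        founder.strain_group = f"sp{p}"
        seq = list(founder.sequence)
        n_sub = rng.binomial(len(seq), 1.0 - ani)
        positions = rng.choice(len(seq), size=n_sub, replace=False)
        for pos in positions:
            old = seq[pos]
            choices = [b for b in _BASES if b != old]
            seq[pos] = choices[int(rng.integers(3))]
        partner = MockGenome(
            f"g{n_base + p:03d}",
            "".join(seq),
            founder.gc_target,
            strain_group=f"sp{p}",
            true_ani=1.0 - n_sub / len(seq),
        )
        founder.true_ani = partner.true_ani
        genomes.append(partner)

    community = MockCommunity(genomes, repeats)
    assign_depths_power_law(community)
    return community


def assign_depths_power_law(
    community: MockCommunity,
    dmin: float = 5.0,
    dmax: float = 128.0,
    exponent: float = 1.5,
) -> MockCommunity:
    """Map abundance ranks through a bounded power law onto [dmin, dmax].

    Rank 1 receives dmax and the last rank dmin; intermediate ranks follow
    d_i = dmin + (dmax - dmin) * ((n - i) / (n - 1))^exponent. Deterministic.
    """
    if dmin >= dmax:
        raise ValueError("dmin must be < dmax")
    n = len(community.genomes)
    for i, g in enumerate(community.genomes, start=1):
        frac = ((n - i) / (n - 1)) ** exponent if n > 1 else 1.0
        g.depth = dmin + (dmax - dmin) * frac
    return community


def unitigs_and_truth(
    community: MockCommunity,
    k: int = 41,
    depth_noise: bool = True,
    seed: int = 0,
) -> MockCommunity:
    """Compact the de Bruijn graph of the community into unitig contigs.

    Genome walks are broken at every (k-1)-mer with bidirected in- or
    out-degree above 1 (both strands of all genomes counted); maximal
    unbranched segments, deduplicated by canonical sequence, are the
    contigs. Consecutive segments overlap by exactly k-1 bases. Per-contig
    depth is the sum of the depths of the genomes carrying it, optionally
    Poisson-resampled.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    km1 = k - 1
    mask = (1 << (2 * km1)) - 1
    shift = 2 * (km1 - 1)
    # (k-1)-mer code -> [succ mask, pred mask], both strands folded in
    ctx: dict[int, list] = {}

    for g in community.genomes:
        seq = g.sequence
        codes = [_CODE[b] for b in seq]
        L = len(codes)
        if L < km1:
            continue
        fwd = 0
        rc = 0
        for i in range(km1):
            fwd = ((fwd << 2) | codes[i]) & mask
            rc = (rc >> 2) | (_COMP[codes[i]] << shift)
        for i in range(L - km1 + 1):
            pred = codes[i - 1] if i > 0 else -1
            succ = codes[i + km1] if i + km1 < L else -1
            entry = ctx.get(fwd)
            if entry is None:
                entry = ctx[fwd] = [0, 0]
            if succ >= 0:
                entry[0] |= 1 << succ
            if pred >= 0:
                entry[1] |= 1 << pred
            rentry = ctx.get(rc)
            if rentry is None:
                rentry = ctx[rc] = [0, 0]
            if succ >= 0:
                rentry[1] |= 1 << _COMP[succ]
            if pred >= 0:
                rentry[0] |= 1 << _COMP[pred]
            if i + km1 < L:
                b = codes[i + km1]
                fwd = ((fwd << 2) | b) & mask
                rc = (rc >> 2) | (_COMP[b] << shift)

    def popcount(x):
        return bin(x).count("1")

    seq_to_id: dict[str, str] = {}
    contigs: dict[str, Contig] = {}
    truth: dict[str, list] = {}
    walks: dict[str, list] = {}
    edges: set[OverlapEdge] = set()

    for g in community.genomes:
        seq = g.sequence
        codes = [_CODE[b] for b in seq]
        L = len(codes)
        fwd = 0
        for i in range(km1):
            fwd = ((fwd << 2) | codes[i]) & mask
        breakpoints = [0]
        for i in range(L - km1 + 1):
            if 0 < i < L - km1:
                e = ctx[fwd]
                if popcount(e[0]) > 1 or popcount(e[1]) > 1:
                    breakpoints.append(i)
            if i + km1 < L:
                fwd = ((fwd << 2) | codes[i + km1]) & mask
        breakpoints.append(L - km1)
        walk = []
        seen = set()
        for j in range(len(breakpoints) - 1):
            a, b = breakpoints[j], breakpoints[j + 1]
            if (a, b) in seen:
                continue
            seen.add((a, b))
            segment = seq[a : b + km1]
            canon = min(segment, revcomp(segment))
            cid = seq_to_id.get(canon)
            if cid is None:
                cid = f"c{len(seq_to_id):06d}"
                seq_to_id[canon] = cid
                contigs[cid] = Contig(cid, canon, source="synthetic")
                truth[cid] = []
            orient = "+" if canon == segment else "-"
            truth[cid].append((g.id, a, orient))
            walk.append((cid, orient))
        walks[g.id] = walk
        for (a_id, a_o), (b_id, b_o) in zip(walk, walk[1:]):
            edges.add(OverlapEdge(a_id, a_o, b_id, b_o, km1).canonical())

    rng = np.random.default_rng(seed + 1)
    gdepth = {g.id: g.depth for g in community.genomes}
    for cid, occs in truth.items():
        d = sum(gdepth[g] for g, _, _ in occs)
        if depth_noise:
            lc = contigs[cid].length
            d = rng.poisson(d * lc) / lc
        contigs[cid].depth = float(d)

    community.contigs = [contigs[c] for c in sorted(contigs)]
    community.truth = truth
    community.walks = walks
    community.edges = edges
    community.k = k
    return community


def reconstruct_from_walk(community: MockCommunity, genome_id: str) -> str:
    """Concatenate the genome's unitig walk, trimming the k-1 overlaps."""
    km1 = community.k - 1
    by_id = {c.id: c for c in community.contigs}
    parts = []
    for idx, (cid, orient) in enumerate(community.walks[genome_id]):
        s = by_id[cid].oriented(orient)
        parts.append(s if idx == 0 else s[km1:])
    return "".join(parts)


@dataclass
class MiniMetaSample:
    genome_ids: list
    covered_fraction: dict  # genome id -> realized fraction
    contigs: list  # graph.Contig, source='meta-S'


def simulate_minimeta(
    community: MockCommunity,
    subset,
    target_fraction: float = 0.6,
    bias_sd: float = 1.0,
    seed: int = 0,
    min_fragment: int = 500,
) -> MiniMetaSample:
    """Emulate an MDA-amplified sorted sample with uneven coverage.

    Per genome a smoothed lognormal amplification field is thresholded at
    the (1 - target_fraction) quantile; covered runs of at least
    ``min_fragment`` bp become the sample's contigs (exact substrings of
    the genome). ``bias_sd = 0`` yields full, even coverage.
    """
    subset = sorted(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    rng = np.random.default_rng(seed)
    covered_fraction = {}
    contigs = []
    by_id = {g.id: g for g in community.genomes}
    for gid in subset:
        g = by_id[gid]
        L = g.length
        n_ctrl = max(L // 2000, 4)
        ctrl = (
            np.ones(n_ctrl)
            if bias_sd == 0
            else rng.lognormal(mean=0.0, sigma=bias_sd, size=n_ctrl)
        )
        xs = np.linspace(0, L - 1, n_ctrl)
        f = np.interp(np.arange(L), xs, ctrl)
        thr = np.quantile(f, 1.0 - target_fraction)
        mask = f >= thr
        covered_fraction[gid] = float(mask.mean())
        i = 0
        idx = 0
        while i < L:
            if mask[i]:
                j = i
                while j < L and mask[j]:
                    j += 1
                if j - i >= min_fragment:
                    contigs.append(
                        Contig(f"S_{gid}_{idx:04d}", g.sequence[i:j], source="meta-S")
                    )
                    idx += 1
                i = j
            else:
                i += 1
    return MiniMetaSample(subset, covered_fraction, contigs)


def simulate_reads(
    community: MockCommunity,
    error_rate: float = 0.02,
    insert_mean: float = 200.0,
    insert_sd: float = 20.0,
    read_len: int = 100,
    seed: int = 0,
):
    """Paired reads at each genome's depth, plus truth alignments.

    Reads are uniform substitution-error copies of genome fragments with
    normally distributed insert sizes. The returned truth alignments place
    each mate on the unitig occurrence containing its 5' start (aligned
    length clipped at the unitig end), so the downstream graph annotation
    steps can run without an external aligner.
    """
    if read_len >= insert_mean:
        raise ValueError("read_len must be below the mean insert size")
    rng = np.random.default_rng(seed)
    km1 = community.k - 1
    by_id = {c.id: c for c in community.contigs}

    # per genome: sorted segment starts for position -> contig occurrence lookup
    seg_index: dict[str, list] = {}
    for cid, occs in community.truth.items():
        for gid, start, orient in occs:
            seg_index.setdefault(gid, []).append((start, cid, orient))
    for gid in seg_index:
        seg_index[gid].sort()

    def place(gid, pos, length, genome_orient):
        segs = seg_index[gid]
        starts = [s[0] for s in segs]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            i = 0
        start, cid, orient = segs[i]
        seg_len = by_id[cid].length
        alen = max(1, min(length, start + seg_len - pos))
        off = pos - start
        if orient == "+":
            cpos = off
            corient = genome_orient
        else:
            cpos = seg_len - off - alen
            corient = "-" if genome_orient == "+" else "+"
        return cid, max(cpos, 0), corient, alen

    reads1, reads2, alignments = [], [], []
    pair_no = 0
    for g in community.genomes:
        L = g.length
        n_pairs = int(round(g.depth * L / (2 * read_len)))
        starts = rng.integers(0, max(L - int(insert_mean) - 1, 1), size=n_pairs)
        inserts = np.maximum(
            rng.normal(insert_mean, insert_sd, size=n_pairs).round().astype(int),
            read_len,
        )
        for s, ins in zip(starts.tolist(), inserts.tolist()):
            e = min(s + ins, L)
            frag = g.sequence[s:e]
            if len(frag) < read_len:
                continue
            r1 = frag[:read_len]
            r2 = revcomp(frag[-read_len:])
            if error_rate > 0:
                r1 = _mutate(rng, r1, error_rate)
                r2 = _mutate(rng, r2, error_rate)
            pid = f"p{pair_no:08d}"
            pair_no += 1
            reads1.append((pid, r1))
            reads2.append((pid, r2))
            ca, pa, oa, la = place(g.id, s, read_len, "+")
            cb, pb, ob, lb = place(g.id, e - read_len, read_len, "-")
            alignments.append(PairedAlignment(pid, ca, pa, oa, cb, pb, ob, la, lb))
    return reads1, reads2, alignments


def _mutate(rng, read: str, rate: float) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    chars = list(read)
    for pos in rng.choice(len(read), size=n_err, replace=False):
        old = chars[pos]
        options = [b for b in _BASES if b != old]
        chars[pos] = options[int(rng.integers(3))]
    return "".join(chars)


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# --------------------------------------------------------------------------
# Evaluation


def nga(block_lengths, reference_length: int, fraction: float = 0.75) -> int:
    """Largest N such that aligned blocks >= N cover ``fraction`` of the
    reference. Returns 0 when the blocks never reach the fraction."""
    need = fraction * reference_length
    total = 0
    for b in sorted(block_lengths, reverse=True):
        total += b
        if total >= need:
            return b
    return 0


@dataclass
class GenomeEvaluation:
    genome_id: str
    coverage: float  # percent of the reference recovered
    contamination: float  # percent of recovered bases from other genomes
    nga75: int
    increase_sensitivity: float | None = None
    decrease_precision: float | None = None
    decrease_sensitivity: float | None = None


@dataclass
class EvalReport:
    per_genome: list

    def mean(self, attr: str):
        vals = [getattr(g, attr) for g in self.per_genome if getattr(g, attr) is not None]
        return float(np.mean(vals)) if vals else None


def evaluate_recovery(
    community: MockCommunity,
    genome_id: str,
    scaffolds,
    k: int = 31,
) -> GenomeEvaluation:
    """Coverage / contamination / NGA75 of recovered scaffolds vs truth.

    Coverage is exact-k-mer reference coverage (inputs are error-free, so
    exact matching suffices); contamination attributes each scaffold part
    to its truth sources; NGA75 follows the aligned-block definition with
    blocks from co-linear exact-match chaining.
    """
    g = community.genome(genome_id)
    by_id = {c.id: c for c in community.contigs}
    seqs = [s.sequence.replace("N", "") for s in scaffolds]
    coverage = 100.0 * reference_coverage(seqs, g.sequence, k=k)
    total = 0
    foreign = 0
    for s in scaffolds:
        for cid, _ in s.parts:
            length = by_id[cid].length
            total += length
            if genome_id not in community.sources(cid):
                foreign += length
    contamination = 100.0 * foreign / total if total else 0.0
    blocks = []
    for s in seqs:
        blocks.extend(match_blocks(s, g.sequence, k=k))
    return GenomeEvaluation(genome_id, coverage, contamination, nga(blocks, g.length))


def step_metrics(predicted, truth_ids, denominator_ids):
    """(precision over predicted, sensitivity over the denominator set)."""
    predicted = set(predicted)
    truth_ids = set(truth_ids)
    denominator_ids = set(denominator_ids)
    tp_p = len(predicted & truth_ids)
    precision = tp_p / len(predicted) if predicted else None
    tp_s = len(predicted & denominator_ids)
    sensitivity = tp_s / len(denominator_ids) if denominator_ids else None
    return precision, sensitivity
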