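"""End-to-end orchestration: from contigs + bins to scaffolds and variants.

Thin glue over the stage modules; every function here is deterministic
given its seed and config, and is what both the command-line interface and
the mock-community evaluation drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import binning, recovery, variation
from .config import PipelineConfig
from .graph import ContigConnectionGraph, build_ccg, partition_ccg
from .mock import (
    EvalReport,
    GenomeEvaluation,
    MockCommunity,
    evaluate_recovery,
    step_metrics,
)

log = logging.getLogger(__name__)


def connected_components(tg) -> list:
    """Orientation-blind connected components of a contig graph, sorted."""
    parent = {cid: cid for cid in tg.contigs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in tg.edges:
        ra, rb = find(e.from_id), find(e.to_id)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, set] = {}
    for cid in tg.contigs:
        comps.setdefault(find(cid), set()).add(cid)
    return [comps[r] for r in sorted(comps)]


@dataclass
class RecoveryResult:
    bin_ids: set
    increase_ran: bool
    candidates: list
    seeds: set
    depth_model: object
    kept: list
    landmarks: set
    tg: object  # simplified target graph (after tip trim and bubble merge)
    bubbles: list  # all bubbles found before merging
    variant_bubbles: list
    scaffolds: list
    components: list
    metrics: list  # ComponentMetrics per component
    m: float
    n_components: int
    variant_sites: dict = field(default_factory=dict)  # bubble id -> VariantSite


def compute_codon_features(contigs, min_len: int = 300, orf_frame: bool = False) -> dict:
    """Codon-usage vectors for every contig at or above the length floor."""
    features = {}
    for c in contigs:
        v = recovery.codon_usage(c.sequence, c.id, min_len=min_len, orf_frame=orf_frame)
        if v is not None:
            features[c.id] = v
    return features


def run_genome_recovery(
    ccg: ContigConnectionGraph,
    bin_ids,
    cfg: PipelineConfig | None = None,
    features: dict | None = None,
    seed: int = 0,
) -> RecoveryResult:
    """Run increase / decrease / connection for one target bin.

    Bins without enough large members for classifier training skip the
    increase step (candidates empty) and recover purely by graph traversal
    from the seed landmarks.
    """
    cfg = cfg or PipelineConfig.default()
    contigs = list(ccg.contigs.values())
    bin_ids = set(bin_ids)
    bin_sequences = {cid: ccg.contigs[cid].sequence for cid in bin_ids}
    if features is None:
        features = compute_codon_features(
            contigs, cfg["mga.min_contig"], cfg["mga.orf_frame"]
        )

    candidates: list = []
    increase_ran = False
    try:
        train = recovery.build_training_sets(
            bin_sequences,
            contigs,
            min_contig=cfg["mga.min_contig"],
            min_positive=cfg["mga.min_positive"],
            negative_rule=cfg["mga.negative_rule"],
        )
        candidates = recovery.svm_increase(
            train, features, seed=seed, c=cfg["mga.svm_c"], gamma=cfg["mga.svm_gamma"]
        )
        increase_ran = True
    except ValueError as exc:
        log.info("increase step skipped: %s", exc)

    try:
        seeds = recovery.seed_contigs(
            bin_sequences, contigs, k=cfg["baf.anchor_k"], coverage=cfg["mga.seed_coverage"]
        )
    except ValueError:
        seeds = set(bin_ids)

    depths = {c.id: c.depth for c in contigs}
    lengths = {c.id: c.length for c in contigs}
    try:
        model = recovery.fit_depth_model(
            seeds, depths, lengths,
            sd_floor=cfg["em.depth_sd_floor"],
            max_iter=cfg["em.max_iter"],
            tol=cfg["em.tol"],
        )
    except ValueError:
        vals = [depths[s] for s in sorted(seeds)]
        model = recovery.DepthModel(
            [(1.0, float(np.mean(vals)), max(float(np.std(vals)), cfg["em.depth_sd_floor"]))], 0
        )

    kept = recovery.depth_decrease(candidates, depths, model, n_sd=cfg["mga.depth_sd"])
    landmarks = set(kept) | set(seeds)

    tg = recovery.connect_landmarks(
        ccg, landmarks, step_limit=cfg["mga.step_limit"], span_limit=cfg["mga.span_limit"]
    )
    recovery.trim_tips(tg, cfg["mga.max_tip_nodes"], cfg["mga.max_tip_len"])
    bubbles = recovery.find_bubbles(
        tg,
        step_limit=cfg["mga.step_limit"],
        span_limit=cfg["mga.span_limit"],
        max_walks=cfg["mga.max_bubble_walks"],
    )

    variant_bubbles = variation.filter_variant_bubbles(
        tg, bubbles,
        identity_threshold=cfg["mga.identity"],
        min_walk_depth=cfg["variation.min_walk_depth"],
        max_walks=cfg["variation.max_walks"],
    )
    components = connected_components(tg)
    metrics = [
        variation.component_metrics(tg, comp, variant_bubbles, f"comp{i:04d}")
        for i, comp in enumerate(components)
    ]
    m = variation.genome_identity_summary(metrics) if metrics else 1.0
    # abundances need every walk's depths, so compute before bubble merging
    variant_sites = {}
    for b in variant_bubbles:
        try:
            variant_sites[b.bubble_id] = variation.variant_abundances(tg, b)
        except ValueError:
            continue

    recovery.merge_bubbles(tg, bubbles, model, identity_threshold=cfg["mga.identity"])
    scaffolds = recovery.build_scaffolds(
        tg,
        plinks=[p for p in ccg.plinks if p.a_id in tg.contigs and p.b_id in tg.contigs],
        min_support=cfg["ccg.plink_min_support"],
        min_gap=cfg["mga.scaffold_min_gap"],
    )
    return RecoveryResult(
        bin_ids, increase_ran, candidates, seeds, model, kept, landmarks,
        tg, bubbles, variant_bubbles, scaffolds, components, metrics,
        m, len(components), variant_sites,
    )


def variant_records(result: RecoveryResult) -> list:
    """VariantRecords for the result's variant bubbles, placed on scaffolds.

    The reference allele is the kept walk's divergent sequence (the walk
    whose nodes survived bubble merging); alternates are the other walks'.
    The position is the 1-based scaffold offset of the kept walk's first
    divergent node.
    """
    from .formats import VariantRecord

    offset_of = {}
    scaffold_of = {}
    for s in result.scaffolds:
        for (cid, _), off in zip(s.parts, s.offsets):
            scaffold_of[cid] = s.id
            offset_of[cid] = off
    records = []
    for b in result.variant_bubbles:
        site = result.variant_sites.get(b.bubble_id)
        if site is None:
            continue
        present = [
            i for i, w in enumerate(b.walks)
            if all(n in result.tg.contigs for n, _ in w)
        ]
        kept = present[0] if present else 0
        kept_div = [
            (n, o) for n, o in b.walks[kept] if n in b.divergent_nodes
        ]
        anchor = next(
            (n for n, _ in kept_div if n in scaffold_of),
            next((n for n, _ in b.walks[kept] if n in scaffold_of), None),
        )
        if anchor is None:
            continue
        # allele sequences were captured pre-merge on the VariantSite
        seqs = site.allele_seqs
        ref = seqs[kept]
        alts = [seqs[i] for i in range(len(b.walks)) if i != kept]
        order = [kept] + [i for i in range(len(b.walks)) if i != kept]
        depths = [
            site.walk_depths[i] if i < len(site.walk_depths) else 0.0 for i in order
        ]
        abund = [float(site.abundances[i]) for i in order]
        total = sum(abund)
        abund = [a / total for a in abund] if total else abund
        records.append(
            VariantRecord(
                scaffold_of[anchor], offset_of[anchor] + 1, ref, alts,
                depths, abund, b.bubble_id,
            )
        )
    records.sort(key=lambda r: (r.scaffold_id, r.position, r.bubble_id))
    return records


# --------------------------------------------------------------------------
# Mock-community evaluation runs


@dataclass
class MockRunResult:
    community: MockCommunity
    ccg: ContigConnectionGraph
    per_genome: dict  # genome id -> RecoveryResult
    report: EvalReport
    excluded: list  # genomes below the seed-coverage recommendation
    strain_features: list  # (genome id, m, n_components, y)


def build_mock_ccg(community: MockCommunity, cfg: PipelineConfig) -> ContigConnectionGraph:
    """Overlap graph of the mock contigs, partitioned at ambiguous junctions.

    Connection-step traversal runs on the partitioned graph: the
    w-convergence rule severs the repeat junctions that would otherwise
    bridge genomes, while bubbles (which reconverge) are retained.
    """
    ccg = build_ccg(community.contigs, min_overlap=cfg["ccg.min_overlap"])
    partition_ccg(ccg, cfg["ccg.w_conv"], cfg["partition.strict_gt2"])
    return ccg


def select_seed_bins(community: MockCommunity, fraction: float, seed: int) -> dict:
    """Randomly pick ``fraction`` of each genome's contigs as its seed bin."""
    rng = np.random.default_rng(seed)
    bins = {}
    for g in community.genomes:
        ids = sorted(
            cid for cid, occs in community.truth.items() if any(o[0] == g.id for o in occs)
        )
        n_pick = max(int(round(fraction * len(ids))), 1)
        picked = rng.choice(len(ids), size=min(n_pick, len(ids)), replace=False)
        bins[g.id] = {ids[i] for i in picked}
    return bins


def run_mock_pipeline(
    community: MockCommunity,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> MockRunResult:
    """Full recovery of every genome of a mock community from seed bins.

    Seed bins are a random fraction of each genome's contigs; genomes whose
    seeds cover less than the recommended fraction of the genome are
    excluded from the evaluation report (but still recorded).
    """
    cfg = cfg or PipelineConfig.default()
    ccg = build_mock_ccg(community, cfg)
    features = compute_codon_features(
        community.contigs, cfg["mga.min_contig"], cfg["mga.orf_frame"]
    )
    bins = select_seed_bins(community, cfg["sim.seed_fraction"], seed)
    by_id = {c.id: c for c in community.contigs}

    per_genome = {}
    rows = []
    excluded = []
    strain_features = []
    for g in community.genomes:
        bin_ids = bins[g.id]
        seed_len = sum(by_id[c].length for c in bin_ids)
        if seed_len / g.length < cfg["sim.min_seed_coverage"]:
            excluded.append(g.id)
        result = run_genome_recovery(ccg, bin_ids, cfg, features=features, seed=seed)
        per_genome[g.id] = result

        truth_ids = {
            cid for cid, occs in community.truth.items() if any(o[0] == g.id for o in occs)
        }
        denom = {
            cid for cid in truth_ids - bin_ids if by_id[cid].length >= cfg["mga.min_contig"]
        }
        ev = evaluate_recovery(community, g.id, result.scaffolds, k=cfg["baf.anchor_k"])
        if result.increase_ran:
            _, inc_sens = step_metrics(result.candidates, truth_ids, denom)
            dec_prec, dec_sens = step_metrics(result.kept, truth_ids, denom)
            ev.increase_sensitivity = inc_sens
            ev.decrease_precision = dec_prec
            ev.decrease_sensitivity = dec_sens
        rows.append(ev)
        strain_features.append(
            (g.id, result.m, result.n_components, 1 if g.strain_group else 0)
        )

    report = EvalReport([r for r in rows if r.genome_id not in excluded])
    return MockRunResult(community, ccg, per_genome, report, excluded, strain_features)


def bin_purity(community: MockCommunity, bins) -> list:
    """Per-bin contamination fraction (bases from non-majority genomes)."""
    by_id = {c.id: c for c in community.contigs}
    out = []
    for b in bins:
        genome_bases: dict[str, int] = {}
        total = 0
        for cid in b.member_contig_ids:
            length = by_id[cid].length
            total += length
            for gid in community.sources(cid):
                genome_bases[gid] = genome_bases.get(gid, 0) + length
        if not genome_bases:
            continue
        majority = max(sorted(genome_bases), key=lambda g: genome_bases[g])
        foreign = sum(
            by_id[cid].length
            for cid in b.member_contig_ids
            if majority not in community.sources(cid)
        )
        out.append(foreign / total if total else 0.0)
    return out


def cluster_mock_meta_o(community: MockCommunity, cfg: PipelineConfig | None = None):
    """TNF-cluster the community's contigs at the binning length floor."""
    cfg = cfg or PipelineConfig.default()
    big = [c for c in community.contigs if c.length >= cfg["baf.min_len"]]
    return binning.cluster_meta_s(
        big,
        min_len=cfg["baf.min_len"],
        cutoff=cfg["baf.cluster_cutoff"],
        metric=cfg["baf.metric"],
    )


def fit_strain_classifier(strain_features, cfg: PipelineConfig | None = None):
    """Fit the logistic strain classifier from per-genome (m, n, y) rows."""
    import math

    cfg = cfg or PipelineConfig.default()
    training = [
        (m, math.log(m / n), y) for _, m, n, y in strain_features if n > 0
    ]
    return variation.fit_strain_model(
        training, lr=cfg["variation.lr"], iters=cfg["variation.gd_iters"]
    )
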