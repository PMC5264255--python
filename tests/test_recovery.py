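import numpy as np
import pytest

from minimeta.graph import Contig, build_ccg
from minimeta.recovery import (
    DepthModel,
    TargetContigGraph,
    build_scaffolds,
    build_training_sets,
    codon_usage,
    connect_landmarks,
    depth_decrease,
    find_bubbles,
    merge_bubbles,
    pairwise_identity,
    seed_contigs,
    svm_increase,
    trim_tips,
    TrainingSets,
    CodonUsageVector,
)


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestCodonUsage:
    def test_constructed_orf_dominated_by_aaa(self):
        seq = "ATG" + "AAA" * 200 + "TAA"
        v = codon_usage(seq, orf_frame=True)
        aaa = 0  # codon code for AAA
        assert v.orf_based
        assert v.values[aaa] == pytest.approx(200 / 202, abs=1e-6)
        # the frame-free default also concentrates on AAA
        v2 = codon_usage(seq)
        assert v2.values[aaa] > 0.95

    def test_below_min_length_excluded(self, rng):
        assert codon_usage(_rand(rng, 250)) is None

    def test_sums_to_one(self, rng):
        v = codon_usage(_rand(rng, 5000))
        assert v.values.sum() == pytest.approx(1.0)
        v = codon_usage(_rand(rng, 5000), orf_frame=True)
        assert v.values.sum() == pytest.approx(1.0)


class TestTrainingSets:
    def test_partition_covers_meta_o(self, clean_community):
        contigs = clean_community.contigs
        gid = "g001"
        ids = sorted(
            c.id for c in contigs
            if gid in clean_community.sources(c.id) and c.length >= 1000
        )[:8]
        bin_seqs = {c.id: c.sequence for c in contigs if c.id in ids}
        train = build_training_sets(bin_seqs, contigs)
        big = {c.id for c in contigs if c.length >= 300}
        assert train.positive_ids | train.negative_ids | train.test_ids >= big
        assert not (train.negative_ids & train.positive_ids)
        assert not (train.test_ids & train.negative_ids)

    def test_bin_members_never_negative(self, clean_community):
        """A bin member evaluated as a query sits near the intra-bin mean."""
        contigs = clean_community.contigs
        gid = "g002"
        ids = sorted(
            c.id for c in contigs
            if gid in clean_community.sources(c.id) and c.length >= 1000
        )
        bin_seqs = {c.id: c.sequence for c in contigs if c.id in ids[:6]}
        train = build_training_sets(bin_seqs, contigs)
        held_out = set(ids[6:])
        # same-genome contigs overwhelmingly land in the test set
        assert len(held_out & train.negative_ids) <= len(held_out) // 4

    def test_foreign_gc_contig_negative(self, rng):
        # bin from a GC-0.30-like genome vs a GC-0.65-like query
        import minimeta.mock as mock

        low = mock._markov_model(np.random.default_rng(1), 0.30)
        high = mock._markov_model(np.random.default_rng(2), 0.65)
        bin_seqs = {
            f"b{i}": mock._markov_sequence(np.random.default_rng(10 + i), low, 2000)
            for i in range(6)
        }
        foreign = Contig("fx", mock._markov_sequence(np.random.default_rng(99), high, 2000))
        train = build_training_sets(bin_seqs, [foreign])
        assert "fx" in train.negative_ids

    def test_too_few_large_members(self, rng):
        with pytest.raises(ValueError, match="1 kb"):
            build_training_sets({"a": _rand(rng, 500)}, [])


class TestSvm:
    def test_linearly_separable_toy(self):
        rngl = np.random.default_rng(0)
        feats = {}
        for i in range(10):
            v = np.zeros(64)
            v[0] = 0.9 + 0.01 * rngl.random()
            v[1:] = (1 - v[0]) / 63
            feats[f"p{i}"] = CodonUsageVector(v, f"p{i}", False)
            w = np.zeros(64)
            w[63] = 0.9 + 0.01 * rngl.random()
            w[:63] = (1 - w[63]) / 63
            feats[f"n{i}"] = CodonUsageVector(w, f"n{i}", False)
        train = TrainingSets({f"p{i}" for i in range(10)}, {f"n{i}" for i in range(10)}, set())
        # training accuracy is perfect: every positive re-predicted positive
        train2 = TrainingSets(train.positive_ids, train.negative_ids, train.positive_ids)
        assert set(svm_increase(train2, feats, seed=0)) == train.positive_ids

    def test_deterministic_given_seed(self, clean_community, cfg):
        from minimeta.pipeline import compute_codon_features

        contigs = clean_community.contigs
        feats = compute_codon_features(contigs)
        gid = "g000"
        ids = sorted(
            c.id for c in contigs
            if gid in clean_community.sources(c.id) and c.length >= 1000
        )[:8]
        bin_seqs = {c.id: c.sequence for c in contigs if c.id in ids}
        train = build_training_sets(bin_seqs, contigs)
        a = svm_increase(train, feats, seed=3)
        b = svm_increase(train, feats, seed=3)
        assert a == b

    def test_class_starvation(self):
        with pytest.raises(ValueError, match="starvation"):
            svm_increase(TrainingSets(set(), set(), set()), {})


class TestSeedsAndDepth:
    def test_identity_contig_is_seed(self, rng):
        s = _rand(rng, 2000)
        seeds = seed_contigs({"m1": s}, [Contig("c1", s), Contig("c2", _rand(rng, 2000))])
        assert seeds == {"c1"}

    def test_half_covered_not_seed(self, rng):
        s = _rand(rng, 2000)
        with pytest.raises(ValueError, match="no seed"):
            seed_contigs({"m1": s[:1000]}, [Contig("c1", s[:1000] + _rand(rng, 1000))], coverage=0.9)

    def test_short_contig_requires_full_coverage(self, rng):
        # 100 bp contig differing by one substitution: 99% covered but not 100%
        s = _rand(rng, 2000)
        short = list(s[:100])
        short[50] = "A" if short[50] != "A" else "C"
        contigs = [Contig("ok", s[:200]), Contig("near", "".join(short))]
        seeds = seed_contigs({"m1": s}, contigs)
        assert seeds == {"ok"}

    def test_depth_decrease_examples(self):
        model = DepthModel([(1.0, 30.0, 3.0)], 0)
        depths = {"far": 100.0, "near": 33.0, "edge": 36.1}
        kept = depth_decrease(["far", "near", "edge"], depths, model, n_sd=2.0)
        assert kept == ["near"]


def _chain_graph(rng, labels, branch=None):
    """Linear chain of 500 bp contigs overlapping by 40, optional branch."""
    ov = 40
    joints = [_rand(rng, ov) for _ in range(len(labels) + 1)]
    contigs = []
    for i, lab in enumerate(labels):
        seq = joints[i] + _rand(rng, 420) + joints[i + 1]
        contigs.append(Contig(lab, seq, depth=30.0))
    if branch:
        # dangling node hanging off the middle joint
        mid = len(labels) // 2
        contigs.append(Contig(branch, joints[mid] + _rand(rng, 200), depth=30.0))
    return build_ccg(contigs, ov)


class TestConnection:
    def test_landmark_pair_with_intermediate(self, rng):
        g = _chain_graph(rng, ["a", "x", "b"])
        tg = connect_landmarks(g, ["a", "b"])
        assert set(tg.contigs) == {"a", "x", "b"}
        assert tg.landmarks == {"a", "b"}

    def test_step_limit_bound(self, rng):
        labels = [f"n{i}" for i in range(8)]
        g = _chain_graph(rng, labels)
        tg = connect_landmarks(g, ["n0", "n7"], step_limit=3)
        # 7 edges separate the landmarks: nothing in between is recovered
        assert set(tg.contigs) == {"n0", "n7"}
        assert not tg.edges

    def test_side_branch_excluded_exhaustive(self, rng):
        """Nodes recovered match an exhaustive path-enumeration oracle."""
        import networkx as nx

        g = _chain_graph(rng, ["a", "x", "b"], branch="dead")
        tg = connect_landmarks(g, ["a", "b"])
        # oracle: all simple paths a->b in the orientation-blind graph
        nxg = nx.Graph()
        for e in g.edges:
            nxg.add_edge(e.from_id, e.to_id)
        expected = {n for path in nx.all_simple_paths(nxg, "a", "b") for n in path}
        assert set(tg.contigs) == expected
        assert "dead" not in tg.contigs


class TestTips:
    def _tg(self, rng, stub_len=200, landmark_stub=False):
        g = _chain_graph(rng, ["a", "x", "b"], branch="stub")
        tg = connect_landmarks(g, ["a", "b", "stub"] if landmark_stub else ["a", "b"])
        # force the stub into the graph for the non-landmark case
        if "stub" not in tg.contigs:
            tg.contigs["stub"] = g.contigs["stub"]
            for e in g.edges:
                if "stub" in (e.from_id, e.to_id):
                    tg.add_edge(e)
        return tg

    def test_stub_removed(self, rng):
        tg = self._tg(rng)
        trim_tips(tg)
        assert "stub" not in tg.contigs

    def test_landmark_stub_retained(self, rng):
        tg = self._tg(rng, landmark_stub=True)
        trim_tips(tg)
        assert "stub" in tg.contigs

    def test_long_tip_retained(self, rng):
        ov = 40
        j0, j1 = _rand(rng, ov), _rand(rng, ov)
        contigs = [
            Contig("a", _rand(rng, 400) + j0, depth=10),
            Contig("b", j0 + _rand(rng, 400) + j1, depth=10),
            Contig("long", j1 + _rand(rng, 5000), depth=10),
        ]
        g = build_ccg(contigs, ov)
        tg = connect_landmarks(g, ["a", "b"])
        tg.contigs.setdefault("long", g.contigs["long"])
        for e in g.edges:
            if "long" in (e.from_id, e.to_id):
                tg.add_edge(e)
        trim_tips(tg)
        assert "long" in tg.contigs  # 5 kb exceeds the tip length guard


def _bubble_graph(rng, arms=2, depths=(28.0, 70.0), escape=False):
    ov = 40
    j0, j1 = _rand(rng, ov), _rand(rng, ov)
    contigs = [
        Contig("v", _rand(rng, 400) + j0, depth=30.0),
        Contig("u", j1 + _rand(rng, 400), depth=30.0),
    ]
    arm_core = _rand(rng, 200)
    for i in range(arms):
        core = list(arm_core)
        core[100 + i] = "ACGT"[(("ACGT".index(core[100 + i])) + 1) % 4]
        contigs.append(Contig(f"d{i}", j0 + "".join(core) + j1, depth=depths[i % len(depths)]))
    if escape:
        contigs.append(Contig("esc", contigs[2].sequence[-ov:] + _rand(rng, 300), depth=5.0))
    g = build_ccg(contigs, ov)
    tg = TargetContigGraph(dict(g.contigs))
    for e in g.edges:
        tg.add_edge(e)
    tg.landmarks = {"v", "u"}
    return tg


class TestBubbles:
    def test_two_arm_bubble_detected(self, rng):
        tg = _bubble_graph(rng)
        (b,) = find_bubbles(tg)
        assert {b.entry[0], b.exit[0]} == {"v", "u"}
        assert b.divergent_nodes == {"d0", "d1"}
        assert not b.uniform_nodes
        assert len(b.walks) == 2

    def test_escape_edge_blocks_bubble(self, rng):
        tg = _bubble_graph(rng, escape=True)
        bubbles = find_bubbles(tg)
        assert not any(b.divergent_nodes == {"d0", "d1"} for b in bubbles)

    def test_merge_keeps_depth_nearest_walk(self, rng):
        tg = _bubble_graph(rng, depths=(28.0, 70.0))
        bubbles = find_bubbles(tg)
        model = DepthModel([(1.0, 30.0, 2.0)], 0)
        merge_bubbles(tg, bubbles, model, identity_threshold=0.95)
        assert "d0" in tg.contigs and "d1" not in tg.contigs
        assert len(tg.removed_walks) == 1
        bid, walk, depth = tg.removed_walks[0]
        assert walk == ["d1"] and depth == pytest.approx(70.0)

    def test_low_identity_bubble_untouched(self, rng):
        ov = 40
        j0, j1 = _rand(rng, ov), _rand(rng, ov)
        contigs = [
            Contig("v", _rand(rng, 400) + j0, depth=30.0),
            Contig("u", j1 + _rand(rng, 400), depth=30.0),
            Contig("d0", j0 + _rand(rng, 200) + j1, depth=30.0),
            Contig("d1", j0 + _rand(rng, 200) + j1, depth=30.0),
        ]
        g = build_ccg(contigs, ov)
        tg = TargetContigGraph(dict(g.contigs))
        for e in g.edges:
            tg.add_edge(e)
        bubbles = find_bubbles(tg)
        assert len(bubbles) == 1
        merge_bubbles(tg, bubbles, DepthModel([(1.0, 30.0, 2.0)], 0))
        assert "d0" in tg.contigs and "d1" in tg.contigs
        assert not tg.removed_walks

    def test_pairwise_identity_values(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0
        assert pairwise_identity("AAAA", "AAAT") == pytest.approx(0.75)
        assert pairwise_identity("", "ACGT") == 0.0


class TestScaffolds:
    def test_chain_collapses_overlaps(self, rng):
        g = _chain_graph(rng, ["c1", "c2", "c3"])
        tg = connect_landmarks(g, ["c1", "c3"])
        scaffolds = build_scaffolds(tg)
        assert len(scaffolds) == 1
        total = sum(tg.contigs[c].length for c in ("c1", "c2", "c3"))
        assert len(scaffolds[0].sequence) == total - 2 * 40

    def test_isolated_landmark_singleton(self, rng):
        c = Contig("lone", _rand(rng, 800), depth=5.0)
        tg = TargetContigGraph({"lone": c})
        tg.landmarks = {"lone"}
        (s,) = build_scaffolds(tg)
        assert s.parts == [("lone", "+")]
        assert s.sequence == c.sequence

    def test_plink_join_inserts_gap(self, rng):
        from minimeta.graph import PLink

        c1 = Contig("c1", _rand(rng, 600), depth=5.0)
        c2 = Contig("c2", _rand(rng, 600), depth=5.0)
        tg = TargetContigGraph({"c1": c1, "c2": c2})
        plink = PLink("c1", "+", "c2", "+", 100.0, 5)
        scaffolds = build_scaffolds(tg, plinks=[plink], min_support=3)
        assert len(scaffolds) == 1
        assert scaffolds[0].sequence.count("N") == 100
        assert scaffolds[0].gaps == [100]

    def test_total_contig_bases_conserved(self, rng):
        tg = _bubble_graph(rng)
        scaffolds = build_scaffolds(tg)
        part_total = sum(
            tg.contigs[cid].length for s in scaffolds for cid, _ in s.parts
        )
        assert part_total == sum(c.length for c in tg.contigs.values())
        all_parts = [cid for s in scaffolds for cid, _ in s.parts]
        assert sorted(all_parts) == sorted(tg.contigs)
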