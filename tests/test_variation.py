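import math

import numpy as np
import pytest

from minimeta.graph import Contig
from minimeta.recovery import Bubble, DepthModel, TargetContigGraph, find_bubbles
from minimeta.variation import (
    alpha_diversity,
    bubble_distances,
    component_metrics,
    filter_variant_bubbles,
    fit_strain_model,
    genome_identity_summary,
    length_weight,
    predict_strain_variation,
    variant_abundances,
)
from tests.test_recovery import _bubble_graph, _rand


class TestFilter:
    def test_low_depth_walk_removal_discards_bubble(self, rng):
        tg = _bubble_graph(rng, depths=(10.0, 1.5))
        bubbles = find_bubbles(tg)
        assert not filter_variant_bubbles(tg, bubbles)

    def test_four_walk_bubble_discarded(self, rng):
        tg = _bubble_graph(rng, arms=4, depths=(10.0, 12.0, 14.0, 16.0))
        bubbles = find_bubbles(tg)
        assert bubbles and not filter_variant_bubbles(tg, bubbles, max_walks=3)

    def test_variant_bubble_retained(self, rng):
        tg = _bubble_graph(rng, depths=(10.0, 30.0))
        bubbles = find_bubbles(tg)
        kept = filter_variant_bubbles(tg, bubbles)
        assert len(kept) == 1 and len(kept[0].walks) == 2


class TestComponentMetrics:
    def test_no_bubbles_convention(self, rng):
        tg = TargetContigGraph({"a": Contig("a", _rand(rng, 500), depth=5.0)})
        met = component_metrics(tg, {"a"}, [], "c0")
        assert met.density == 0.0
        assert met.mean_identity == 1.0 and met.no_bubble

    def test_density_arithmetic(self, rng):
        # two divergent nodes of 100 bp, uniform total 900 bp
        tg = TargetContigGraph(
            {
                "u1": Contig("u1", _rand(rng, 400), depth=20.0),
                "u2": Contig("u2", _rand(rng, 500), depth=20.0),
                "d1": Contig("d1", _rand(rng, 100), depth=10.0),
                "d2": Contig("d2", _rand(rng, 100), depth=10.0),
            }
        )
        bubble = Bubble(
            "b0", ("u1", "+"), ("u2", "+"),
            [[("d1", "+")], [("d2", "+")]], set(), {"d1", "d2"},
        )
        met = component_metrics(tg, {"u1", "u2", "d1", "d2"}, [bubble], "c0")
        assert met.density == pytest.approx(200 / 1100)

    def test_identity_from_alignment(self, rng):
        """A bubble with 5 substitutions over 100 aligned columns."""
        core = _rand(rng, 100)
        other = list(core)
        for i in (10, 30, 50, 70, 90):
            other[i] = "ACGT"[("ACGT".index(other[i]) + 1) % 4]
        tg = TargetContigGraph(
            {
                "d1": Contig("d1", core, depth=10.0),
                "d2": Contig("d2", "".join(other), depth=10.0),
            }
        )
        bubble = Bubble(
            "b0", ("x", "+"), ("y", "+"),
            [[("d1", "+")], [("d2", "+")]], set(), {"d1", "d2"},
        )
        met = component_metrics(tg, {"d1", "d2"}, [bubble], "c0")
        assert met.mean_identity == pytest.approx(0.95)

    def test_invariant_to_relabeling(self, rng):
        tg = _bubble_graph(rng)
        bubbles = find_bubbles(tg)
        comp = set(tg.contigs)
        m1 = component_metrics(tg, comp, bubbles, "a")
        m2 = component_metrics(tg, sorted(comp, reverse=True), bubbles, "b")
        assert m1.density == m2.density and m1.mean_identity == m2.mean_identity


class TestBubbleDistances:
    def _chain_with_bubbles(self, rng, uniform_lens, n_bubbles):
        contigs = {}
        nodes = []
        for i, L in enumerate(uniform_lens):
            cid = f"u{i}"
            contigs[cid] = Contig(cid, _rand(rng, L), depth=20.0)
            nodes.append(cid)
        for i in range(n_bubbles):
            cid = f"d{i}"
            contigs[cid] = Contig(cid, _rand(rng, 80), depth=10.0)
        tg = TargetContigGraph(contigs)
        # chain u0 - d0 - u1 - d1 - u2 ... via explicit edges
        from minimeta.graph import OverlapEdge

        seq = []
        for i in range(len(uniform_lens) + n_bubbles):
            seq.append(f"u{i//2}" if i % 2 == 0 else f"d{i//2}")
        for a, b in zip(seq, seq[1:]):
            tg.add_edge(OverlapEdge(a, "+", b, "+", 10))
        bubbles = [
            Bubble(f"b{i}", (f"u{i}", "+"), (f"u{i+1}", "+"), [[(f"d{i}", "+")]], set(), {f"d{i}"})
            for i in range(n_bubbles)
        ]
        return tg, bubbles

    def test_hand_trace_single_interior(self, rng):
        tg, bubbles = self._chain_with_bubbles(rng, [100, 250, 300], 2)
        out = bubble_distances(tg, set(tg.contigs), bubbles, "c0")
        assert out.distances == [250]

    def test_no_bubbles_empty(self, rng):
        tg = TargetContigGraph({"a": Contig("a", _rand(rng, 500), depth=1.0)})
        assert bubble_distances(tg, {"a"}, [], "c0").distances == []

    def test_three_bubbles_two_distances(self, rng):
        tg, bubbles = self._chain_with_bubbles(rng, [120, 50, 70, 130], 3)
        out = bubble_distances(tg, set(tg.contigs), bubbles, "c0")
        assert out.distances == [50, 70]


class TestStrainModel:
    def test_zero_theta_gives_half(self):
        model = fit_strain_model([(0.9, -1.0, 0), (0.99, -2.0, 1)], lr=0.5, iters=0)
        p, _ = predict_strain_variation(model, 0.95, 3)
        assert p == pytest.approx(0.5)

    def test_loss_decreases_on_separable_data(self):
        training = [(0.90, math.log(0.90 / 2), 0), (0.99, math.log(0.99 / 40), 1)] * 5
        model = fit_strain_model(training, lr=0.5, iters=200)
        assert model.history[-1] < model.history[0]
        assert all(b <= a + 1e-12 for a, b in zip(model.history, model.history[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_strain_model([(0.9, 0.1, 1), (0.95, 0.2, 1)])

    def test_probability_in_unit_interval(self):
        training = [(1.0, math.log(1.0 / 2), 0), (0.97, math.log(0.97 / 30), 1)] * 3
        model = fit_strain_model(training)
        for m, n in [(1.0, 1), (0.9, 100), (0.99, 7)]:
            p, label = predict_strain_variation(model, m, n)
            assert 0.0 < p < 1.0
            assert label == (p >= 0.5)

    def test_outlier_removal_single_pass(self):
        from minimeta.variation import ComponentMetrics

        mets = [
            ComponentMetrics(f"c{i}", 1, 0.1, v, False, 1, [], [], 0)
            for i, v in enumerate([0.97] * 30 + [0.2])
        ]
        m = genome_identity_summary(mets)
        assert m == pytest.approx(0.97)  # the 0.2 outlier is dropped


class TestAbundances:
    def _site(self, rng, depths, uniform_depth=None, lens=(200, 200)):
        contigs = {}
        walks = []
        for i, d in enumerate(depths):
            cid = f"d{i}"
            contigs[cid] = Contig(cid, _rand(rng, lens[i % len(lens)]), depth=d)
            walks.append([(cid, "+")])
        uniform = set()
        if uniform_depth is not None:
            contigs["u"] = Contig("u", _rand(rng, 200), depth=uniform_depth)
            uniform = {"u"}
        tg = TargetContigGraph(contigs)
        bubble = Bubble("b0", ("x", "+"), ("y", "+"), walks, uniform, {f"d{i}" for i in range(len(depths))})
        return tg, bubble, uniform

    def test_closed_form_two_walks(self, rng):
        """Depths (10, 30) + all-ones row at 40, equal weights:
        normal equations give a = (10, 30), Pi = (0.25, 0.75)."""
        tg, bubble, uniform = self._site(rng, [10.0, 30.0], uniform_depth=40.0)
        site = variant_abundances(tg, bubble, uniform)
        assert site.abundances == pytest.approx([0.25, 0.75], abs=1e-9)

    def test_single_walk(self, rng):
        tg, bubble, _ = self._site(rng, [12.0])
        site = variant_abundances(tg, bubble)
        assert site.abundances == pytest.approx([1.0])

    def test_weight_function_closed_form(self):
        assert length_weight(0) == 0.0
        assert length_weight(100) == pytest.approx(1 - math.exp(-0.5))
        assert length_weight(1e7) == pytest.approx(1.0)

    def test_nnls_matches_grid_search(self, rng):
        """Active-set NNLS equals a dense grid-search oracle within 1e-3."""
        for trial in range(5):
            r = np.random.default_rng(trial)
            depths = (r.uniform(2, 50, size=3)).tolist()
            tg, bubble, uniform = self._site(
                rng, depths, uniform_depth=float(sum(depths) * r.uniform(0.8, 1.2)),
                lens=(150, 400, 800),
            )
            site = variant_abundances(tg, bubble, uniform)
            # oracle: dense grid over the simplex scale
            rows, obs, w = [], [], []
            for i, d in enumerate(depths):
                e = np.zeros(3); e[i] = 1
                rows.append(e); obs.append(tg.contigs[f"d{i}"].depth)
                w.append(length_weight(tg.contigs[f"d{i}"].length))
            rows.append(np.ones(3)); obs.append(tg.contigs["u"].depth)
            w.append(length_weight(200))
            A = np.array(rows); d = np.array(obs); sw = np.sqrt(np.array(w))
            best, best_val = None, np.inf
            grid = np.linspace(0, 60, 121)
            for a0 in grid:
                for a1 in grid:
                    resid_base = (A[:, 0] * a0 + A[:, 1] * a1 - d)
                    # minimize analytically over a2 >= 0 for speed
                    col = A[:, 2] * sw
                    num = -(resid_base * sw) @ col
                    den = col @ col
                    a2 = max(num / den, 0.0)
                    v = np.sum(((A @ [a0, a1, a2] - d) * sw) ** 2)
                    if v < best_val:
                        best_val, best = v, np.array([a0, a1, a2])
            pi_oracle = best / best.sum()
            assert np.allclose(site.abundances, pi_oracle, atol=2e-2)

    def test_zero_depths_rejected(self, rng):
        tg, bubble, _ = self._site(rng, [0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            variant_abundances(tg, bubble)


class TestAlphaDiversity:
    def test_single_variant_zero(self):
        assert alpha_diversity([1.0]) == 0.0

    def test_even_pair_ln2(self):
        assert alpha_diversity([0.5, 0.5]) == pytest.approx(math.log(2))

    def test_permutation_invariance(self):
        assert alpha_diversity([0.2, 0.3, 0.5]) == pytest.approx(
            alpha_diversity([0.5, 0.2, 0.3])
        )

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0.5, 0.6])

    def test_maximal_iff_uniform_on_grid(self):
        """On a 3-allele grid the entropy maximizer is the uniform point."""
        grid = np.linspace(0.01, 0.98, 30)
        best, best_h = None, -1
        for p0 in grid:
            for p1 in grid:
                p2 = 1 - p0 - p1
                if p2 <= 0:
                    continue
                h = alpha_diversity(np.array([p0, p1, p2]) / (p0 + p1 + p2))
                if h > best_h:
                    best_h, best = h, (p0, p1, p2)
        assert np.allclose(best, (1 / 3, 1 / 3, 1 / 3), atol=0.05)
        assert best_h <= math.log(3) + 1e-9
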