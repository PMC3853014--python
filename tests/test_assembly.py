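import itertools

import numpy as np
import pytest

from polydesign import (DesignGraph, GAParams, RunConfig, build_graph,
                        parse_motif, render_polyepitope, solve_exhaustive,
                        solve_ga, solve_greedy)
from polydesign.assembly import path_weight
from tests.conftest import make_flanked, p1prime_model


def random_graph(n: int, rng: np.random.Generator,
                 flanked: bool = False) -> DesignGraph:
    ids = [f"e{i}" for i in range(1, n + 1)]
    weights = {
        (i, j): float(np.round(rng.uniform(0.5, 9.5), 3))
        for i, j in itertools.permutations(ids, 2)
    }
    fl = {i: make_flanked("SLYNTVATL", i) for i in ids} if flanked else None
    return DesignGraph.from_weights(weights, flanked=fl)


THREE_NODE = {
    ("A", "B"): 1.0, ("B", "C"): 2.0, ("A", "C"): 5.0,
    ("B", "A"): 4.0, ("C", "A"): 6.0, ("C", "B"): 3.0,
}


class TestBuildGraph:
    def test_complete_digraph_from_three_epitopes(self, neutral_models, empty_freqs, config):
        pr, impr = neutral_models
        peps = [make_flanked(s, f"e{i}") for i, s in
                enumerate(["SLYNTVATL", "ILKEPVHGV", "KLVGKLVGK"], 1)]
        g = build_graph(peps, parse_motif("ADLVKV"), pr, impr, [], empty_freqs, config)
        assert g.g.number_of_edges() == 6
        assert all(g.weight(i, j) < 5000 for i, j in g.g.edges)

    def test_inadmissible_pair_gets_weight_5000(self, empty_freqs, config):
        # nothing cleaves -> every ordered pair is disallowed
        pr = p1prime_model("proteasome", {}, default=11)
        impr = p1prime_model("immunoproteasome", {}, default=11)
        peps = [make_flanked("SLYNTVATL", "e1"), make_flanked("ILKEPVHGV", "e2")]
        g = build_graph(peps, parse_motif("ADLVKV"), pr, impr, [], empty_freqs, config)
        assert g.weight("e1", "e2") == 5000.0
        assert g.edge("e1", "e2")["allowed"] is False

    def test_edges_match_independent_best_junction_recomputation(
            self, empty_freqs, config, rng):
        from polydesign import best_junction
        pr = p1prime_model("proteasome",
                           {aa: int(r) for aa, r in zip("ACDEFGHIKL", rng.integers(1, 12, 10))},
                           default=9)
        impr = p1prime_model("immunoproteasome", {"A": 2}, default=8)
        motif = parse_motif("[AC]D")
        peps = [make_flanked(s, f"e{i}") for i, s in
                enumerate(["SLYNTVATL", "ILKEPVHGV", "KLVGKLVGK"], 1)]
        targets = {p.epitope.sequence for p in peps}
        g = build_graph(peps, motif, pr, impr, [], empty_freqs, config)
        for p1, p2 in itertools.permutations(peps, 2):
            expected = best_junction(p1, p2, motif, pr, impr, [], empty_freqs, config, targets)
            data = g.edge(p1.id, p2.id)
            assert data["spacer"] == expected.spacer
            assert data["weight"] == pytest.approx(expected.weight)


class TestSolveExhaustive:
    def test_three_node_hand_example(self):
        g = DesignGraph.from_weights(THREE_NODE)
        d = solve_exhaustive(g)
        assert d.order == ("A", "B", "C")
        assert d.total_weight == pytest.approx(3.0)

    def test_single_node_path_has_zero_weight(self):
        g = DesignGraph.from_weights({})
        g.g.add_node("A", flanked=None)
        d = solve_exhaustive(g)
        assert d.order == ("A",) and d.total_weight == 0.0

    def test_matches_independent_permutation_scan(self, rng):
        g = random_graph(6, rng)
        d = solve_exhaustive(g)
        best = min(itertools.permutations(g.node_ids),
                   key=lambda p: path_weight(g, p))
        assert d.total_weight == pytest.approx(path_weight(g, best))

    def test_refuses_above_node_cap(self, rng):
        g = random_graph(9, rng)
        with pytest.raises(ValueError, match="GA|genetic"):
            solve_exhaustive(g)


class TestSolveGreedy:
    def test_three_node_hand_example(self):
        d = solve_greedy(DesignGraph.from_weights(THREE_NODE))
        assert d.order == ("A", "B", "C") and d.total_weight == pytest.approx(3.0)

    def test_never_beats_exhaustive(self, rng):
        for _ in range(20):
            g = random_graph(int(rng.integers(4, 8)), rng)
            assert solve_greedy(g).total_weight >= solve_exhaustive(g).total_weight - 1e-9

    def test_equal_weights_degenerate_case(self):
        ids = ["A", "B", "C", "D"]
        g = DesignGraph.from_weights({(i, j): 2.0 for i, j in itertools.permutations(ids, 2)})
        d = solve_greedy(g)
        assert sorted(d.order) == ids
        assert d.total_weight == pytest.approx(3 * 2.0)


class TestSolveGA:
    def test_same_seed_is_bit_identical(self, rng):
        g = random_graph(7, rng)
        params = GAParams(population=30, generations=60)
        d1 = solve_ga(g, params, seed=42)
        d2 = solve_ga(g, params, seed=42)
        assert d1.order == d2.order and d1.total_weight == d2.total_weight

    def test_requires_seed(self, rng):
        with pytest.raises(ValueError, match="seed"):
            solve_ga(random_graph(4, rng), seed=None)

    def test_population_one_generations_zero_returns_seeded_permutation(self, rng):
        g = random_graph(5, rng)
        d = solve_ga(g, GAParams(population=1, generations=0), seed=11)
        expected = [g.node_ids[k] for k in np.random.default_rng(11).permutation(5)]
        assert list(d.order) == expected
        assert d.total_weight == pytest.approx(path_weight(g, d.order))

    def test_finds_exhaustive_optimum_on_small_graphs(self, rng):
        for _ in range(5):
            g = random_graph(6, rng)
            d = solve_ga(g, GAParams(population=40, generations=80), seed=5)
            assert d.total_weight >= solve_exhaustive(g).total_weight - 1e-9

    def test_output_is_a_permutation(self, rng):
        g = random_graph(8, rng)
        d = solve_ga(g, GAParams(population=20, generations=30), seed=1)
        assert sorted(d.order) == g.node_ids


class TestRender:
    def test_sequence_length_arithmetic(self, neutral_models, empty_freqs, config):
        pr, impr = neutral_models
        peps = [make_flanked("SLYNTVATL", "e1"), make_flanked("ILKEPVHGV", "e2")]
        g = build_graph(peps, parse_motif("AD"), pr, impr, [], empty_freqs, config)
        d = render_polyepitope(g, ("e1", "e2"))
        spacer = d.junctions[0].spacer
        assert len(d.sequence) == 18 + len(spacer)
        # neutral models: direct junction is optimal, so the pure-concatenation case
        assert spacer == "" and d.sequence == "SLYNTVATL" + "ILKEPVHGV"

    def test_disallowed_edge_flagged_and_weighted(self, empty_freqs, config):
        pr = p1prime_model("proteasome", {}, default=11)
        impr = p1prime_model("immunoproteasome", {}, default=11)
        peps = [make_flanked("SLYNTVATL", "e1"), make_flanked("ILKEPVHGV", "e2")]
        g = build_graph(peps, parse_motif("ADLVKV"), pr, impr, [], empty_freqs, config)
        d = render_polyepitope(g, ("e1", "e2"))
        assert d.contains_disallowed and d.total_weight >= 5000.0

    def test_total_weight_equals_edge_sum_bookkeeping(self, rng):
        g = random_graph(6, rng, flanked=True)
        d = solve_greedy(g)
        assert d.total_weight == pytest.approx(sum(j.weight for j in d.junctions))
        assert d.total_weight == pytest.approx(path_weight(g, d.order))

    def test_non_permutation_rejected(self, rng):
        g = random_graph(4, rng)
        with pytest.raises(ValueError, match="permutation"):
            render_polyepitope(g, ("e1", "e2", "e3", "e3"))
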