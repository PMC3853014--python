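"""Epitope-ordering optimization over the junction-weight digraph.

Every ordered pair of flanked epitopes gets an edge carrying its optimal
spacer and ranking weight; inadmissible pairs (no candidate spacer creates a
usable proteasomal cleavage site) are completed with edges of weight 5000,
orders of magnitude above the usual allowed-junction weights.  The
polyepitope sequence is then the minimum-weight Hamiltonian (open) path —
a travelling-salesman variant without the return edge.  Three solvers are
provided: exhaustive enumeration (n <= 8), deterministic multi-start greedy
nearest neighbour, and a permutation-encoded genetic algorithm for larger
sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .cleavage import CleavageModel
from .core import AlleleFrequencyTable, GAParams, RunConfig, SpacerMotif
from .junctions import DISALLOWED, JunctionEvaluation, best_junction
from .mhc import MhcPssm
from .tap import FlankedEpitope

logger = logging.getLogger("polydesign")

EXHAUSTIVE_MAX_NODES = 8


@dataclass
class DesignGraph:
    """Complete weighted digraph over flanked epitopes.

    Node keys are epitope ids; each node stores its :class:`FlankedEpitope`.
    Every ordered pair (i, j), i != j, has exactly one edge with attributes
    ``spacer`` (str, or None for a disallowed matching), ``weight`` (float;
    exactly ``disallowed_weight`` for disallowed matchings), ``allowed``
    (bool) and ``evaluation`` (:class:`JunctionEvaluation` or None).
    """

    g: nx.DiGraph
    disallowed_weight: float

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.g.nodes)

    def flanked(self, node_id: str) -> FlankedEpitope:
        return self.g.nodes[node_id]["flanked"]

    def edge(self, i: str, j: str) -> dict:
        return self.g.edges[i, j]

    def weight(self, i: str, j: str) -> float:
        return self.g.edges[i, j]["weight"]

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    @classmethod
    def from_weights(
        cls,
        weights: dict[tuple[str, str], float],
        flanked: Optional[dict[str, FlankedEpitope]] = None,
        disallowed_weight: float = 5000.0,
    ) -> "DesignGraph":
        """Build a graph directly from an edge-weight map (testing/analysis aid)."""
        g = nx.DiGraph()
        nodes = sorted({i for i, _ in weights} | {j for _, j in weights})
        for n in nodes:
            g.add_node(n, flanked=None if flanked is None else flanked[n])
        for (i, j), w in weights.items():
            allowed = w < disallowed_weight
            g.add_edge(i, j, spacer="" if allowed else None, weight=float(w),
                       allowed=allowed, evaluation=None)
        for i, j in itertools.permutations(nodes, 2):
            if not g.has_edge(i, j):
                raise ValueError(f"weight map incomplete: missing edge {i}->{j}")
        return cls(g=g, disallowed_weight=disallowed_weight)


@dataclass(frozen=True)
class PathEdge:
    """One junction along a chosen epitope ordering."""

    src: str
    dst: str
    spacer: str
    weight: float
    allowed: bool
    evaluation: Optional[JunctionEvaluation]


@dataclass(frozen=True)
class PolyepitopeDesign:
    """A finished ordering: epitope ids, junctions, total weight and sequence."""

    order: tuple[str, ...]
    junctions: tuple[PathEdge, ...]
    total_weight: float
    sequence: str
    contains_disallowed: bool


def build_graph(
    peps: Sequence[FlankedEpitope],
    motif: SpacerMotif,
    model_pr: CleavageModel,
    model_impr: CleavageModel,
    panel: Sequence[MhcPssm],
    freqs: AlleleFrequencyTable,
    config: RunConfig,
    targets: Optional[Iterable[str]] = None,
) -> DesignGraph:
    """Evaluate the optimal junction for every ordered pair of epitopes.

    ``targets`` defaults to the full set of target epitope sequences, so a
    junctional window that reconstitutes *any* target epitope is never
    counted as off-target.
    """
    if len(peps) < 2:
        raise ValueError("need at least 2 epitopes to build a design graph")
    ids = [p.id for p in peps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate epitope ids in graph input")
    if targets is None:
        targets = {p.epitope.sequence for p in peps}
    targets = set(targets)
    g = nx.DiGraph()
    for p in peps:
        g.add_node(p.id, flanked=p)
    n_edges = n_disallowed = 0
    for p1, p2 in itertools.permutations(peps, 2):
        result = best_junction(
            p1, p2, motif, model_pr, model_impr, panel, freqs, config, targets
        )
        if result is DISALLOWED:
            g.add_edge(p1.id, p2.id, spacer=None, weight=config.disallowed_weight,
                       allowed=False, evaluation=None)
            n_disallowed += 1
        else:
            g.add_edge(p1.id, p2.id, spacer=result.spacer, weight=result.weight,
                       allowed=True, evaluation=result)
        n_edges += 1
    logger.info("design graph: %d nodes, %d edges (%d disallowed)",
                len(peps), n_edges, n_disallowed)
    return DesignGraph(g=g, disallowed_weight=config.disallowed_weight)


def path_weight(graph: DesignGraph, order: Sequence[str]) -> float:
    return sum(graph.weight(a, b) for a, b in zip(order, order[1:]))


def render_polyepitope(graph: DesignGraph, order: Sequence[str]) -> PolyepitopeDesign:
    """Concatenate flanked peptides and chosen spacers along ``order``.

    A disallowed edge contributes its 5000 weight, joins the peptides
    directly, and raises the ``contains_disallowed`` flag.
    """
    order = tuple(order)
    if sorted(order) != graph.node_ids:
        raise ValueError("order is not a permutation of the graph's nodes")
    pieces = []
    junctions = []
    contains_disallowed = False
    total = 0.0
    for idx, node in enumerate(order):
        flanked = graph.flanked(node)
        pieces.append(flanked.full_sequence if flanked is not None else "")
        if idx + 1 < len(order):
            data = graph.edge(node, order[idx + 1])
            spacer = data["spacer"] if data["allowed"] else ""
            junctions.append(PathEdge(
                src=node, dst=order[idx + 1], spacer=spacer,
                weight=data["weight"], allowed=data["allowed"],
                evaluation=data["evaluation"],
            ))
            total += data["weight"]
            contains_disallowed = contains_disallowed or not data["allowed"]
            pieces.append(spacer)
    return PolyepitopeDesign(
        order=order,
        junctions=tuple(junctions),
        total_weight=total,
        sequence="".join(pieces),
        contains_disallowed=contains_disallowed,
    )


def solve_exhaustive(graph: DesignGraph) -> PolyepitopeDesign:
    """Globally optimal ordering by scanning all n! permutations (n <= 8).

    Ties are broken lexicographically on the id sequence.
    """
    n = len(graph)
    if n > EXHAUSTIVE_MAX_NODES:
        raise ValueError(
            f"{n} nodes exceeds the exhaustive-solver cap of {EXHAUSTIVE_MAX_NODES} "
            f"({n}! orderings); use the genetic-algorithm solver instead"
        )
    ids = graph.node_ids
    best_order = ids
    best_w = float("inf")
    # itertools.permutations of the sorted ids is lexicographic, so strict <
    # keeps the lexicographically first optimum.
    for perm in itertools.permutations(ids):
        w = path_weight(graph, perm)
        if w < best_w:
            best_w = w
            best_order = perm
    return render_polyepitope(graph, best_order)


def solve_greedy(graph: DesignGraph) -> PolyepitopeDesign:
    """Multi-start greedy nearest neighbour: from every start node, repeatedly
    follow the cheapest outgoing edge to an unvisited node; the best of the n
    resulting paths wins (ties: lexicographically smallest order)."""
    ids = graph.node_ids
    best_order: Optional[tuple[str, ...]] = None
    best_w = float("inf")
    for start in ids:
        order = [start]
        remaining = set(ids) - {start}
        while remaining:
            here = order[-1]
            nxt = min(remaining, key=lambda j: (graph.weight(here, j), j))
            order.append(nxt)
            remaining.remove(nxt)
        w = path_weight(graph, order)
        key = (w, tuple(order))
        if best_order is None or key < (best_w, best_order):
            best_w, best_order = w, tuple(order)
    return render_polyepitope(graph, best_order)


def _order_crossover(p1: list[int], p2: list[int], rng: np.random.Generator) -> list[int]:
    # OX: copy a slice of p1, fill the rest in p2's order.
    n = len(p1)
    a, b = sorted(rng.integers(0, n, size=2))
    b += 1
    segment = p1[a:b]
    in_segment = set(segment)
    fill = [x for x in p2 if x not in in_segment]
    return fill[:a] + segment + fill[a:]


def solve_ga(
    graph: DesignGraph,
    params: Optional[GAParams] = None,
    seed: Optional[int] = None,
) -> PolyepitopeDesign:
    """Permutation-encoded genetic algorithm for the ordering problem.

    Tournament selection, order crossover, segment-inversion mutation and
    single-individual elitism; a fixed seed gives a bit-identical result.
    Returns the best individual of the final generation.
    """
    if len(graph) < 2:
        raise ValueError("GA solver needs at least 2 nodes")
    if seed is None:
        raise ValueError("solve_ga requires an explicit random seed for reproducibility")
    params = params or GAParams()
    params.validate()
    rng = np.random.default_rng(seed)
    ids = graph.node_ids
    n = len(ids)
    # Dense weight lookup: python nested lists are fastest for scalar access.
    index = {v: i for i, v in enumerate(ids)}
    W = [[0.0] * n for _ in range(n)]
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                W[i][j] = graph.weight(a, b)

    def fitness(perm: list[int]) -> float:
        total = 0.0
        for a, b in zip(perm, perm[1:]):
            total += W[a][b]
        return total

    pop = [list(rng.permutation(n)) for _ in range(params.population)]
    if params.population > 1:
        # Seed part of the population with the multi-start greedy paths so the
        # GA starts from, and can only improve on, the nearest-neighbour
        # solutions (the random majority preserves exploration).
        greedy_seeds = []
        for start in range(n):
            order = [start]
            remaining = set(range(n)) - {start}
            while remaining:
                here = order[-1]
                order.append(min(remaining, key=lambda j: (W[here][j], j)))
                remaining.remove(order[-1])
            greedy_seeds.append(order)
        greedy_seeds.sort(key=fitness)
        for k, seeded in enumerate(greedy_seeds[: max(1, params.population // 4)]):
            pop[-(k + 1)] = seeded
    fits = [fitness(p) for p in pop]
    for _ in range(params.generations):
        elite_idx = sorted(range(len(pop)), key=lambda i: fits[i])[: params.elitism]
        new_pop = [pop[i][:] for i in elite_idx]
        while len(new_pop) < params.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, params.population, size=params.tournament_size)
                winner = min(contenders, key=lambda i: fits[i])
                parents.append(pop[winner])
            if rng.random() < params.crossover_rate:
                child = _order_crossover(parents[0], parents[1], rng)
            else:
                child = parents[0][:]
            # Inversion mutation: reversing a random segment is a 2-opt move,
            # the natural neighbourhood for path weight, and escapes the
            # local minima that plain swaps leave untouched.
            for pos in range(n):
                if rng.random() < params.mutation_rate:
                    other = int(rng.integers(0, n))
                    lo, hi = min(pos, other), max(pos, other)
                    child[lo : hi + 1] = reversed(child[lo : hi + 1])
            new_pop.append(child)
        pop = new_pop
        fits = [fitness(p) for p in pop]
    best_i = min(range(len(pop)), key=lambda i: (fits[i], i))
    best_order = tuple(ids[k] for k in pop[best_i])
    return render_polyepitope(graph, best_order)


def solve(
    graph: DesignGraph,
    solver: str = "ga",
    params: Optional[GAParams] = None,
    seed: Optional[int] = None,
) -> PolyepitopeDesign:
    """Dispatch to one of the three ordering solvers by name."""
    if solver == "exhaustive":
        return solve_exhaustive(graph)
    if solver == "greedy":
        return solve_greedy(graph)
    if solver == "ga":
        return solve_ga(graph, params=params, seed=seed)
    raise ValueError(f"unknown solver {solver!r} (expected greedy, ga or exhaustive)")
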