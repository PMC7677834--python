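"""Conserved-complex assembly: cost function, greedy pruning, post-processing.

Given the k per-network minimum-conductance sets around one spine, the
candidate complex is scored by

    F = -( sum_j  2 E_j(S) / |S_j|  +  lambda * 2 Sim(S) / |S| )

where E_j(S) is the number of interactions among the selected proteins of
network j, |S_j| the number selected in network j, Sim(S) the sum of
similarity scores over selected unordered cross-network homolog pairs, and
|S| the total selection.  Both sums run over ordered pairs (hence the
factors 2): adjacency and similarity terms are summed in both orientations.
A per-network term with nothing selected contributes 0.  Starting from the
full candidate, the protein whose single removal lowers F the most is
deleted, repeatedly, until no removal strictly lowers F (steepest descent,
deterministic tie-break).  Post-processing removes exact duplicates, drops
complexes whose internal similarity sum falls below beta, and optionally
enforces a minimum per-species size.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .netio import (
    ConservedComplex,
    NetworkCollection,
    ProteinSpine,
    SimilarityMap,
)
from .separation import (
    DEFAULT_EXHAUSTIVE_CAP,
    DEFAULT_M,
    DEFAULT_RESTART,
    DEFAULT_TOLERANCE,
    extract_separated_set,
)
from .spines import SpineSet

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 10.0
DEFAULT_BETA = 0.1
DEFAULT_MIN_SIZE = 3


@dataclass
class ClusterMConfig:
    """Tunable parameters of the full pipeline.

    lambda_weight balances interaction density against cross-species
    homology (the values 1, 10 and 100 span the useful range; 10 is the
    default).  beta is the post-filter threshold on a complex's internal
    similarity sum.  min_size_per_species=0 disables the size filter.
    """

    m: int = DEFAULT_M
    restart: float = DEFAULT_RESTART
    tolerance: float = DEFAULT_TOLERANCE
    lambda_weight: float = DEFAULT_LAMBDA
    beta: float = DEFAULT_BETA
    min_size_per_species: int = DEFAULT_MIN_SIZE
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP
    mode: str = "mip"
    workers: int = 1
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.lambda_weight < 0 or self.beta < 0:
            raise ValueError("invalid configuration value")


@dataclass
class ComplexCandidate:
    """A pruning problem: k protein sets, their internal edges, and the
    cross-network similarity entries restricted to candidate members."""

    per_network_sets: list[list[str]]
    # (j, a, b) unordered within-network edges, a < b
    edges: list[tuple[int, str, str]]
    # ((j, a), (l, b)) -> s, stored once per unordered cross pair
    cross_pairs: dict[tuple[tuple[int, str], tuple[int, str]], float]
    lambda_weight: float = DEFAULT_LAMBDA
    source_spine: ProteinSpine | None = None
    selection: dict[tuple[int, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.selection:
            self.selection = {
                (j, p): 1
                for j, members in enumerate(self.per_network_sets)
                for p in members
            }

    @classmethod
    def from_separated_sets(
        cls,
        sets: list[set[str]],
        collection: NetworkCollection,
        sim: SimilarityMap,
        lambda_weight: float,
        source_spine: ProteinSpine | None = None,
    ) -> "ComplexCandidate":
        edges = []
        for j, members in enumerate(sets):
            graph = collection[j].graph
            for a in sorted(members):
                for b in graph.neighbors(a):
                    if b in members and a < b:
                        edges.append((j, a, b))
        cross: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
        k = len(sets)
        for j in range(k):
            for l in range(j + 1, k):
                for p, q, s in sim.pair_items(j, l):
                    if p in sets[j] and q in sets[l]:
                        cross[((j, p), (l, q))] = s
        return cls(
            per_network_sets=[sorted(s) for s in sets],
            edges=edges,
            cross_pairs=cross,
            lambda_weight=lambda_weight,
            source_spine=source_spine,
        )


def complex_cost(candidate: ComplexCandidate) -> float:
    """Value of the topology+homology objective for the current selection.

    Ordered-pair convention: a selected triangle contributes density 2 (i.e.
    2|E|/|S|), and every selected unordered homolog pair is counted twice in
    the similarity numerator.  Returns 0 when nothing is selected.
    """
    sel = candidate.selection
    k = len(candidate.per_network_sets)
    sizes = [0] * k
    for (j, p), v in sel.items():
        sizes[j] += v
    total = sum(sizes)
    if total == 0:
        return 0.0
    edge_counts = [0] * k
    for j, a, b in candidate.edges:
        if sel.get((j, a), 0) and sel.get((j, b), 0):
            edge_counts[j] += 1
    density = sum(
        (2.0 * edge_counts[j] / sizes[j]) for j in range(k) if sizes[j] > 0
    )
    sim_sum = sum(
        s
        for (a, b), s in candidate.cross_pairs.items()
        if sel.get(a, 0) and sel.get(b, 0)
    )
    homology = candidate.lambda_weight * 2.0 * sim_sum / total
    return -(density + homology)


class _PruneState:
    """Incrementally maintained statistics for O(1) removal evaluation."""

    def __init__(self, candidate: ComplexCandidate):
        self.cand = candidate
        self.k = len(candidate.per_network_sets)
        self.selected: set[tuple[int, str]] = {
            key for key, v in candidate.selection.items() if v
        }
        self.sizes = [0] * self.k
        for j, _ in self.selected:
            self.sizes[j] += 1
        self.edge_count = [0] * self.k  # selected-edge count per network
        self.sel_degree: dict[tuple[int, str], int] = {
            key: 0 for key in self.selected
        }
        self.adj: dict[tuple[int, str], list[tuple[int, str]]] = {
            key: [] for key in self.selected
        }
        for j, a, b in candidate.edges:
            ka, kb = (j, a), (j, b)
            if ka in self.selected and kb in self.selected:
                self.edge_count[j] += 1
                self.sel_degree[ka] += 1
                self.sel_degree[kb] += 1
                self.adj[ka].append(kb)
                self.adj[kb].append(ka)
        self.sim_total = 0.0
        self.sim_of: dict[tuple[int, str], float] = {key: 0.0 for key in self.selected}
        self.sim_adj: dict[tuple[int, str], list[tuple[tuple[int, str], float]]] = {
            key: [] for key in self.selected
        }
        for (a, b), s in candidate.cross_pairs.items():
            if a in self.selected and b in self.selected:
                self.sim_total += s
                self.sim_of[a] += s
                self.sim_of[b] += s
                self.sim_adj[a].append((b, s))
                self.sim_adj[b].append((a, s))

    def cost(self) -> float:
        total = sum(self.sizes)
        if total == 0:
            return 0.0
        density = sum(
            2.0 * self.edge_count[j] / self.sizes[j]
            for j in range(self.k)
            if self.sizes[j] > 0
        )
        homology = self.cand.lambda_weight * 2.0 * self.sim_total / total
        return -(density + homology)

    def cost_after_removal(self, key: tuple[int, str]) -> float:
        j = key[0]
        total = sum(self.sizes) - 1
        if total == 0:
            return 0.0
        density = 0.0
        for jj in range(self.k):
            size = self.sizes[jj] - (1 if jj == j else 0)
            edges = self.edge_count[jj] - (self.sel_degree[key] if jj == j else 0)
            if size > 0:
                density += 2.0 * edges / size
        sim = self.sim_total - self.sim_of[key]
        homology = self.cand.lambda_weight * 2.0 * sim / total
        return -(density + homology)

    def remove(self, key: tuple[int, str]) -> None:
        j = key[0]
        self.selected.discard(key)
        self.sizes[j] -= 1
        self.edge_count[j] -= self.sel_degree[key]
        for nb in self.adj[key]:
            if nb in self.selected:
                self.sel_degree[nb] -= 1
                self.adj[nb].remove(key)
        self.sim_total -= self.sim_of[key]
        for nb, s in self.sim_adj[key]:
            if nb in self.selected:
                self.sim_of[nb] -= s
                self.sim_adj[nb] = [(x, v) for x, v in self.sim_adj[nb] if x != key]
        del self.sel_degree[key]
        del self.adj[key]
        del self.sim_of[key]
        del self.sim_adj[key]


def greedy_prune(candidate: ComplexCandidate) -> ConservedComplex:
    """Steepest-descent pruning of a candidate complex.

    All proteins start selected; each step removes the protein whose
    deletion lowers the objective the most, with ties broken by (network
    index, protein ID); pruning stops when no single removal strictly
    lowers the objective.
    """
    state = _PruneState(candidate)
    current = state.cost()
    trace = [current]
    while state.selected:
        best_key: tuple[int, str] | None = None
        best_cost = float("inf")
        for key in sorted(state.selected):
            c = state.cost_after_removal(key)
            # strict < keeps the lexicographically first key on exact ties
            if c < best_cost - 1e-12:
                best_cost = c
                best_key = key
        if best_key is None or best_cost >= current - 1e-12:
            break
        state.remove(best_key)
        current = best_cost
        trace.append(current)

    sets: list[set[str]] = [set() for _ in range(state.k)]
    for j, p in state.selected:
        sets[j].add(p)
    sim_sum = sum(
        s
        for (a, b), s in candidate.cross_pairs.items()
        if a in state.selected and b in state.selected
    )
    return ConservedComplex(
        per_network_sets=sets,
        source_spine=candidate.source_spine,
        cost=current,
        internal_similarity_sum=sim_sum,
    )


def postprocess(
    complexes: list[ConservedComplex],
    beta: float = DEFAULT_BETA,
    min_size_per_species: int = 0,
) -> list[ConservedComplex]:
    """Duplicate removal, similarity-sum filter, optional size filter.

    Exact duplicates (all k protein sets equal) keep their first occurrence;
    complexes with internal similarity sum below ``beta`` are dropped, as
    are complexes with any species set smaller than ``min_size_per_species``
    (when positive).
    """
    seen: set[tuple[frozenset, ...]] = set()
    out: list[ConservedComplex] = []
    for cx in complexes:
        key = cx.key()
        if key in seen:
            continue
        seen.add(key)
        if cx.internal_similarity_sum < beta:
            continue
        if min_size_per_species > 0 and (
            cx.k == 0 or cx.min_species_size() < min_size_per_species
        ):
            continue
        out.append(cx)
    return out


def _process_spine(
    spine: ProteinSpine,
    collection: NetworkCollection,
    sim: SimilarityMap,
    config: ClusterMConfig,
) -> ConservedComplex:
    separated: list[set[str]] = []
    for j, seed in enumerate(spine.members):
        result = extract_separated_set(
            collection[j],
            seed,
            host_network_index=j,
            m=config.m,
            restart=config.restart,
            tolerance=config.tolerance,
            mode=config.mode,
            exhaustive_cap=config.exhaustive_cap,
        )
        separated.append(result.members)
    candidate = ComplexCandidate.from_separated_sets(
        separated, collection, sim, config.lambda_weight, source_spine=spine
    )
    return greedy_prune(candidate)


def run_clusterm(
    collection: NetworkCollection,
    sim: SimilarityMap,
    spines: SpineSet,
    config: ClusterMConfig | None = None,
) -> list[ConservedComplex]:
    """Full divide-and-conquer pipeline over a set of spines.

    Spines are processed independently (optionally by a worker pool) and the
    per-spine results are reassembled in spine order before post-processing,
    so the output is identical for any worker count.  A spine whose local
    search fails is skipped with a warning.
    """
    if config is None:
        config = ClusterMConfig()
    for spine in spines:
        spine.validate(collection)

    def safe(spine: ProteinSpine) -> ConservedComplex | None:
        try:
            return _process_spine(spine, collection, sim, config)
        except Exception:
            logger.exception("spine %s failed; skipped", spine.members)
            return None

    spine_list = list(spines)
    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(safe, spine_list))
    else:
        results = [safe(s) for s in spine_list]
    complexes = [cx for cx in results if cx is not None]
    return postprocess(
        complexes, beta=config.beta, min_size_per_species=config.min_size_per_species
    )
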