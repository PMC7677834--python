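"""Synthetic planted-complex worlds for offline testing and benchmarking.

A world consists of k PPI networks that each contain the same set of
planted modules (dense, well-separated protein groups, the topological
signature of protein complexes) embedded in an Erdős–Rényi background,
plus a cross-network similarity map in which index-aligned module proteins
are orthologs with high similarity and a sprinkling of decoy similarities
imitates spurious BLAST hits.  The ground-truth module memberships, one
seed spine per planted complex, and projections to reference pairs are all
returned, so every pipeline stage and metric can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .metrics import ReferencePair
from .netio import (
    DEFAULT_SIMILARITY_THRESHOLD,
    NetworkCollection,
    PPINetwork,
    ProteinSpine,
    SimilarityMap,
)
from .spines import SpineSet


@dataclass
class GeneratorParams:
    """Study conditions for the planted world.

    Defaults describe a two-species benchmark of 10 conserved complexes of
    5 proteins each, with near-clique modules (p_in=0.9), light leakage to
    a 200-protein background (p_out=0.02), a sparse background (mean degree
    ~2), and ortholog similarities centered at 0.6 — strong but imperfect
    homology, comfortably above the 0.1 reporting threshold.
    """

    k: int = 2
    n_complexes: int = 10
    size_min: int = 5
    size_max: int = 5
    p_in: float = 0.9
    p_out: float = 0.02
    background_nodes: int = 200
    background_edge_prob: float = 0.01
    ortholog_mean: float = 0.6
    ortholog_sd: float = 0.15
    decoy_rate: float = 0.0005
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.size_min < 3 or self.size_max < self.size_min:
            raise ValueError("complex sizes must be >= 3 with size_min <= size_max")
        if not self.p_in > self.p_out:
            raise ValueError("planted modules must be denser than their surroundings")
        if self.k < 2 or self.n_complexes < 1:
            raise ValueError("need k >= 2 networks and at least one complex")


@dataclass
class PlantedWorld:
    """A generated benchmark instance with its ground truth."""

    collection: NetworkCollection
    sim: SimilarityMap
    spines: SpineSet
    truth: list[list[set[str]]]  # per complex: one protein set per network
    generator_params: GeneratorParams = field(default_factory=GeneratorParams)


def generate(params: GeneratorParams | None = None, seed: int = 0) -> PlantedWorld:
    """Generate a planted world; fully deterministic given ``seed``.

    Per network: each planted module is an independent G(size, p_in) graph,
    every (module protein, background protein) pair is linked with
    probability p_out, and the background is G(n_bg, p_bg).  Across
    networks: index-aligned module proteins are orthologs with similarity
    drawn from a normal clipped to [threshold, 1]; decoy similarities are
    added at ``decoy_rate`` per non-ortholog cross pair.  Spines are the
    first protein of each module counterpart.
    """
    if params is None:
        params = GeneratorParams()
    rng = np.random.default_rng(seed)
    sizes = [
        int(rng.integers(params.size_min, params.size_max + 1))
        for _ in range(params.n_complexes)
    ]

    networks: list[PPINetwork] = []
    truth: list[list[set[str]]] = [[] for _ in range(params.n_complexes)]
    module_names: list[list[list[str]]] = []  # [net][complex] -> ordered names
    for j in range(params.k):
        tag = f"sp{j + 1}"
        graph = nx.Graph()
        per_net_modules: list[list[str]] = []
        bg = [f"{tag}_bg{t}" for t in range(params.background_nodes)]
        graph.add_nodes_from(bg)
        for i, size in enumerate(sizes):
            names = [f"{tag}_c{i}p{t}" for t in range(size)]
            graph.add_nodes_from(names)
            for a in range(size):
                for b in range(a + 1, size):
                    if rng.random() < params.p_in:
                        graph.add_edge(names[a], names[b])
            for name in names:
                for node in bg:
                    if rng.random() < params.p_out:
                        graph.add_edge(name, node)
            per_net_modules.append(names)
            truth[i].append(set(names))
        for a in range(params.background_nodes):
            for b in range(a + 1, params.background_nodes):
                if rng.random() < params.background_edge_prob:
                    graph.add_edge(bg[a], bg[b])
        networks.append(PPINetwork(tag, graph))
        module_names.append(per_net_modules)

    sim = SimilarityMap()
    ortholog_pairs: set[tuple[int, int, str, str]] = set()
    for j in range(params.k):
        for l in range(j + 1, params.k):
            for i, size in enumerate(sizes):
                for t in range(size):
                    p = module_names[j][i][t]
                    q = module_names[l][i][t]
                    s = float(
                        np.clip(
                            rng.normal(params.ortholog_mean, params.ortholog_sd),
                            params.similarity_threshold,
                            1.0,
                        )
                    )
                    sim.set(j, p, l, q, s)
                    ortholog_pairs.add((j, l, p, q))
            if params.decoy_rate > 0:
                left = sorted(networks[j].proteins)
                right = sorted(networks[l].proteins)
                n_pairs = len(left) * len(right)
                n_decoys = rng.binomial(n_pairs, params.decoy_rate)
                for _ in range(n_decoys):
                    p = left[int(rng.integers(len(left)))]
                    q = right[int(rng.integers(len(right)))]
                    if (j, l, p, q) in ortholog_pairs:
                        continue
                    s = float(rng.uniform(params.similarity_threshold, 0.5))
                    if s > sim.get(j, p, l, q):
                        sim.set(j, p, l, q, s)

    spines = SpineSet(
        [
            ProteinSpine(tuple(module_names[j][i][0] for j in range(params.k)))
            for i in range(params.n_complexes)
        ]
    )
    return PlantedWorld(
        collection=NetworkCollection(networks),
        sim=sim,
        spines=spines,
        truth=truth,
        generator_params=params,
    )


def truth_as_references(
    world: PlantedWorld, pair: tuple[int, int] = (0, 1)
) -> list[ReferencePair]:
    """Project the k-species ground truth onto one species pair."""
    j, l = pair
    return [
        ReferencePair(
            set_1=frozenset(cx[j]), set_2=frozenset(cx[l]), label=f"planted_{i}"
        )
        for i, cx in enumerate(world.truth)
    ]


def truth_as_references_all(
    world: PlantedWorld,
) -> dict[tuple[int, int], list[ReferencePair]]:
    """All C(k, 2) pairwise projections of the ground truth."""
    k = world.collection.k
    return {
        (j, l): truth_as_references(world, (j, l))
        for j in range(k)
        for l in range(j + 1, k)
    }


def write_world(world: PlantedWorld, directory: str) -> dict[str, str]:
    """Write a world in the package's file formats; returns the path map."""
    import os

    from . import netio

    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for j, network in enumerate(world.collection):
        path = os.path.join(directory, f"network_{network.species_tag}.tsv")
        netio.write_edge_list(network, path)
        paths[f"network_{j}"] = path
    tags = world.collection.species_tags
    for j, l in world.sim.network_pairs():
        path = os.path.join(directory, f"similarity_{tags[j]}_{tags[l]}.tsv")
        netio.write_similarity_tsv(world.sim, path, tags, network_pair=(j, l))
        paths[f"similarity_{j}_{l}"] = path
    spine_path = os.path.join(directory, "spines.tsv")
    netio.write_spines(list(world.spines), spine_path)
    paths["spines"] = spine_path
    truth_path = os.path.join(directory, "truth_complexes.txt")
    truth_cx = [
        netio.ConservedComplex(per_network_sets=[set(s) for s in cx])
        for cx in world.truth
    ]
    netio.write_complexes(truth_cx, truth_path)
    paths["truth"] = truth_path
    return paths
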