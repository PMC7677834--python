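"""Noise-injection harness and grid-search parameter sampler.

Topological noise is injected by degree-preserving double-edge swaps
(Maslov–Sneppen rewiring): two edges (a, b) and (c, d) are replaced by
(a, d) and (c, b) unless that would create a self-loop or duplicate edge.
Swapping continues until the requested fraction of the original edge set
has been displaced, so "10% noise" means at least 10% of the original
interactions are no longer present while every protein keeps its degree.
The same procedure applied to the cross-species similarity bipartite graph
perturbs homology: partners are exchanged between two similarity entries,
preserving both species' homology degree sequences.

The replicate harness runs a pipeline+evaluator under four conditions
(clean, topology-only, homology-only, both) and reports per-condition means
and standard deviations, plus the spread of the condition composite means.
The grid sampler spreads an evaluation budget N over k parameters with
n = floor(N^(1/k)) evenly spaced values each.
"""

from __future__ import annotations

import itertools
import logging
import statistics
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .netio import NetworkCollection, PPINetwork, SimilarityMap
from .metrics import ComplexMatchReport

logger = logging.getLogger(__name__)


@dataclass
class PerturbationSpec:
    """Noise levels and replication for a robustness run."""

    edge_fraction: float = 0.1
    homology_fraction: float = 0.1
    replicates: int = 10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_fraction <= 1.0 and 0.0 <= self.homology_fraction <= 1.0):
            raise ValueError("noise fractions must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class GridSpec:
    """Parameter ranges and total budget for grid sampling."""

    parameters: list[tuple[str, float, float]]
    budget: int = 100

    def __post_init__(self) -> None:
        for name, lo, hi in self.parameters:
            if not lo < hi:
                raise ValueError(f"parameter {name!r}: need min < max")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


def rewire_network(
    network: PPINetwork,
    fraction: float,
    rng: np.random.Generator,
    max_tries_factor: int = 100,
) -> PPINetwork:
    """Degree-preserving rewiring displacing ``fraction`` of the edges.

    Performs random double-edge swaps until the number of current edges not
    present in the original reaches ceil(fraction * |E|); swaps that would
    create self-loops or duplicate edges are rejected.  Graphs too small or
    rigid to reach the target within the retry cap return best effort with
    a warning.
    """
    new = network.copy()
    n_edges = new.n_edges
    if fraction <= 0 or n_edges < 2:
        return new
    target = int(np.ceil(fraction * n_edges))
    original = new.edges
    graph = new.graph

    def displaced() -> int:
        return sum(1 for e in graph.edges if frozenset(e) not in original)

    count = displaced()
    tries = 0
    max_tries = max_tries_factor * max(target, 1)
    while count < target and tries < max_tries:
        tries += 1
        edges = list(graph.edges)
        i1, i2 = rng.integers(0, len(edges), size=2)
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        # propose (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if graph.has_edge(a, d) or graph.has_edge(c, b):
            continue
        was_new_1 = frozenset((a, b)) not in original
        was_new_2 = frozenset((c, d)) not in original
        graph.remove_edge(a, b)
        graph.remove_edge(c, d)
        graph.add_edge(a, d)
        graph.add_edge(c, b)
        count -= int(was_new_1) + int(was_new_2)
        count += int(frozenset((a, d)) not in original)
        count += int(frozenset((c, b)) not in original)
    if count < target:
        logger.warning(
            "rewiring reached %d/%d displaced edges before the retry cap",
            count,
            target,
        )
    return new


def perturb_homology(
    sim: SimilarityMap,
    fraction: float,
    rng: np.random.Generator,
    max_tries_factor: int = 100,
) -> SimilarityMap:
    """Double-swap perturbation of the homology bipartite graph.

    Applied independently to every stored network pair: entries (p1, q1)
    and (p2, q2) become (p1, q2) and (p2, q1), each new pair inheriting the
    score of the original entry whose left endpoint it keeps.  Left and
    right homology degree sequences are preserved; the loop stops once the
    requested fraction of entries has been displaced.
    """
    out = SimilarityMap()
    for j, l in sim.network_pairs():
        entries = {(p, q): s for p, q, s in sim.pair_items(j, l)}
        original_pairs = set(entries)
        n = len(entries)
        if fraction <= 0 or n < 2:
            for (p, q), s in entries.items():
                out.set(j, p, l, q, s)
            continue
        target = int(np.ceil(fraction * n))
        count = 0
        tries = 0
        max_tries = max_tries_factor * max(target, 1)
        while count < target and tries < max_tries:
            tries += 1
            keys = sorted(entries)
            i1, i2 = rng.integers(0, len(keys), size=2)
            if i1 == i2:
                continue
            (p1, q1), (p2, q2) = keys[i1], keys[i2]
            if p1 == p2 or q1 == q2:
                continue
            if (p1, q2) in entries or (p2, q1) in entries:
                continue
            s1 = entries.pop((p1, q1))
            s2 = entries.pop((p2, q2))
            entries[(p1, q2)] = s1
            entries[(p2, q1)] = s2
            count = sum(1 for key in entries if key not in original_pairs)
        if count < target:
            logger.warning(
                "homology perturbation reached %d/%d displaced pairs", count, target
            )
        for (p, q), s in entries.items():
            out.set(j, p, l, q, s)
    return out


@dataclass
class RobustnessReport:
    """Per-condition score summaries from a replicate-and-average run."""

    conditions: dict[str, dict[str, float]] = field(default_factory=dict)
    composite_mean: float = 0.0
    composite_std: float = 0.0

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("condition\tmetric\tmean\tstd\n")
            for condition, stats in self.conditions.items():
                metrics = sorted({k.rsplit("_", 1)[0] for k in stats})
                for metric in metrics:
                    fh.write(
                        f"{condition}\t{metric}\t"
                        f"{stats[metric + '_mean']:.6f}\t{stats[metric + '_std']:.6f}\n"
                    )


def _summarize(reports: Sequence[ComplexMatchReport]) -> dict[str, float]:
    out: dict[str, float] = {}
    for metric in ("fraction", "sn", "ppv", "acc", "mmrc", "composite"):
        values = [report.as_dict()[metric] for report in reports]
        out[f"{metric}_mean"] = statistics.fmean(values)
        out[f"{metric}_std"] = statistics.pstdev(values) if len(values) > 1 else 0.0
    return out


def replicate_and_average(
    collection: NetworkCollection,
    sim: SimilarityMap,
    spec: PerturbationSpec,
    pipeline: Callable[[NetworkCollection, SimilarityMap], object],
    evaluator: Callable[[object], ComplexMatchReport],
    conditions: Sequence[str] = ("clean", "topology", "homology", "both"),
) -> RobustnessReport:
    """Run pipeline+evaluator under noise conditions and average the scores.

    ``pipeline`` maps (collection, sim) to predictions; ``evaluator`` maps
    predictions to a ComplexMatchReport.  The clean condition is run once
    (it is deterministic); noisy conditions are re-perturbed and re-run for
    every replicate with a seed derived from ``spec.random_seed``, so the
    whole procedure is reproducible.
    """
    report = RobustnessReport()
    composite_means: list[float] = []
    for condition in conditions:
        if condition == "clean":
            runs = [evaluator(pipeline(collection, sim))]
        else:
            runs = []
            for rep in range(spec.replicates):
                rng = np.random.default_rng(
                    [spec.random_seed, rep, list(conditions).index(condition)]
                )
                networks = collection.networks
                if condition in ("topology", "both") and spec.edge_fraction > 0:
                    networks = [
                        rewire_network(net, spec.edge_fraction, rng) for net in networks
                    ]
                noisy_sim = sim
                if condition in ("homology", "both") and spec.homology_fraction > 0:
                    noisy_sim = perturb_homology(sim, spec.homology_fraction, rng)
                noisy = NetworkCollection(networks)
                runs.append(evaluator(pipeline(noisy, noisy_sim)))
        stats = _summarize(runs)
        report.conditions[condition] = stats
        composite_means.append(stats["composite_mean"])
    report.composite_mean = statistics.fmean(composite_means)
    report.composite_std = (
        statistics.pstdev(composite_means) if len(composite_means) > 1 else 0.0
    )
    return report


def grid_sample(
    spec: GridSpec, mode: str = "even", seed: int = 0
) -> list[dict[str, float]]:
    """Cartesian grid of parameter vectors within an evaluation budget.

    Each of the k parameters gets n = floor(budget^(1/k)) values, so the
    grid size n^k never exceeds the budget.  With ``mode="even"`` (default)
    the values are evenly spaced including both endpoints — reproducible
    without bookkeeping; ``mode="random"`` draws them uniformly from the
    range with the given seed instead.  n < 1 (budget too small for k
    parameters) is an error.
    """
    k = len(spec.parameters)
    if k == 0:
        raise ValueError("grid needs at least one parameter")
    # exact integer k-th root, immune to FP rounding
    n = int(round(spec.budget ** (1.0 / k)))
    while (n + 1) ** k <= spec.budget:
        n += 1
    while n > 0 and n**k > spec.budget:
        n -= 1
    if n < 1:
        raise ValueError(f"budget {spec.budget} too small for {k} parameters")
    if mode not in ("even", "random"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    axes = []
    for name, lo, hi in spec.parameters:
        if mode == "random":
            values = sorted(rng.uniform(lo, hi, size=n))
        elif n == 1:
            values = [lo]
        else:
            values = list(np.linspace(lo, hi, n))
        axes.append([(name, float(v)) for v in values])
    return [dict(combo) for combo in itertools.product(*axes)]
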