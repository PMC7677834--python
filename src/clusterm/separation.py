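"""Local topological separation around a seed protein.

Implements the per-network half of the divide-and-conquer search: an
approximate personalized PageRank vector computed by a local push scheme
ranks the seed's neighborhood, the top-m proteins form the candidate set H,
and the exact minimum-conductance subset of H containing the seed is found
by mixed-integer programming (with an exhaustive enumerator as the small-
instance oracle and fallback).

Conductance of a selection S is measured against the host network:
phi(S) = |E(S, S-bar)| / vol(S) with vol(S) the sum of the members' degrees
in the full network.  Restricting the optimization to subsets of H while
keeping full-network degrees is what makes the problem non-degenerate: the
all-of-H selection is still charged for every edge leaving H, so a seed
module that is genuinely well separated wins only when it really is.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize as sco
import scipy.sparse as sp

from .netio import PPINetwork

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.15
DEFAULT_TOLERANCE = 1e-4
DEFAULT_M = 20
DEFAULT_EXHAUSTIVE_CAP = 15


@dataclass
class Neighborhood:
    """Top-m personalized-PageRank neighborhood of a seed in one network."""

    network: PPINetwork
    host_network_index: int
    seed: str
    members: list[str]
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a member of its neighborhood")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MinConductanceSet:
    """Seed-containing subset of a neighborhood with minimal conductance."""

    host_network_index: int
    seed: str
    members: set[str]
    conductance_value: float


def personalized_pagerank(
    network: PPINetwork,
    seed: str,
    restart: float = DEFAULT_RESTART,
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[str, float]:
    """Approximate personalized PageRank by local push.

    Maintains an approximation p and residual r with the invariant
    p + ppr(r) = ppr(seed); a node is pushed while its residual is at least
    ``tolerance`` times its degree, so the work is proportional to the size
    of the seed's local neighborhood rather than to the network.  Returned
    scores are non-negative and sum to at most 1.  A degree-0 seed gets unit
    mass on itself.
    """
    if not network.has_protein(seed):
        raise ValueError(f"seed {seed!r} not in network {network.species_tag!r}")
    if not 0.0 < restart < 1.0:
        raise ValueError("restart probability must be in (0, 1)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if network.degree(seed) == 0:
        return {seed: 1.0}

    graph = network.graph
    p: dict[str, float] = {}
    r: dict[str, float] = {seed: 1.0}
    queue = [seed]
    in_queue = {seed}
    while queue:
        u = queue.pop()
        in_queue.discard(u)
        ru = r.get(u, 0.0)
        du = graph.degree[u]
        if du == 0 or ru < tolerance * du:
            continue
        p[u] = p.get(u, 0.0) + restart * ru
        r[u] = 0.0
        share = (1.0 - restart) * ru / du
        for v in graph.neighbors(u):
            r[v] = r.get(v, 0.0) + share
            dv = graph.degree[v]
            if dv > 0 and r[v] >= tolerance * dv and v not in in_queue:
                queue.append(v)
                in_queue.add(v)
    return p


def pagerank_dense(
    network: PPINetwork, seed: str, restart: float = DEFAULT_RESTART
) -> dict[str, float]:
    """Exact personalized PageRank by solving the dense linear system
    (I - (1-restart) A D^{-1}) x = restart * e_seed.  Small networks only."""
    nodes = sorted(network.proteins)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = nx_adjacency(network, nodes)
    d = A.sum(axis=1)
    d[d == 0] = 1.0  # isolated nodes keep their mass via the restart
    W = A / d[np.newaxis, :]  # column-normalized: A D^{-1}
    e = np.zeros(n)
    e[idx[seed]] = 1.0
    x = np.linalg.solve(np.eye(n) - (1.0 - restart) * W, restart * e)
    return {nodes[i]: float(x[i]) for i in range(n)}


def nx_adjacency(network: PPINetwork, nodes: list[str]) -> np.ndarray:
    import networkx as nx

    return nx.to_numpy_array(network.graph, nodelist=nodes)


def top_m_neighborhood(
    network: PPINetwork,
    seed: str,
    scores: dict[str, float],
    m: int = DEFAULT_M,
    host_network_index: int = 0,
) -> Neighborhood:
    """Seed plus the m-1 highest-scoring other proteins.

    Ties are broken by higher degree, then lexicographic protein ID; if
    fewer than m proteins carry positive score, all of them are returned.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    others = [
        p for p, s in scores.items() if p != seed and s > 0.0 and network.has_protein(p)
    ]
    others.sort(key=lambda p: (-scores[p], -network.degree(p), p))
    members = [seed] + others[: m - 1]
    return Neighborhood(
        network=network,
        host_network_index=host_network_index,
        seed=seed,
        members=members,
        scores={p: scores.get(p, 0.0) for p in members},
    )


def conductance(network: PPINetwork, subset: set[str] | list[str], strict: bool = False) -> float:
    """Conductance of a protein set in its network.

    Returns |E(S, S-bar)| / vol(S); with ``strict`` the denominator is
    min(vol(S), vol(S-bar)) instead.  A zero denominator returns 1 by
    convention.  The empty set is an error.
    """
    members = set(subset)
    if not members:
        raise ValueError("conductance of an empty set is undefined")
    for p in members:
        if not network.has_protein(p):
            raise ValueError(f"protein {p!r} not in network")
    graph = network.graph
    vol = sum(graph.degree[p] for p in members)
    boundary = sum(
        1 for p in members for q in graph.neighbors(p) if q not in members
    )
    denom = vol
    if strict:
        vol_rest = 2 * graph.number_of_edges() - vol
        denom = min(vol, vol_rest)
    if denom == 0:
        return 1.0
    return boundary / denom


def _subset_conductance(
    degrees: dict[str, int], internal_adj: dict[str, set[str]], members: set[str]
) -> float:
    """phi within the host network for a subset of a neighborhood, computed
    from full-network degrees and neighborhood-internal adjacency."""
    vol = sum(degrees[p] for p in members)
    internal = sum(
        1 for p in members for q in internal_adj[p] if q in members
    )  # ordered count = 2|E(S)|
    if vol == 0:
        return 1.0
    return (vol - internal) / vol


def _tie_key(members: set[str]) -> tuple[int, list[str]]:
    return (-len(members), sorted(members))


def _exhaustive_min_conductance(
    neighborhood: Neighborhood,
    degrees: dict[str, int],
    internal_adj: dict[str, set[str]],
) -> tuple[set[str], float]:
    seed = neighborhood.seed
    others = sorted(p for p in neighborhood.members if p != seed)
    best_members: set[str] | None = None
    best_phi = float("inf")
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            members = {seed, *combo}
            phi = _subset_conductance(degrees, internal_adj, members)
            if phi < best_phi or (
                phi == best_phi
                and best_members is not None
                and _tie_key(members) < _tie_key(best_members)
            ):
                best_phi = phi
                best_members = members
    assert best_members is not None
    return best_members, best_phi


def _mip_min_conductance(
    neighborhood: Neighborhood,
    degrees: dict[str, int],
    internal_adj: dict[str, set[str]],
) -> tuple[set[str], float] | None:
    """Exact MILP for min_{S in H, seed in S} cut(S)/vol(S).

    The fractional objective is handled by an auxiliary level variable z and
    the bilinear products z*x_i and x_i*x_j are linearized with standard
    McCormick envelopes, leaving a mixed-integer linear program solved by
    HiGHS.  Returns None on solver failure.
    """
    nodes = sorted(neighborhood.members)
    idx = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    d = np.array([degrees[p] for p in nodes], dtype=float)
    edges = sorted(
        (idx[p], idx[q])
        for p in nodes
        for q in internal_adj[p]
        if q in idx and idx[p] < idx[q]
    )
    ne = len(edges)
    # variable layout: x (n, binary), z (1), w = z*x (n), y_e = x_i*x_j (ne)
    nz = n
    nw = n + 1
    ny = n + 1 + n
    nvar = n + 1 + n + ne

    c = np.zeros(nvar)
    c[nz] = 1.0  # minimize z

    rows: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_row(coeffs: dict[int, float], lb: float, ub: float) -> None:
        row = np.zeros(nvar)
        for j, v in coeffs.items():
            row[j] = v
        rows.append(row)
        lbs.append(lb)
        ubs.append(ub)

    if d.sum() == 0:
        # every selection has zero volume, hence conductance 1 by convention;
        # ties go to the larger subset
        return set(nodes), 1.0

    # vol(S) >= 1 rules out the degenerate zero-volume selections the level
    # constraint below would otherwise satisfy vacuously at z = 0
    add_row({i: d[i] for i in range(n)}, 1.0, np.inf)

    # cut(S) <= z * vol(S):  sum d_i x_i - 2 sum_e y_e - sum d_i w_i <= 0
    coeffs = {i: d[i] for i in range(n)}
    for e, _ in enumerate(edges):
        coeffs[ny + e] = coeffs.get(ny + e, 0.0) - 2.0
    for i in range(n):
        coeffs[nw + i] = coeffs.get(nw + i, 0.0) - d[i]
    add_row(coeffs, -np.inf, 0.0)

    # w_i = z * x_i   (McCormick, z in [0,1], x binary)
    for i in range(n):
        add_row({nw + i: 1.0, nz: -1.0}, -np.inf, 0.0)  # w <= z
        add_row({nw + i: 1.0, i: -1.0}, -np.inf, 0.0)  # w <= x
        add_row({nw + i: 1.0, nz: -1.0, i: -1.0}, -1.0, np.inf)  # w >= z + x - 1

    # y_e = x_i * x_j
    for e, (i, j) in enumerate(edges):
        add_row({ny + e: 1.0, i: -1.0}, -np.inf, 0.0)
        add_row({ny + e: 1.0, j: -1.0}, -np.inf, 0.0)
        add_row({ny + e: 1.0, i: -1.0, j: -1.0}, -1.0, np.inf)

    lower = np.zeros(nvar)
    upper = np.ones(nvar)
    seed_i = idx[neighborhood.seed]
    lower[seed_i] = 1.0  # seed fixed in
    integrality = np.zeros(nvar)
    integrality[:n] = 1  # x binary; z, w, y continuous

    try:
        res = sco.milp(
            c=c,
            constraints=sco.LinearConstraint(
                sp.csr_matrix(np.vstack(rows)), np.array(lbs), np.array(ubs)
            ),
            integrality=integrality,
            bounds=sco.Bounds(lower, upper),
            options={"mip_rel_gap": 0.0, "presolve": True},
        )
    except Exception:  # pragma: no cover - solver-side failure
        logger.exception("MILP solve raised")
        return None
    if not res.success or res.x is None:  # pragma: no cover
        logger.warning("MILP solve failed: %s", getattr(res, "message", "?"))
        return None
    members = {nodes[i] for i in range(n) if res.x[i] > 0.5}
    members.add(neighborhood.seed)
    # re-evaluate exactly; the solver's z carries FP slack
    phi = _subset_conductance(degrees, internal_adj, members)
    return members, phi


def _sweep_cut(
    neighborhood: Neighborhood,
    degrees: dict[str, int],
    internal_adj: dict[str, set[str]],
) -> tuple[set[str], float]:
    """Best prefix of the PageRank ordering; last-resort fallback."""
    order = sorted(
        neighborhood.members,
        key=lambda p: (p != neighborhood.seed, -neighborhood.scores.get(p, 0.0), p),
    )
    best_members: set[str] = {neighborhood.seed}
    best_phi = _subset_conductance(degrees, internal_adj, best_members)
    prefix: set[str] = set()
    for p in order:
        prefix.add(p)
        phi = _subset_conductance(degrees, internal_adj, prefix)
        if phi < best_phi:
            best_phi = phi
            best_members = set(prefix)
    return best_members, best_phi


def min_conductance_subset(
    neighborhood: Neighborhood,
    mode: str = "mip",
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> MinConductanceSet:
    """Exact minimum-conductance subset of a neighborhood containing its seed.

    ``mode`` is "mip" (MILP, any size) or "exhaustive" (enumeration of all
    seed-containing subsets; the small-instance oracle).  Selections with
    zero volume score 1 (worst).  Exact ties go to the larger subset, then
    the lexicographically smallest sorted member list.  If the MILP solver
    fails, enumeration is used when the neighborhood is within
    ``exhaustive_cap``, else the best PageRank sweep cut with a warning.
    """
    network = neighborhood.network
    degrees = {p: network.degree(p) for p in neighborhood.members}
    member_set = set(neighborhood.members)
    internal_adj = {
        p: {q for q in network.neighbors(p) if q in member_set}
        for p in neighborhood.members
    }
    if mode == "exhaustive":
        members, phi = _exhaustive_min_conductance(neighborhood, degrees, internal_adj)
    elif mode == "mip":
        result = _mip_min_conductance(neighborhood, degrees, internal_adj)
        if result is None:
            if len(neighborhood) <= exhaustive_cap:
                members, phi = _exhaustive_min_conductance(
                    neighborhood, degrees, internal_adj
                )
            else:
                logger.warning(
                    "MILP failed on |H|=%d; falling back to sweep cut", len(neighborhood)
                )
                members, phi = _sweep_cut(neighborhood, degrees, internal_adj)
        else:
            members, phi = result
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MinConductanceSet(
        host_network_index=neighborhood.host_network_index,
        seed=neighborhood.seed,
        members=members,
        conductance_value=phi,
    )


def extract_separated_set(
    network: PPINetwork,
    seed: str,
    host_network_index: int = 0,
    m: int = DEFAULT_M,
    restart: float = DEFAULT_RESTART,
    tolerance: float = DEFAULT_TOLERANCE,
    mode: str = "mip",
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> MinConductanceSet:
    """Convenience: PageRank -> top-m neighborhood -> min-conductance subset."""
    scores = personalized_pagerank(network, seed, restart=restart, tolerance=tolerance)
    hood = top_m_neighborhood(
        network, seed, scores, m=m, host_network_index=host_network_index
    )
    return min_conductance_subset(hood, mode=mode, exhaustive_cap=exhaustive_cap)
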