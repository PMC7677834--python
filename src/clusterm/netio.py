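"""Core data model and file I/O.

Containers for PPI networks, cross-species sequence-similarity maps, protein
spines, conserved complexes, and GO annotation tables, together with readers
and writers for the plain-text formats the rest of the package exchanges:

* edge lists — two whitespace-separated columns, ``#`` comments;
* similarity — three-column TSV (protein_a, protein_b, score) with a header
  line naming the two species tags, or BLAST tabular (outfmt-6-like, bit
  score in the last column) plus a two-column self-score file;
* spines — k-column TSV, one protein per species per row;
* complexes — one complex per line, k semicolon-separated blocks of
  comma-separated proteins, blocks aligned with the species order;
* GO annotations — GAF 2.x.

Protein identifiers are opaque strings; no accession mapping is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: default cutoff below which normalized sequence-similarity scores are dropped
DEFAULT_SIMILARITY_THRESHOLD = 0.1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class PPINetwork:
    """An undirected, simple protein-protein interaction network.

    Backed by a :class:`networkx.Graph`; self-loops are never stored and
    parallel edge lines collapse to one edge.  Isolated proteins (degree 0)
    are allowed.
    """

    def __init__(self, species_tag: str, graph: nx.Graph | None = None):
        self.species_tag = species_tag
        self.graph = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)

    @property
    def proteins(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, protein: str) -> int:
        return self.graph.degree[protein]

    def has_protein(self, protein: str) -> bool:
        return protein in self.graph

    def neighbors(self, protein: str) -> list[str]:
        return list(self.graph.neighbors(protein))

    def copy(self) -> "PPINetwork":
        return PPINetwork(self.species_tag, self.graph.copy())

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PPINetwork({self.species_tag!r}, {self.n_proteins} proteins, "
            f"{self.n_edges} interactions)"
        )


@dataclass
class NetworkCollection:
    """Ordered list of the k networks under joint analysis."""

    networks: list[PPINetwork]

    def __post_init__(self) -> None:
        tags = [n.species_tag for n in self.networks]
        if len(set(tags)) != len(tags):
            raise ValueError(f"species tags must be unique, got {tags}")
        if len(self.networks) < 2:
            raise ValueError("a NetworkCollection needs at least two networks")

    @property
    def k(self) -> int:
        return len(self.networks)

    @property
    def species_tags(self) -> list[str]:
        return [n.species_tag for n in self.networks]

    def index_of(self, tag: str) -> int:
        return self.species_tags.index(tag)

    def __getitem__(self, j: int) -> PPINetwork:
        return self.networks[j]

    def __iter__(self) -> Iterator[PPINetwork]:
        return iter(self.networks)


class SimilarityMap:
    """Sparse normalized cross-network sequence-similarity scores.

    Scores s(p, q) in [0, 1] are stored once per unordered cross-network
    protein pair, keyed by the ordered network-index pair (j, l) with j < l;
    lookups are symmetric and an absent pair scores 0.
    """

    def __init__(self) -> None:
        # (j, l) with j < l  ->  {(p, q): score}
        self._pairs: dict[tuple[int, int], dict[tuple[str, str], float]] = {}

    @staticmethod
    def _canon(j: int, p: str, l: int, q: str) -> tuple[int, int, str, str]:
        if j == l:
            raise ValueError("similarity is only defined across networks")
        if j < l:
            return j, l, p, q
        return l, j, q, p

    def set(self, j: int, p: str, l: int, q: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"similarity score {score} outside [0, 1]")
        a, b, p2, q2 = self._canon(j, p, l, q)
        self._pairs.setdefault((a, b), {})[(p2, q2)] = score

    def get(self, j: int, p: str, l: int, q: str) -> float:
        a, b, p2, q2 = self._canon(j, p, l, q)
        return self._pairs.get((a, b), {}).get((p2, q2), 0.0)

    def pair_items(self, j: int, l: int) -> list[tuple[str, str, float]]:
        """All stored (p_in_j, q_in_l, score) entries for a network pair."""
        a, b = (j, l) if j < l else (l, j)
        entries = self._pairs.get((a, b), {})
        if j < l:
            return sorted((p, q, s) for (p, q), s in entries.items())
        return sorted((q, p, s) for (p, q), s in entries.items())

    def network_pairs(self) -> list[tuple[int, int]]:
        return sorted(self._pairs)

    def partners(self, j: int, p: str, l: int) -> list[tuple[str, float]]:
        """Proteins of network ``l`` with a stored score against ``p``."""
        return sorted(
            (q, s) for (pp, q, s) in self.pair_items(j, l) if pp == p
        )

    def n_entries(self) -> int:
        return sum(len(v) for v in self._pairs.values())

    def copy(self) -> "SimilarityMap":
        new = SimilarityMap()
        for key, entries in self._pairs.items():
            new._pairs[key] = dict(entries)
        return new


@dataclass(frozen=True)
class ProteinSpine:
    """A tuple of k proteins, one per network, used as a cross-species seed."""

    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)

    def validate(self, collection: NetworkCollection) -> None:
        if len(self.members) != collection.k:
            raise ValueError(
                f"spine has {len(self.members)} members for k={collection.k}"
            )
        for j, p in enumerate(self.members):
            if not collection[j].has_protein(p):
                raise ValueError(
                    f"spine protein {p!r} not in network "
                    f"{collection[j].species_tag!r}"
                )


@dataclass
class ConservedComplex:
    """A predicted conserved complex: one protein set per network.

    ``cost`` is the (negative) value of the topology+homology objective the
    greedy pruner minimized; ``internal_similarity_sum`` is the sum of stored
    similarity scores over cross-network pairs with both endpoints selected,
    counted once per unordered pair — the quantity the β post-filter
    thresholds.
    """

    per_network_sets: list[set[str]]
    source_spine: ProteinSpine | None = None
    cost: float = 0.0
    internal_similarity_sum: float = 0.0

    @property
    def k(self) -> int:
        return len(self.per_network_sets)

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self.per_network_sets)

    def min_species_size(self) -> int:
        return min(len(s) for s in self.per_network_sets)

    def key(self) -> tuple[frozenset, ...]:
        """Canonical identity used for exact-duplicate removal."""
        return tuple(frozenset(s) for s in self.per_network_sets)

    def all_proteins(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_network_sets:
            out |= s
        return out


@dataclass
class AnnotationTable:
    """GO annotations for one species' proteins.

    ``assignments`` maps a protein to its annotated GO term identifiers;
    ``evidence`` records every evidence code seen for a (protein, term)
    pair; ``aspects`` records each term's root namespace (P, F or C).
    """

    assignments: dict[str, set[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    aspects: dict[str, str] = field(default_factory=dict)

    def add(self, protein: str, term: str, evidence_code: str, aspect: str) -> None:
        self.assignments.setdefault(protein, set()).add(term)
        self.evidence.setdefault((protein, term), set()).add(evidence_code)
        self.aspects[term] = aspect

    def filtered(self, excluded_evidence: set[str]) -> "AnnotationTable":
        """Copy with (protein, term) pairs dropped when every supporting
        evidence code is excluded."""
        out = AnnotationTable()
        for (protein, term), codes in self.evidence.items():
            kept = codes - excluded_evidence
            if not kept:
                continue
            for code in sorted(kept):
                out.add(protein, term, code, self.aspects.get(term, ""))
        return out

    def term_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for protein, terms in self.assignments.items():
            for term in terms:
                sizes[term] = sizes.get(term, 0) + 1
        return sizes

    def root_sizes(self) -> dict[str, int]:
        """Number of distinct annotated proteins per root namespace."""
        roots: dict[str, set[str]] = {}
        for protein, terms in self.assignments.items():
            for term in terms:
                roots.setdefault(self.aspects.get(term, ""), set()).add(protein)
        return {aspect: len(members) for aspect, members in roots.items()}

    def terms_of(self, protein: str) -> set[str]:
        return set(self.assignments.get(protein, set()))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def read_edge_list(path: str, species_tag: str) -> PPINetwork:
    """Read a two-column edge-list file into a simple undirected network.

    Lines beginning ``#`` are comments; duplicate edges collapse; self-loop
    lines are dropped with a warning.  A line with fewer than two columns is
    a format error naming the line number.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(cols)}"
                )
            a, b = cols[0], cols[1]
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    return PPINetwork(species_tag, graph)


def write_edge_list(network: PPINetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# species: {network.species_tag}\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")
        for p in sorted(network.proteins):
            if network.degree(p) == 0:
                fh.write(f"{p}\t{p}\n")  # read back as an isolate


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def normalize_bitscores(
    hits: Iterable[tuple[str, str, float]],
    self_scores: Mapping[str, float],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    network_pair: tuple[int, int] = (0, 1),
) -> SimilarityMap:
    """Turn raw BLAST bit scores into normalized similarities.

    s(p, q) = blast(p, q) / sqrt(blast(p, p) * blast(q, q)); the highest bit
    score is kept when a pair is hit more than once, and entries with
    s < ``threshold`` are discarded.  Self bit scores must be available and
    positive for every protein occurring in ``hits``.
    """
    j, l = network_pair
    best: dict[tuple[str, str], float] = {}
    for p, q, bitscore in hits:
        key = (p, q)
        if bitscore > best.get(key, float("-inf")):
            best[key] = bitscore
    sim = SimilarityMap()
    for (p, q), bitscore in best.items():
        for prot in (p, q):
            if prot not in self_scores:
                raise ValueError(f"missing self bit score for protein {prot!r}")
            if self_scores[prot] <= 0:
                raise ValueError(f"non-positive self bit score for {prot!r}")
        s = bitscore / math.sqrt(self_scores[p] * self_scores[q])
        s = min(s, 1.0)
        if s >= threshold:
            existing = sim.get(j, p, l, q)
            if s > existing:
                sim.set(j, p, l, q, s)
    return sim


def read_blast_tab(path: str) -> list[tuple[str, str, float]]:
    """Read BLAST tabular output (outfmt-6-like); bit score = last column."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected BLAST tabular with >=3 columns"
                )
            hits.append((cols[0], cols[1], float(cols[-1])))
    return hits


def read_self_scores(path: str) -> dict[str, float]:
    """Two-column TSV: protein, self bit score."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[cols[0]] = float(cols[1])
    return out


def write_similarity_tsv(
    sim: SimilarityMap,
    path: str,
    species_tags: Sequence[str],
    network_pair: tuple[int, int] = (0, 1),
) -> None:
    j, l = network_pair
    with open(path, "w") as fh:
        fh.write(f"#similarity\t{species_tags[j]}\t{species_tags[l]}\n")
        for p, q, s in sim.pair_items(j, l):
            fh.write(f"{p}\t{q}\t{s:.6g}\n")


def read_similarity_tsv(
    path: str,
    collection: NetworkCollection | None = None,
    network_pair: tuple[int, int] | None = None,
) -> tuple[SimilarityMap, tuple[str, str]]:
    """Read a 3-column similarity TSV.

    The header line ``#similarity<TAB>tag_a<TAB>tag_b`` names the two species;
    when a ``collection`` is given the tags are resolved against it, otherwise
    ``network_pair`` (default (0, 1)) fixes the indices.  Returns the map and
    the (tag_a, tag_b) pair.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}: missing species-tag header line")
    header = lines[0].lstrip("#").strip().split("\t")
    if len(header) == 3 and header[0] == "similarity":
        tag_a, tag_b = header[1], header[2]
    elif len(header) >= 2:
        tag_a, tag_b = header[-2], header[-1]
    else:
        raise FormatError(f"{path}: header must name two species tags")
    if collection is not None:
        j, l = collection.index_of(tag_a), collection.index_of(tag_b)
    else:
        j, l = network_pair if network_pair is not None else (0, 1)
    sim = SimilarityMap()
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        sim.set(j, cols[0], l, cols[1], float(cols[2]))
    return sim, (tag_a, tag_b)


def merge_similarity(maps: Iterable[SimilarityMap]) -> SimilarityMap:
    """Union of several per-pair maps into one multi-pair map."""
    out = SimilarityMap()
    for sim in maps:
        for j, l in sim.network_pairs():
            for p, q, s in sim.pair_items(j, l):
                out.set(j, p, l, q, s)
    return out


# ---------------------------------------------------------------------------
# spines
# ---------------------------------------------------------------------------


def write_spines(spines: Sequence[ProteinSpine], path: str) -> None:
    with open(path, "w") as fh:
        for spine in spines:
            fh.write("\t".join(spine.members) + "\n")


def read_spines(path: str, k: int | None = None) -> list[ProteinSpine]:
    """Read a k-column TSV of spines; a row with the wrong arity is an error."""
    spines: list[ProteinSpine] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if k is not None and len(cols) != k:
                raise FormatError(
                    f"{path}:{lineno}: spine has {len(cols)} columns, expected {k}"
                )
            spines.append(ProteinSpine(tuple(cols)))
    return spines


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------


def write_complexes(complexes: Sequence[ConservedComplex], path: str) -> None:
    """One complex per line: k semicolon-separated blocks of comma-separated
    proteins, blocks aligned with the species order."""
    with open(path, "w") as fh:
        for cx in complexes:
            blocks = [",".join(sorted(s)) for s in cx.per_network_sets]
            fh.write(";".join(blocks) + "\n")


def read_complexes(path: str, k: int | None = None) -> list[ConservedComplex]:
    out: list[ConservedComplex] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            blocks = line.split(";")
            if k is not None and len(blocks) != k:
                raise FormatError(
                    f"{path}:{lineno}: complex has {len(blocks)} blocks, expected {k}"
                )
            sets = [
                {p for p in block.split(",") if p} for block in blocks
            ]
            out.append(ConservedComplex(per_network_sets=sets))
    return out


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------


def read_gaf(path: str) -> AnnotationTable:
    """Read a GAF 2.x association file.

    Uses the DB object ID (column 2) as the protein identifier, the GO ID
    (column 5), the evidence code (column 7) and the aspect (column 9).
    ``NOT``-qualified associations are skipped; evidence codes are retained
    verbatim for later filtering.
    """
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(
                    f"{path}:{lineno}: GAF line has {len(cols)} columns, expected >=9"
                )
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            protein, term, evidence_code, aspect = cols[1], cols[4], cols[6], cols[8]
            table.add(protein, term, evidence_code, aspect)
    return table
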