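"""Protein-spine construction and loading.

A spine is a tuple of k proteins, one per network, that seeds the local
search for a conserved complex.  Spines are normally produced by a multiple
network aligner; this module accepts such output from file and also provides
a deterministic internal builder based on greedy reciprocal-best-hit
chaining through the networks in input order, so the pipeline can run
without an external aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .netio import NetworkCollection, ProteinSpine, SimilarityMap, read_spines

logger = logging.getLogger(__name__)


@dataclass
class SpineSet:
    """An ordered, duplicate-free list of spines."""

    spines: list[ProteinSpine] = field(default_factory=list)

    @property
    def h(self) -> int:
        return len(self.spines)

    def __iter__(self):
        return iter(self.spines)

    def __len__(self) -> int:
        return len(self.spines)


def _best_partner(
    sim: SimilarityMap,
    j: int,
    p: str,
    l: int,
    used: set[tuple[int, str]],
) -> str | None:
    """Highest-similarity partner of p (network j) in network l that is not
    already used in a spine; ties broken lexicographically by protein ID."""
    best: str | None = None
    best_score = 0.0
    for q, s in sim.partners(j, p, l):
        if (l, q) in used or s <= 0.0:
            continue
        if s > best_score or (s == best_score and best is not None and q < best):
            best, best_score = q, s
    return best


def build_spines(
    collection: NetworkCollection,
    sim: SimilarityMap,
    max_spines: int | None = None,
) -> SpineSet:
    """Build spines by greedy reciprocal-best-hit chaining.

    Proteins of network 1 are visited in lexicographic order; each chain is
    extended through networks 2..k by taking the highest-similarity unused
    partner, and the hop is accepted only if it is a reciprocal best hit
    among unused proteins.  A spine is emitted only when all k slots fill,
    and every protein participates in at most one built spine.  The result
    is deterministic for identical inputs.
    """
    k = collection.k
    used: set[tuple[int, str]] = set()
    spines: list[ProteinSpine] = []
    for p0 in sorted(collection[0].proteins):
        if max_spines is not None and len(spines) >= max_spines:
            break
        if (0, p0) in used:
            continue
        chain = [p0]
        ok = True
        for l in range(1, k):
            j = l - 1
            q = _best_partner(sim, j, chain[-1], l, used)
            if q is None:
                ok = False
                break
            back = _best_partner(sim, l, q, j, used)
            if back != chain[-1]:
                ok = False
                break
            chain.append(q)
        if not ok:
            continue
        for l, prot in enumerate(chain):
            used.add((l, prot))
        spines.append(ProteinSpine(tuple(chain)))
    return SpineSet(spines)


def load_spines(path: str, collection: NetworkCollection) -> SpineSet:
    """Load and validate a k-column spine file (e.g. aligner output).

    Unknown proteins are errors naming the row and column; duplicated rows
    are dropped with a warning.
    """
    rows = read_spines(path, k=collection.k)
    seen: set[tuple[str, ...]] = set()
    spines: list[ProteinSpine] = []
    for row_idx, spine in enumerate(rows, start=1):
        for col_idx, p in enumerate(spine.members):
            if not collection[col_idx].has_protein(p):
                raise ValueError(
                    f"{path}: row {row_idx}, column {col_idx + 1}: protein "
                    f"{p!r} not in network {collection[col_idx].species_tag!r}"
                )
        if spine.members in seen:
            logger.warning("%s: row %d duplicates an earlier spine; dropped", path, row_idx)
            continue
        seen.add(spine.members)
        spines.append(spine)
    return SpineSet(spines)
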