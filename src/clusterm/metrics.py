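"""Evaluation metrics for conserved-complex prediction.

Pairwise (two-species) prediction quality is summarized by:

* fraction — share of reference conserved complexes matched by at least one
  prediction, where a match needs neighborhood affinity
  w(X, Y) = |X∩Y|²/(|X||Y|) ≥ tau in both species simultaneously;
* Sn / PPV / Acc — complex-wise sensitivity and positive predictive value
  from reference-vs-prediction protein overlap counts, and their geometric
  mean;
* MMRC — maximum-weight one-to-one matching between references and
  predictions, with pair weight the harmonic mean of the two per-species
  affinities, divided by the number of references;
* composite — fraction + Acc + MMRC, in [0, 3].

Functional coherence of predictions (any k) is summarized by the mean
normalized entropy (MNE) of high-level GO term assignments (lower is more
coherent) and by coverage, the number of distinct proteins in qualifying
complexes.  High-level terms are those with information content
-log(|term|/|root|) above a threshold after excluding circular evidence
codes (electronic annotation, protein interaction, sequence similarity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .netio import AnnotationTable, ConservedComplex

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.25
DEFAULT_IC_THRESHOLD = 2.0
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA", "IPI", "ISS"})


@dataclass(frozen=True)
class ReferencePair:
    """A reference conserved complex: one protein set per species."""

    set_1: frozenset
    set_2: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        if not self.set_1 or not self.set_2:
            raise ValueError("reference sets must be non-empty")


@dataclass
class ComplexMatchReport:
    """Bundle of the pairwise prediction-quality scores."""

    fraction: float
    sn: float
    ppv: float
    acc: float
    mmrc: float

    @property
    def composite(self) -> float:
        return self.fraction + self.acc + self.mmrc

    def as_dict(self) -> dict[str, float]:
        return {
            "fraction": self.fraction,
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
            "mmrc": self.mmrc,
            "composite": self.composite,
        }


def neighborhood_affinity(X: Iterable, Y: Iterable) -> float:
    """|X∩Y|² / (|X|·|Y|); both sets must be non-empty."""
    xs, ys = set(X), set(Y)
    if not xs or not ys:
        raise ValueError("neighborhood affinity of an empty set is undefined")
    inter = len(xs & ys)
    return inter * inter / (len(xs) * len(ys))


def _prediction_sets(prediction: ConservedComplex) -> tuple[set[str], set[str]]:
    if prediction.k != 2:
        raise ValueError("pairwise metrics require two-species predictions")
    return prediction.per_network_sets[0], prediction.per_network_sets[1]


def fraction_matched(
    references: Sequence[ReferencePair],
    predictions: Sequence[ConservedComplex],
    tau: float = DEFAULT_TAU,
) -> float:
    """Fraction of references matched at affinity >= tau in both species."""
    if not references:
        raise ValueError("empty reference list")
    matched = 0
    for ref in references:
        for pred in predictions:
            b1, b2 = _prediction_sets(pred)
            if not b1 or not b2:
                continue
            if (
                neighborhood_affinity(ref.set_1, b1) >= tau
                and neighborhood_affinity(ref.set_2, b2) >= tau
            ):
                matched += 1
                break
    return matched / len(references)


def accuracy_scores(
    references: Sequence[ReferencePair],
    predictions: Sequence[ConservedComplex],
) -> tuple[float, float, float]:
    """Complex-wise sensitivity, positive predictive value, and geometric
    accuracy.

    t_ij = |A1_j ∩ B1_i| + |A2_j ∩ B2_i| counts shared proteins species by
    species; w_j = |A1_j| + |A2_j| (the species-disjoint union).  PPV is 0
    when there is no overlap at all.
    """
    if not references:
        raise ValueError("empty reference list")
    n, m = len(references), len(predictions)
    t = np.zeros((m, n))
    for i, pred in enumerate(predictions):
        b1, b2 = _prediction_sets(pred)
        for j, ref in enumerate(references):
            t[i, j] = len(ref.set_1 & b1) + len(ref.set_2 & b2)
    w = np.array([len(ref.set_1) + len(ref.set_2) for ref in references])
    sn = float(t.max(axis=0).sum() / w.sum()) if m else 0.0
    total = t.sum()
    ppv = float(t.max(axis=1).sum() / total) if m and total > 0 else 0.0
    return sn, ppv, math.sqrt(sn * ppv)


def _overlap_weight(ref: ReferencePair, pred: ConservedComplex) -> float:
    """Harmonic mean of the two per-species affinities (0 when both are 0)."""
    b1, b2 = _prediction_sets(pred)
    if not b1 or not b2:
        return 0.0
    w1 = neighborhood_affinity(ref.set_1, b1)
    w2 = neighborhood_affinity(ref.set_2, b2)
    if w1 + w2 == 0:
        return 0.0
    return 2.0 * w1 * w2 / (w1 + w2)


def mmrc(
    references: Sequence[ReferencePair],
    predictions: Sequence[ConservedComplex],
    tau: float = DEFAULT_TAU,
) -> float:
    """Maximum matching ratio for conserved complexes.

    Builds the bipartite weight matrix of harmonic-mean overlap weights,
    drops edges below tau, solves the maximum-weight one-to-one assignment,
    and divides the matched weight by the number of references.
    """
    if not references:
        raise ValueError("empty reference list")
    if not predictions:
        return 0.0
    B = np.zeros((len(references), len(predictions)))
    for i, ref in enumerate(references):
        for j, pred in enumerate(predictions):
            o = _overlap_weight(ref, pred)
            if o >= tau:
                B[i, j] = o
    rows, cols = linear_sum_assignment(B, maximize=True)
    return float(B[rows, cols].sum() / len(references))


def composite_score(fraction: float, acc: float, mmrc_value: float) -> float:
    return fraction + acc + mmrc_value


def evaluate_predictions(
    references: Sequence[ReferencePair],
    predictions: Sequence[ConservedComplex],
    tau: float = DEFAULT_TAU,
) -> ComplexMatchReport:
    """All pairwise metrics in one report."""
    frac = fraction_matched(references, predictions, tau=tau)
    sn, ppv, acc = accuracy_scores(references, predictions)
    mm = mmrc(references, predictions, tau=tau)
    return ComplexMatchReport(fraction=frac, sn=sn, ppv=ppv, acc=acc, mmrc=mm)


# ---------------------------------------------------------------------------
# GO-based metrics
# ---------------------------------------------------------------------------


def high_level_terms(
    annotations: AnnotationTable,
    ic_threshold: float = DEFAULT_IC_THRESHOLD,
    excluded_evidence: frozenset = DEFAULT_EXCLUDED_EVIDENCE,
    log_base: float | None = None,
) -> set[str]:
    """GO terms with information content above ``ic_threshold``.

    Annotations whose every evidence code is excluded are dropped first,
    then IC = -log(|term| / |root namespace|) is computed on the remaining
    table (natural log by default; pass ``log_base`` to change).
    """
    filtered = annotations.filtered(set(excluded_evidence))
    term_sizes = filtered.term_sizes()
    root_sizes = filtered.root_sizes()
    out: set[str] = set()
    for term, size in term_sizes.items():
        root = root_sizes.get(filtered.aspects.get(term, ""), 0)
        if size <= 0 or root <= 0:
            continue
        ic = -math.log(size / root)
        if log_base is not None:
            ic /= math.log(log_base)
        if ic > ic_threshold:
            out.add(term)
    return out


def normalized_entropy(term_counts: dict[str, int]) -> float:
    """-1/log(d) * sum p_j log p_j over d distinct terms (0 when d <= 1)."""
    counts = [c for c in term_counts.values() if c > 0]
    d = len(counts)
    if d <= 1:
        return 0.0
    total = sum(counts)
    h = -sum((c / total) * math.log(c / total) for c in counts)
    return h / math.log(d)


def mne(
    complexes: Sequence[ConservedComplex],
    annotations: AnnotationTable | Sequence[AnnotationTable],
    term_filter: set[str] | None = None,
) -> float:
    """Mean normalized entropy of term assignments within complexes.

    Each complex's proteins (all species pooled) contribute one count per
    (protein, term) assignment surviving ``term_filter``; complexes with no
    annotated protein are skipped with a warning.  When per-species tables
    are given they are matched to the complex's species order.
    """
    values: list[float] = []
    for cx in complexes:
        counts: dict[str, int] = {}
        for j, members in enumerate(cx.per_network_sets):
            if isinstance(annotations, AnnotationTable):
                table = annotations
            else:
                table = annotations[j]
            for p in members:
                for term in table.terms_of(p):
                    if term_filter is not None and term not in term_filter:
                        continue
                    counts[term] = counts.get(term, 0) + 1
        if not counts:
            logger.warning("complex with no annotated protein skipped in MNE")
            continue
        values.append(normalized_entropy(counts))
    if not values:
        raise ValueError("no complex with annotated proteins")
    return sum(values) / len(values)


def coverage(
    complexes: Sequence[ConservedComplex],
    min_size_per_species: int = 3,
    distinct: bool = True,
) -> int:
    """Number of proteins in complexes with >= ``min_size_per_species``
    proteins in every species.

    Proteins are namespaced by species index; with ``distinct`` (default) a
    protein appearing in several complexes is counted once, otherwise with
    multiplicity.
    """
    qualifying = [
        cx
        for cx in complexes
        if cx.k > 0 and cx.min_species_size() >= min_size_per_species
    ]
    if distinct:
        seen: set[tuple[int, str]] = set()
        for cx in qualifying:
            for j, members in enumerate(cx.per_network_sets):
                seen.update((j, p) for p in members)
        return len(seen)
    return sum(cx.total_size for cx in qualifying)


def build_reference_pairs(
    labeled_complexes_1: Sequence[tuple[Iterable, str]],
    complexes_2: Sequence[Iterable],
    annotations_2: AnnotationTable,
) -> list[ReferencePair]:
    """Align species-1 complexes to species-2 complexes by shared GO term.

    Each species-1 complex carries one GO term label.  A pair is emitted
    when at least half of a species-2 complex's proteins are annotated to
    that term; a species-2 complex may pair with several species-1
    complexes sharing a term.
    """
    out: list[ReferencePair] = []
    for set_1, term in labeled_complexes_1:
        set_1 = frozenset(set_1)
        if not set_1:
            continue
        for raw_2 in complexes_2:
            set_2 = frozenset(raw_2)
            if not set_2:
                continue
            annotated = sum(1 for p in set_2 if term in annotations_2.terms_of(p))
            if 2 * annotated >= len(set_2):
                out.append(ReferencePair(set_1=set_1, set_2=set_2, label=term))
    return out


def write_report_tsv(report: ComplexMatchReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in report.as_dict().items():
            fh.write(f"{key}\t{value:.6f}\n")
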