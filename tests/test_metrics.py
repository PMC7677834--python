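import itertools
import math

import numpy as np
import pytest

from clusterm.metrics import (
    ComplexMatchReport,
    ReferencePair,
    accuracy_scores,
    build_reference_pairs,
    composite_score,
    coverage,
    evaluate_predictions,
    fraction_matched,
    high_level_terms,
    mmrc,
    mne,
    neighborhood_affinity,
    normalized_entropy,
)
from clusterm.netio import AnnotationTable, ConservedComplex


def pred(set_1, set_2):
    return ConservedComplex(per_network_sets=[set(set_1), set(set_2)])


def ref(set_1, set_2, label=""):
    return ReferencePair(set_1=frozenset(set_1), set_2=frozenset(set_2), label=label)


class TestNeighborhoodAffinity:
    def test_identity_and_disjoint(self):
        assert neighborhood_affinity({"a", "b"}, {"a", "b"}) == 1.0
        assert neighborhood_affinity({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert neighborhood_affinity({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(
            4 / 9
        )

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            neighborhood_affinity(set(), {"a"})


class TestFractionMatched:
    def test_perfect_predictions(self):
        refs = [ref("abc", "xyz"), ref("def", "uvw")]
        preds = [pred("abc", "xyz"), pred("def", "uvw")]
        assert fraction_matched(refs, preds) == 1.0

    def test_half_matched(self):
        refs = [ref("abc", "xyz"), ref("def", "uvw")]
        preds = [pred("abc", "xyz")]
        assert fraction_matched(refs, preds) == 0.5

    def test_match_requires_both_species_simultaneously(self):
        # species 1 affinity 9/16 >= 0.25, species 2 affinity 1/5 < 0.25
        refs = [ref({"a", "b", "c", "d"}, {"x", "y", "z", "w", "v"})]
        preds = [pred({"a", "b", "c", "e"}, {"x"})]
        assert neighborhood_affinity(refs[0].set_1, {"a", "b", "c", "e"}) >= 0.25
        assert neighborhood_affinity(refs[0].set_2, {"x"}) < 0.25
        assert fraction_matched(refs, preds) == 0.0

    def test_empty_references_error(self):
        with pytest.raises(ValueError):
            fraction_matched([], [pred("a", "b")])


class TestAccuracyScores:
    def test_perfect_predictions(self):
        refs = [ref("abc", "xyz"), ref("def", "uvw")]
        preds = [pred("abc", "xyz"), pred("def", "uvw")]
        sn, ppv, acc = accuracy_scores(refs, preds)
        assert (sn, ppv, acc) == (1.0, 1.0, 1.0)

    def test_partial_overlap_sensitivity(self):
        refs = [ref({"a", "b", "c"}, {"x", "y", "z"})]
        preds = [pred({"a", "b", "q"}, {"x", "y", "r"})]
        sn, ppv, acc = accuracy_scores(refs, preds)
        assert sn == pytest.approx(4 / 6)
        assert acc == pytest.approx(math.sqrt(sn * ppv))

    def test_no_overlap_scores_zero(self):
        refs = [ref("abc", "xyz")]
        preds = [pred("qrs", "tuv")]
        assert accuracy_scores(refs, preds) == (0.0, 0.0, 0.0)


class TestMMRC:
    def test_identical_single_pair(self):
        refs = [ref("abc", "xyz")]
        assert mmrc(refs, [pred("abc", "xyz")]) == 1.0

    def test_one_of_two_matched(self):
        refs = [ref("abc", "xyz"), ref("def", "uvw")]
        assert mmrc(refs, [pred("abc", "xyz")]) == 0.5

    def test_one_to_one_constraint_picks_heavier_edge(self):
        refs = [ref({"a", "b", "c"}, {"x", "y", "z"})]
        good = pred({"a", "b", "c"}, {"x", "y", "z"})
        partial = pred({"a", "b", "q"}, {"x", "y", "r"})
        value = mmrc(refs, [partial, good])
        assert value == 1.0  # only the perfect prediction can be matched

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_assignment(self, trial):
        rng = np.random.default_rng(trial)
        universe = [f"p{i}" for i in range(8)]
        n_ref, n_pred = int(rng.integers(1, 5)), int(rng.integers(1, 5))

        def random_sets():
            k1 = int(rng.integers(2, 5))
            k2 = int(rng.integers(2, 5))
            return (
                set(rng.choice(universe, size=k1, replace=False)),
                set(rng.choice(universe, size=k2, replace=False)),
            )

        refs = [ref(*random_sets()) for _ in range(n_ref)]
        preds = [pred(*random_sets()) for _ in range(n_pred)]

        def w(X, Y):
            inter = len(set(X) & set(Y))
            return inter * inter / (len(X) * len(Y))

        def weight(r, p):
            w1 = w(r.set_1, p.per_network_sets[0])
            w2 = w(r.set_2, p.per_network_sets[1])
            if w1 + w2 == 0:
                return 0.0
            o = 2 * w1 * w2 / (w1 + w2)
            return o if o >= 0.25 else 0.0

        best = 0.0
        indices = list(range(n_pred))
        for r_subset in itertools.permutations(range(n_ref)):
            for assignment in itertools.permutations(indices, min(n_ref, n_pred)):
                total = sum(
                    weight(refs[r_subset[i]], preds[assignment[i]])
                    for i in range(min(n_ref, n_pred))
                )
                best = max(best, total)
        assert mmrc(refs, preds) == pytest.approx(best / n_ref, abs=1e-9)


class TestCompositeAndReport:
    def test_composite_arithmetic(self):
        assert composite_score(1, 1, 1) == 3
        assert composite_score(0, 0, 0) == 0
        assert composite_score(0.5, 0.4, 0.3) == pytest.approx(1.2)

    def test_report_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        universe = [f"p{i}" for i in range(10)]

        def random_sets():
            return (
                set(rng.choice(universe, size=3, replace=False)),
                set(rng.choice(universe, size=3, replace=False)),
            )

        refs = [ref(*random_sets()) for _ in range(4)]
        preds = [pred(*random_sets()) for _ in range(4)]
        fwd = evaluate_predictions(refs, preds)
        rev = evaluate_predictions(list(reversed(refs)), list(reversed(preds)))
        assert fwd.as_dict() == pytest.approx(rev.as_dict())

    def test_perfect_and_empty_extremes(self):
        refs = [ref("abc", "xyz"), ref("def", "uvw")]
        perfect = evaluate_predictions(refs, [pred("abc", "xyz"), pred("def", "uvw")])
        assert perfect.as_dict() == pytest.approx(
            {"fraction": 1, "sn": 1, "ppv": 1, "acc": 1, "mmrc": 1, "composite": 3}
        )
        empty = evaluate_predictions(refs, [])
        assert empty.composite == 0.0


class TestGoMetrics:
    def build_table(self, assignments, aspect="P", evidence="EXP"):
        table = AnnotationTable()
        for protein, terms in assignments.items():
            for term in terms:
                code = evidence[(protein, term)] if isinstance(evidence, dict) else evidence
                table.add(protein, term, code, aspect)
        return table

    def test_ic_threshold_natural_log(self):
        # term sizes 1000 (== root) and 100: IC 0 and ~2.303
        table = self.build_table(
            {f"p{i}": {"GO:big"} | ({"GO:small"} if i < 100 else set()) for i in range(1000)}
        )
        terms = high_level_terms(table, ic_threshold=2.0, excluded_evidence=frozenset())
        assert terms == {"GO:small"}

    def test_iea_only_support_removes_term(self):
        table = AnnotationTable()
        table.add("p1", "GO:x", "IEA", "P")
        table.add("p2", "GO:y", "EXP", "P")
        table.add("p2", "GO:z", "EXP", "P")
        filtered = table.filtered({"IEA"})
        assert "GO:x" not in filtered.term_sizes()

    def test_normalized_entropy_limits(self):
        assert normalized_entropy({"t": 5}) == 0.0
        assert normalized_entropy({"a": 3, "b": 3, "c": 3}) == pytest.approx(1.0)
        assert normalized_entropy({"a": 3, "b": 1}) == pytest.approx(0.8113, abs=1e-4)

    def test_mne_averages_over_complexes(self):
        table = self.build_table(
            {"a": {"GO:1"}, "b": {"GO:1"}, "x": {"GO:1"}, "y": {"GO:2"}}
        )
        uniform = ConservedComplex(per_network_sets=[{"a"}, {"b"}])
        split = ConservedComplex(per_network_sets=[{"x"}, {"y"}])
        assert mne([uniform], table) == 0.0
        assert mne([uniform, split], table) == pytest.approx(0.5)

    def test_mne_respects_term_filter_and_skips_unannotated(self):
        table = self.build_table({"a": {"GO:1", "GO:2"}})
        cx = ConservedComplex(per_network_sets=[{"a"}, set()])
        bare = ConservedComplex(per_network_sets=[{"zzz"}, set()])
        assert mne([cx, bare], table, term_filter={"GO:1"}) == 0.0

    def test_coverage_counts_distinct_proteins(self):
        a = ConservedComplex(per_network_sets=[{"a", "b", "c"}, {"x", "y", "z"}])
        shared = ConservedComplex(per_network_sets=[{"a", "d", "e"}, {"u", "v", "w"}])
        small = ConservedComplex(per_network_sets=[{"q", "r"}, {"s", "t", "u"}])
        assert coverage([]) == 0
        assert coverage([a]) == 6
        assert coverage([a, shared]) == 11  # "a" counted once
        assert coverage([a, small]) == 6  # 2-protein species set disqualifies
        assert coverage([a, shared], distinct=False) == 12

    def test_build_reference_pairs_half_rule(self):
        table = AnnotationTable()
        for p in ("h1", "h2"):
            table.add(p, "GO:term", "EXP", "P")
        labeled = [({"y1", "y2", "y3"}, "GO:term")]
        paired = build_reference_pairs(labeled, [{"h1", "h2", "h3", "h4"}], table)
        assert len(paired) == 1
        assert paired[0].label == "GO:term"
        # only 1 of 4 annotated -> below half -> no pair
        table2 = AnnotationTable()
        table2.add("h1", "GO:term", "EXP", "P")
        assert build_reference_pairs(labeled, [{"h1", "h2", "h3", "h4"}], table2) == []
        # term annotating nothing -> no pair
        assert build_reference_pairs(labeled, [{"h5", "h6"}], table) == []


class TestEntropyProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=8)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalized_entropy_in_unit_interval_and_label_free(self, counts):
        """NE lies in [0, 1] and depends only on the count multiset, not on
        which terms carry the counts."""
        ne = normalized_entropy({f"t{i}": c for i, c in enumerate(counts)})
        assert 0.0 <= ne <= 1.0 + 1e-12
        relabeled = normalized_entropy({f"XX{i}": c for i, c in enumerate(counts)})
        assert ne == relabeled

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=8),
        donor=st.integers(min_value=1, max_value=7),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_concentrating_mass_never_raises_entropy(self, counts, donor):
        """Moving one count from a minority term onto the majority term can
        only keep or lower NE (for a fixed number of terms)."""
        d = donor % len(counts)
        big = counts.index(max(counts))
        if d == big or counts[d] <= 1:
            return
        before = normalized_entropy({f"t{i}": c for i, c in enumerate(counts)})
        moved = list(counts)
        moved[d] -= 1
        moved[big] += 1
        after = normalized_entropy({f"t{i}": c for i, c in enumerate(moved)})
        assert after <= before + 1e-12
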