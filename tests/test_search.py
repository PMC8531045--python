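"""Score enumeration, exact tie-aware AUC, and exhaustive search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import PLANTED_COMPONENTS, make_cohort, planted_score_spec
from deliriscore.cohort import VariableSpec
from deliriscore.errors import ScoringError, SearchError, UndefinedAUCError
from deliriscore.search import (
    ExactAUC,
    ScoreDefinition,
    SearchConfig,
    apply_score,
    count_scores,
    enumerate_scores,
    exact_auc,
    search_best,
)
from deliriscore.simulate import generate_cohort

PAPER_SCORE = ScoreDefinition((
    ("age_ge75", 2), ("dementia", 3), ("psychotropics", 1), ("hearing_impairment", 2),
))


def brute_force_auc(scores, outcomes):
    """O(n^2) all-pairs Mann–Whitney oracle with exact integer bookkeeping."""
    s = list(scores)
    y = list(outcomes)
    pos = [v for v, t in zip(s, y) if t == 1]
    neg = [v for v, t in zip(s, y) if t == 0]
    doubled = sum(2 if p > q else (1 if p == q else 0) for p in pos for q in neg)
    return ExactAUC(doubled, len(pos), len(neg))


class TestCountScores:
    def test_seven_candidates_default_constraints(self):
        assert count_scores(7) == 3969
        assert 3969 == math.comb(7, 2) * 9 + math.comb(7, 3) * 27 + math.comb(7, 4) * 81

    def test_single_admissible_score(self):
        assert count_scores(2, SearchConfig(2, 2, 1, 1)) == 1

    def test_closed_form_matches_enumeration(self):
        cfg = SearchConfig(2, 3, 1, 2)
        names = [f"v{i}" for i in range(4)]
        assert count_scores(4, cfg) == 56
        assert len(list(enumerate_scores(names, cfg))) == 56

    @given(st.integers(1, 6), st.integers(1, 4), st.integers(1, 3), st.integers(0, 2))
    @settings(max_examples=50)
    def test_enumeration_count_and_uniqueness(self, n, kmax, wmin, wspan):
        kmin = 1
        kmax = min(kmax, n)
        cfg = SearchConfig(kmin, kmax, wmin, wmin + wspan)
        names = [f"v{i}" for i in range(n)]
        defs = list(enumerate_scores(names, cfg))
        assert len(defs) == count_scores(n, cfg)
        assert len({d.components for d in defs}) == len(defs)

    def test_excess_components_rejected(self):
        with pytest.raises(SearchError):
            count_scores(3, SearchConfig(2, 4, 1, 3))


class TestEnumerateScores:
    def test_two_candidate_hand_enumeration(self):
        cfg = SearchConfig(2, 2, 1, 2)
        defs = [d.components for d in enumerate_scores(["A", "B"], cfg)]
        assert defs == [
            (("A", 1), ("B", 1)), (("A", 1), ("B", 2)),
            (("A", 2), ("B", 1)), (("A", 2), ("B", 2)),
        ]

    def test_repeated_calls_identical_order(self):
        names = [f"v{i}" for i in range(5)]
        a = [d.components for d in enumerate_scores(names, SearchConfig(2, 3, 1, 3))]
        b = [d.components for d in enumerate_scores(names, SearchConfig(2, 3, 1, 3))]
        assert a == b

    def test_duplicate_candidates_rejected(self):
        with pytest.raises(SearchError):
            list(enumerate_scores(["A", "A"], SearchConfig(1, 1, 1, 1)))


class TestApplyScore:
    def _cohort(self, rows):
        cols = {n: [r[i] for r in rows] for i, n in enumerate(PAPER_SCORE.names)}
        return make_cohort([1] * len(rows), **cols)

    def test_published_weights_span_zero_to_eight(self):
        cohort = self._cohort([(1, 1, 1, 1), (0, 0, 0, 0), (0, 1, 0, 0)])
        s = apply_score(PAPER_SCORE, cohort)
        assert s.tolist() == [8, 0, 3]  # all components / none / dementia only
        assert PAPER_SCORE.max_score == 8

    def test_missing_component_is_error(self):
        cohort = make_cohort([1, 0], age_ge75=[1.0, 0.0])
        with pytest.raises(ScoringError, match="dementia"):
            apply_score(PAPER_SCORE, cohort)


class TestExactAUC:
    def test_perfect_separation(self):
        assert exact_auc([5, 5, 1, 1], [1, 1, 0, 0]).value == 1.0

    def test_all_ties_half(self):
        assert exact_auc([2, 2, 2, 2], [1, 0, 1, 0]).value == 0.5

    def test_worked_example(self):
        auc = exact_auc([3, 1, 2, 2], [1, 0, 0, 1])
        assert auc.doubled_numerator == 7
        assert auc.value == 0.875

    def test_single_class_error(self):
        with pytest.raises(UndefinedAUCError):
            exact_auc([1, 2], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 50)
        s = rng.integers(0, 9, n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        fast = exact_auc(s, y)
        slow = brute_force_auc(s, y)
        assert (fast.doubled_numerator, fast.n_pos, fast.n_neg) == \
               (slow.doubled_numerator, slow.n_pos, slow.n_neg)

    def test_matches_sklearn_on_float_scores(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        s = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        assert exact_auc(s, y).value == pytest.approx(
            sk.roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 6, 80)
        y = rng.integers(0, 2, 80)
        a = exact_auc(s, y)
        b = exact_auc(np.exp(s.astype(float)) + 5, y)
        assert a == b

    def test_complement_symmetry_on_label_flip(self):
        rng = np.random.default_rng(4)
        s = rng.integers(0, 6, 80)
        y = rng.integers(0, 2, 80)
        assert exact_auc(s, y).value + exact_auc(s, 1 - y).value == pytest.approx(1.0)


class TestSearchBest:
    def test_seven_candidates_tests_3969(self):
        cohort = generate_cohort(planted_score_spec(), seed=5, n=800)
        result = search_best(cohort, cohort.candidate_names())
        assert result.n_tested == 3969

    def test_tie_break_prefers_fewer_components(self):
        # B duplicates A, so {A:1} and {A:w, B:w'} tie in AUC exactly
        a = np.array([1, 1, 0, 0, 1, 0], dtype=float)
        y = np.array([1, 1, 0, 0, 0, 1])
        cohort = make_cohort(y, A=a, B=a.copy())
        result = search_best(cohort, ["A", "B"], SearchConfig(1, 2, 1, 2))
        assert result.best.components == (("A", 1),)

    def test_best_dominates_independent_reevaluation(self):
        cohort = generate_cohort(planted_score_spec(), seed=6, n=600)
        cands = cohort.candidate_names()
        result = search_best(cohort, cands)
        y = cohort.outcome()
        rng = np.random.default_rng(0)
        all_defs = list(enumerate_scores(cands, SearchConfig()))
        for i in rng.choice(len(all_defs), 100, replace=False):
            other = exact_auc(apply_score(all_defs[i], cohort), y)
            assert result.best_auc.doubled_numerator >= other.doubled_numerator

    def test_ranking_is_sorted_and_consistent(self):
        cohort = generate_cohort(planted_score_spec(), seed=8, n=400)
        result = search_best(cohort, cohort.candidate_names(), top_k=20)
        nums = [a.doubled_numerator for _, a in result.ranking]
        assert nums == sorted(nums, reverse=True)
        assert result.ranking[0][1] == result.best_auc
        y = cohort.outcome()
        for d, a in result.ranking[:5]:
            assert exact_auc(apply_score(d, cohort), y) == a

    def test_null_candidate_never_lowers_best_auc(self):
        spec = planted_score_spec()
        cohort = generate_cohort(spec, seed=9, n=1000)
        cands = ["age_ge75", "dementia", "hearing_impairment"]
        cfg = SearchConfig(2, 3, 1, 2)
        before = search_best(cohort, cands, cfg).best_auc
        rng = np.random.default_rng(1)
        noisy = cohort.with_variable(
            VariableSpec("coin", "binary", role="candidate"),
            rng.integers(0, 2, cohort.n).astype(float),
        )
        after = search_best(noisy, cands + ["coin"], cfg).best_auc
        assert after.doubled_numerator >= before.doubled_numerator

    def test_planted_component_set_recovered(self):
        cohort = generate_cohort(planted_score_spec(), seed=10, n=5000)
        result = search_best(cohort, cohort.candidate_names())
        assert set(result.best.names) == PLANTED_COMPONENTS
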