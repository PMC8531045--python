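"""Exhaustive search over integer-weighted risk scores, ranked by exact AUC.

The score space is every choice of k binary components (min_components <= k
<= max_components) from the screened candidates, crossed with every integer
weight vector in [weight_min, weight_max]^k.  With 7 candidates, 2-4
components and weights 1-3 this is sum_k C(7,k)*3^k = 3969 definitions.
Weight-vector symmetry is deliberately not collapsed: {A:1, B:2} and
{A:2, B:1} are distinct definitions, which is what makes the closed-form
count match explicit enumeration.

Discrimination is the nonparametric (Mann–Whitney) ROC AUC with ties
counted as half-wins, kept as an exact rational — the doubled numerator
2*wins + ties over the pair count 2*n_pos*n_neg — so that the maximum over
thousands of candidate scores is found by integer comparison, immune to
floating-point ties.  Equal-AUC scores are broken deterministically: fewer
components, then smaller total weight, then canonical enumeration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations, product
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .cohort import BINARY, Cohort
from .errors import ScoringError, SearchError, UndefinedAUCError


@dataclass(frozen=True)
class SearchConfig:
    """Constraints of the exhaustive score search."""

    min_components: int = 2
    max_components: int = 4
    weight_min: int = 1
    weight_max: int = 3

    def validate(self, n_candidates: int) -> None:
        if not 1 <= self.min_components <= self.max_components:
            raise SearchError(
                f"need 1 <= min_components <= max_components, got "
                f"{self.min_components}..{self.max_components}"
            )
        if self.max_components > n_candidates:
            raise SearchError(
                f"max_components={self.max_components} exceeds the "
                f"{n_candidates} available candidates"
            )
        if not 1 <= self.weight_min <= self.weight_max:
            raise SearchError(
                f"need 1 <= weight_min <= weight_max, got "
                f"{self.weight_min}..{self.weight_max}"
            )

    @property
    def n_weights(self) -> int:
        return self.weight_max - self.weight_min + 1


@dataclass(frozen=True)
class ScoreDefinition:
    """An ordered set of binary components with integer point weights.

    A patient's score is S = sum_i w_i * x_i with x_i in {0, 1}, so S ranges
    over [0, sum_i w_i].
    """

    components: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise SearchError(f"duplicate component names in score: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.components)

    @property
    def weights(self) -> tuple[int, ...]:
        return tuple(w for _, w in self.components)

    @property
    def total_weight(self) -> int:
        return sum(self.weights)

    @property
    def max_score(self) -> int:
        return self.total_weight

    def to_dict(self) -> dict:
        return {"components": [[n, w] for n, w in self.components]}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDefinition":
        return cls(tuple((str(n), int(w)) for n, w in d["components"]))


@dataclass(frozen=True, order=True)
class ExactAUC:
    """Tie-aware Mann–Whitney AUC as an exact rational.

    ``doubled_numerator`` is 2*wins + ties over all (case, non-case) pairs;
    the AUC value is doubled_numerator / (2 * n_pos * n_neg).
    """

    doubled_numerator: int
    n_pos: int
    n_neg: int

    @property
    def value(self) -> float:
        return self.doubled_numerator / (2 * self.n_pos * self.n_neg)

    @property
    def as_fraction(self) -> Fraction:
        return Fraction(self.doubled_numerator, 2 * self.n_pos * self.n_neg)

    def to_dict(self) -> dict:
        return {
            "doubled_numerator": self.doubled_numerator,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "value": self.value,
        }


@dataclass
class SearchResult:
    best: ScoreDefinition
    best_auc: ExactAUC
    n_tested: int
    ranking: list[tuple[ScoreDefinition, ExactAUC]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def count_scores(n_candidates: int, config: SearchConfig = SearchConfig()) -> int:
    """Closed-form count of admissible definitions:
    sum_{k=min}^{max} C(n, k) * W^k with W the number of weight levels."""
    config.validate(n_candidates)
    W = config.n_weights
    return sum(
        math.comb(n_candidates, k) * W ** k
        for k in range(config.min_components, config.max_components + 1)
    )


def enumerate_scores(
    candidates: Sequence[str], config: SearchConfig = SearchConfig()
) -> Iterator[ScoreDefinition]:
    """Yield every admissible definition exactly once, in canonical order:
    subset size ascending, subsets in lexicographic candidate order, weight
    vectors in odometer order."""
    if len(set(candidates)) != len(candidates):
        raise SearchError("duplicate candidate names")
    if not candidates:
        raise SearchError("empty candidate list")
    config.validate(len(candidates))
    levels = range(config.weight_min, config.weight_max + 1)
    for k in range(config.min_components, config.max_components + 1):
        for subset in combinations(candidates, k):
            for weights in product(levels, repeat=k):
                yield ScoreDefinition(tuple(zip(subset, weights)))


# ---------------------------------------------------------------------------
# Scoring and exact AUC
# ---------------------------------------------------------------------------

def apply_score(score: ScoreDefinition, cohort: Cohort) -> np.ndarray:
    """Per-patient integer score S = sum w_i x_i."""
    total = np.zeros(cohort.n, dtype=np.int64)
    for name, w in score.components:
        if not cohort.has_variable(name):
            raise ScoringError(f"score component {name!r} missing from cohort")
        if cohort.spec(name).kind != BINARY:
            raise ScoringError(f"score component {name!r} is not binary")
        x = cohort.values(name)
        if np.isnan(x).any():
            raise ScoringError(f"score component {name!r} has missing values")
        total += w * x.astype(np.int64)
    return total


def exact_auc(scores: Sequence[float], outcomes: Sequence[int]) -> ExactAUC:
    """Tie-aware Mann–Whitney AUC via sorting/counting (O(n log n)).

    For each (case, non-case) pair the doubled numerator gains 2 if the case
    scores higher, 1 on a tie.  Works for any orderable scores, not only
    integers.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    y = y.astype(np.int64)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: outcome has a single class")
    _, inv = np.unique(s, return_inverse=True)
    k = inv.max() + 1
    pos_c = np.bincount(inv[y == 1], minlength=k).astype(np.int64)
    neg_c = np.bincount(inv[y == 0], minlength=k).astype(np.int64)
    neg_below = np.cumsum(neg_c) - neg_c
    wins = int(np.sum(pos_c * neg_below))
    ties = int(np.sum(pos_c * neg_c))
    return ExactAUC(2 * wins + ties, n_pos, n_neg)


def _grouped_doubled_numerator(
    s: np.ndarray, pos_w: np.ndarray, neg_w: np.ndarray
) -> int:
    """Doubled Mann–Whitney numerator from small integer scores over
    weighted (pattern-compressed) observations."""
    m = int(s.max()) + 1
    pos_c = np.zeros(m, dtype=np.int64)
    neg_c = np.zeros(m, dtype=np.int64)
    np.add.at(pos_c, s, pos_w)
    np.add.at(neg_c, s, neg_w)
    neg_below = np.cumsum(neg_c) - neg_c
    return int(2 * np.sum(pos_c * neg_below) + np.sum(pos_c * neg_c))


def search_best(
    cohort: Cohort,
    candidates: Sequence[str],
    config: SearchConfig = SearchConfig(),
    top_k: int = 20,
) -> SearchResult:
    """Evaluate every admissible score on the cohort; return the AUC
    maximizer under exact rational comparison.

    Patients are first collapsed onto their unique candidate-pattern, so each
    of the thousands of definitions is scored on at most 2^m patterns rather
    than n patients.  Ties are broken by fewer components, then smaller total
    weight, then canonical enumeration order.
    """
    candidates = list(candidates)
    config.validate(len(candidates))
    y = cohort.outcome()
    if y.min() == y.max():
        raise UndefinedAUCError("cohort outcome has a single class")
    m = len(candidates)
    if m > 62:
        raise SearchError("more than 62 candidates not supported")
    X = np.column_stack([cohort.values(c) for c in candidates])
    if np.isnan(X).any():
        raise ScoringError("candidate values contain missing data")
    if not np.isin(X, (0, 1)).all():
        raise ScoringError("candidates must be binary 0/1")
    bits = (X.astype(np.int64) @ (np.int64(1) << np.arange(m, dtype=np.int64)))
    uniq, inv = np.unique(bits, return_inverse=True)
    u = len(uniq)
    P = ((uniq[:, None] >> np.arange(m, dtype=np.int64)) & 1).astype(np.int64)
    pos_w = np.bincount(inv[y == 1], minlength=u).astype(np.int64)
    neg_w = np.bincount(inv[y == 0], minlength=u).astype(np.int64)
    n_pos, n_neg = int(pos_w.sum()), int(neg_w.sum())

    col_index = {name: i for i, name in enumerate(candidates)}
    defs: list[ScoreDefinition] = []
    doubled: list[int] = []
    for sd in enumerate_scores(candidates, config):
        cols = [col_index[n] for n in sd.names]
        w = np.asarray(sd.weights, dtype=np.int64)
        s = P[:, cols] @ w
        doubled.append(_grouped_doubled_numerator(s, pos_w, neg_w))
        defs.append(sd)

    n_tested = len(defs)
    order = sorted(
        range(n_tested),
        key=lambda i: (-doubled[i], len(defs[i].components), defs[i].total_weight, i),
    )
    best_i = order[0]
    ranking = [
        (defs[i], ExactAUC(doubled[i], n_pos, n_neg)) for i in order[: max(top_k, 1)]
    ]
    return SearchResult(
        best=defs[best_i],
        best_auc=ExactAUC(doubled[best_i], n_pos, n_neg),
        n_tested=n_tested,
        ranking=ranking if top_k else [],
    )
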