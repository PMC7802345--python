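"""Fragment-set similarity scoring and corpus-level success rates.

Predictions and ground truths are key sets; the score of a prediction is a
set-overlap coefficient — Tanimoto by default,

    Tc(R, P) = |R ∩ P| / (|R| + |P| − |R ∩ P|),

with the Tversky index (and its Dice special case) as alternatives.  A
record may hold one or two reactants on either side, so scoring first
solves a tiny assignment problem: for 2-vs-2 both bijective pairings are
evaluated and the better mean wins; for unequal counts every cross pair is
tried and the best single pair is kept.  Corpus summaries report exact
matches (score 1.0), the "bioactively similar" band (0.85 < score < 1.0),
and the mean score, plus a histogram over the similarity bands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Sequence

from .keys import KeySet

__all__ = [
    "SimilarityConfig",
    "EvalOutcome",
    "CorpusSummary",
    "tanimoto",
    "tversky",
    "dice",
    "match_pairs",
    "corpus_success",
]

DEFAULT_BANDS = (0.50, 0.70, 0.85)


@dataclass(frozen=True)
class SimilarityConfig:
    metric: str = "tanimoto"            # tanimoto | dice | tversky
    alpha: float = 1.0
    beta: float = 1.0
    bands: tuple[float, ...] = DEFAULT_BANDS

    def __post_init__(self):
        if self.metric not in ("tanimoto", "dice", "tversky"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        b = self.bands
        if not all(0 < x < 1 for x in b) or list(b) != sorted(set(b)):
            raise ValueError("bands must be strictly increasing within (0,1)")

    def scorer(self) -> Callable[[KeySet, KeySet], float]:
        if self.metric == "tanimoto":
            return tanimoto
        if self.metric == "dice":
            return dice
        return lambda r, p: tversky(r, p, self.alpha, self.beta)


def tanimoto(r: KeySet, p: KeySet) -> float:
    """|R∩P| / |R∪P|.  Both-empty is scored 0 (with a warning), not 1."""
    inter = r.intersection_size(p)
    union = len(r) + len(p) - inter
    if union == 0:
        warnings.warn("Tanimoto of two empty key sets; scoring 0", stacklevel=2)
        return 0.0
    return inter / union


def tversky(r: KeySet, p: KeySet, alpha: float, beta: float) -> float:
    """Asymmetric Tversky index; alpha=beta=1 is Tanimoto, 0.5/0.5 is Dice."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    inter = r.intersection_size(p)
    denom = inter + alpha * (len(r) - inter) + beta * (len(p) - inter)
    if denom == 0:
        warnings.warn("Tversky of two empty key sets; scoring 0", stacklevel=2)
        return 0.0
    return inter / denom


def dice(r: KeySet, p: KeySet) -> float:
    return tversky(r, p, 0.5, 0.5)


def match_pairs(
    true_reactants: Sequence[KeySet],
    predicted_reactants: Sequence[KeySet],
    metric: Callable[[KeySet, KeySet], float] = tanimoto,
) -> tuple[list[tuple[int, int]], float]:
    """Best pairing of predicted against true reactant sets and its score.

    Equal counts: evaluate every bijective assignment, keep the one with the
    highest mean pair similarity; the score is that mean, so an exact match
    (score 1.0) requires every pair exact.  Unequal counts: evaluate all
    cross pairs and keep the single best one.  Returns ``(assignment,
    score)`` with the assignment as (true index, predicted index) pairs.
    """
    nt, np_ = len(true_reactants), len(predicted_reactants)
    if nt == 0 or np_ == 0:
        raise ValueError("match_pairs requires non-empty reactant lists")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if nt == np_:
            best_assign, best = None, -1.0
            for perm in permutations(range(np_)):
                score = sum(
                    metric(true_reactants[i], predicted_reactants[perm[i]])
                    for i in range(nt)
                ) / nt
                if score > best:
                    best, best_assign = score, [(i, perm[i]) for i in range(nt)]
            return best_assign, best
        best_assign, best = None, -1.0
        for i in range(nt):
            for j in range(np_):
                s = metric(true_reactants[i], predicted_reactants[j])
                if s > best:
                    best, best_assign = s, [(i, j)]
        return best_assign, best


@dataclass
class EvalOutcome:
    """Matched score of one test record."""

    score: float
    assignment: list[tuple[int, int]]
    n_true: int = 1
    n_predicted: int = 1


@dataclass
class CorpusSummary:
    """Corpus-level success rates over evaluated records."""

    n: int
    exact_pct: float                      # score == 1.0
    bioactively_similar_pct: float        # 0.85 < score < 1.0 (strict band)
    cumulative_similar_pct: float         # score >= 0.85 (includes exact)
    mean_score: float
    band_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "exact_pct": self.exact_pct,
            "bioactively_similar_pct": self.bioactively_similar_pct,
            "cumulative_similar_pct": self.cumulative_similar_pct,
            "mean_score": self.mean_score,
            "band_counts": dict(self.band_counts),
        }


def corpus_success(
    outcomes: Sequence[EvalOutcome],
    config: SimilarityConfig = SimilarityConfig(),
) -> CorpusSummary:
    """Summarize matched scores into exact/band/mean success rates.

    The band histogram uses the configured thresholds; with the defaults the
    bins are [0,.50), [.50,.70), [.70,.85), (.85,1.0) and {1.0}, with scores
    exactly on a threshold counted in the band above it.
    """
    if not outcomes:
        raise ValueError("corpus_success: empty outcome list")
    scores = [o.score for o in outcomes]
    n = len(scores)
    # Exactness additionally requires the predicted reactant count to match:
    # a 2-vs-1 comparison can score 1.0 on its best cross pair without the
    # prediction being the true reactant set.
    exact = sum(1 for o in outcomes if o.score == 1.0 and o.n_true == o.n_predicted)
    top = config.bands[-1]
    similar = sum(1 for o in outcomes
                  if top < o.score < 1.0
                  or (o.score == 1.0 and o.n_true != o.n_predicted))
    cumulative = sum(1 for s in scores if s >= top)
    edges = (0.0,) + tuple(config.bands)
    band_counts: dict[str, int] = {}
    pairs = list(zip(edges, edges[1:]))
    for i, (lo, hi) in enumerate(pairs):
        if i == len(pairs) - 1:
            # closed at the top threshold so the bins partition [0, 1]
            band_counts[f"[{lo:.2f},{hi:.2f}]"] = sum(1 for s in scores if lo <= s <= hi)
        else:
            band_counts[f"[{lo:.2f},{hi:.2f})"] = sum(1 for s in scores if lo <= s < hi)
    band_counts[f"({top:.2f},1.00)"] = similar
    band_counts["1.00"] = exact
    return CorpusSummary(
        n=n,
        exact_pct=100.0 * exact / n,
        bioactively_similar_pct=100.0 * similar / n,
        cumulative_similar_pct=100.0 * cumulative / n,
        mean_score=math.fsum(scores) / n,  # exact sum: permutation-invariant
        band_counts=band_counts,
    )
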