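"""The semiotic metric suite: sub-scores, weighting, and the composite Q.

The quality model grades an ontology on four aspects:

* syntactic  S = w_s1·SL + w_s2·SR   (lawfulness, richness)
* semantic   E = w_e1·EI + w_e2·EC + w_e3·EA (interpretability, consistency,
  clarity)
* pragmatic  P = w_p1·PO + w_p2·PU + w_p3·PR (comprehensiveness, accuracy,
  relevancy)
* social     O = w_o1·OT + w_o2·OH   (authority, history; manual inputs)

and combines them as Q = w_q1·S + w_q2·E + w_q3·P + w_q4·O.

Two of the printed sub-score equations read as *defect* fractions: lawfulness
as violations/axioms and interpretability as 1 − sense-coverage.  Both
contradict the convention that a higher score is better, so each is offered
in two modes: ``literal`` evaluates the equation exactly as printed, and
``classic`` (the default) evaluates its complement, consistent with the
classic semiotic metric suite the model descends from.  The mode used is
recorded on every score card.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .labels import TokenCensus
from .lexicon import SenseStats
from .model import (
    AxiomCensus,
    ElementCensus,
    FeatureInventory,
    ParameterError,
    UndefinedScoreError,
    DataError,
)

Mode = Literal["literal", "classic"]

ASPECTS = ("syntactic", "semantic", "pragmatic", "social")


@dataclass(frozen=True)
class MetricMode:
    """Equation-mode switches, recorded in every ScoreCard for provenance."""

    lawfulness_mode: Mode = "classic"
    interpretability_mode: Mode = "classic"
    clamp_to_unit: bool = True


@dataclass(frozen=True)
class Weights:
    """Two-level weight scheme: across aspects and within each aspect.

    ``aspect`` holds (w_q1, w_q2, w_q3, w_q4) for syntactic, semantic,
    pragmatic, social.  With ``auto_normalize`` on, the weights of the
    *active* members of each group are rescaled to sum to one before use;
    explicit weights pass through unrescaled otherwise.
    """

    aspect: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    syntactic: tuple[float, float] = (0.5, 0.5)
    semantic: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    pragmatic: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    social: tuple[float, float] = (0.5, 0.5)
    auto_normalize: bool = True

    def __post_init__(self) -> None:
        for group in (
            self.aspect,
            self.syntactic,
            self.semantic,
            self.pragmatic,
            self.social,
        ):
            if any(w < 0 for w in group):
                raise ParameterError(f"weights must be non-negative: {group}")


@dataclass(frozen=True)
class ScoreCard:
    """All sub-scores, aspect scores and the composite for one session."""

    SL: float | None = None
    SR: float | None = None
    S: float | None = None
    EI: float | None = None
    EC: float | None = None
    EA: float | None = None
    E: float | None = None
    PO: float | None = None
    PU: float | None = None
    PR: float | None = None
    P: float | None = None
    OT: float | None = None
    OH: float | None = None
    O: float | None = None
    Q: float | None = None
    excluded_aspects: frozenset[str] = frozenset()
    modes: MetricMode = MetricMode()
    weights: Weights = Weights()
    inputs: dict = field(default_factory=dict, compare=False)

    def scores(self) -> dict[str, float | None]:
        return {
            name: getattr(self, name)
            for name in (
                "SL", "SR", "S", "EI", "EC", "EA", "E",
                "PO", "PU", "PR", "P", "OT", "OH", "O", "Q",
            )
        }


# ---------------------------------------------------------------------------
# syntactic


def lawfulness(
    census: AxiomCensus, violations: int, mode: Mode = "classic"
) -> float:
    """Lawfulness SL from the DL-violation count and total axiom count.

    ``literal``: SL = violations / AX (the violation fraction, exactly as
    the defining equation prints it).  ``classic``: SL = 1 − violations/AX,
    so that a lawful ontology scores 1.
    """
    if census.n_total <= 0:
        raise UndefinedScoreError("lawfulness undefined: ontology has no axioms")
    if violations < 0:
        raise DataError("violation count must be non-negative")
    fraction = violations / census.n_total
    return fraction if mode == "literal" else 1.0 - fraction


def richness(inventory: FeatureInventory) -> float:
    """Richness SR: fraction of the 39 possible OWL constructs used."""
    return inventory.n_used / inventory.n_possible


# ---------------------------------------------------------------------------
# semantic


def interpretability(stats: SenseStats, mode: Mode = "classic") -> float:
    """Interpretability EI from sense coverage of unique tokens.

    ``literal``: EI = 1 − t_sense/t as printed; ``classic``: EI = t_sense/t,
    the fraction of unique tokens with at least one word sense.
    """
    if stats.t <= 0:
        raise UndefinedScoreError("interpretability undefined: no unique tokens")
    coverage = stats.t_sense / stats.t
    return 1.0 - coverage if mode == "literal" else coverage


def clarity(stats: SenseStats, clamp_to_unit: bool = True) -> float:
    """Clarity EA = 1 − t_avg_sense/t; ambiguous vocabularies score lower.

    The raw value can go negative when the average sense count exceeds the
    number of unique tokens; with ``clamp_to_unit`` it is floored at 0.
    """
    if stats.t <= 0:
        raise UndefinedScoreError("clarity undefined: no unique tokens")
    raw = 1.0 - stats.t_avg_sense / stats.t
    return max(0.0, raw) if clamp_to_unit else raw


def consistency(census: TokenCensus, clamp_to_unit: bool = True) -> float:
    """Consistency EC = 1 − d/t, penalizing duplicate token occurrences."""
    if census.t <= 0:
        raise UndefinedScoreError("consistency undefined: no unique tokens")
    raw = 1.0 - census.d / census.t
    return max(0.0, raw) if clamp_to_unit else raw


# ---------------------------------------------------------------------------
# pragmatic


def comprehensiveness(elements: ElementCensus, baseline_average: float) -> float:
    """Comprehensiveness PO = n_elements / library-baseline average.

    Deliberately unclamped: against a small historical baseline (e.g. 500)
    a modern ontology may score well above 1, which reports flag.
    """
    if baseline_average <= 0:
        raise ParameterError(
            f"baseline_average must be positive, got {baseline_average}"
        )
    return elements.n_elements / baseline_average


def accuracy(true_counts_per_reviewer: list[int], n_logical: int) -> float:
    """Accuracy PU: per-reviewer fraction of true statements, averaged."""
    if not true_counts_per_reviewer:
        raise UndefinedScoreError("accuracy undefined without reviewers")
    if n_logical <= 0:
        raise UndefinedScoreError("accuracy undefined without logical axioms")
    for count in true_counts_per_reviewer:
        if count < 0 or count > n_logical:
            raise DataError(
                f"true count {count} outside [0, {n_logical}]"
            )
    fractions = [c / n_logical for c in true_counts_per_reviewer]
    return sum(fractions) / len(fractions)


# ---------------------------------------------------------------------------
# weighting


def aspect_score(
    sub_scores: list[tuple[float, float]], auto_normalize: bool = False
) -> float:
    """Weighted sum of active sub-scores.

    With ``auto_normalize`` the weights are first rescaled to sum to one
    over the sub-scores actually supplied.
    """
    if not sub_scores:
        raise ParameterError("aspect score needs at least one sub-score")
    total_weight = sum(w for _, w in sub_scores)
    if any(w < 0 for _, w in sub_scores):
        raise ParameterError("sub-score weights must be non-negative")
    if total_weight == 0:
        raise ParameterError("all sub-score weights are zero")
    if auto_normalize:
        return sum(s * w for s, w in sub_scores) / total_weight
    return sum(s * w for s, w in sub_scores)


def normalize_weights(raw: Weights, active_aspects: set[str]) -> Weights:
    """Force excluded aspects to weight 0 and optionally renormalize.

    With ``auto_normalize`` the remaining aspect weights are rescaled to sum
    to one; otherwise explicit weights pass through unrescaled (matching a
    demonstration weighting like 0.15/0.51/0.33 used as-is).
    """
    unknown = active_aspects - set(ASPECTS)
    if unknown:
        raise ParameterError(f"unknown aspects: {sorted(unknown)}")
    masked = tuple(
        w if name in active_aspects else 0.0
        for name, w in zip(ASPECTS, raw.aspect)
    )
    total = sum(masked)
    if total == 0:
        raise ParameterError("all active aspect weights are zero")
    if raw.auto_normalize:
        masked = tuple(w / total for w in masked)
    return replace(raw, aspect=masked)


def overall_quality(
    S: float | None,
    E: float | None,
    P: float | None,
    O: float | None,
    weights: Weights,
) -> float:
    """Composite quality Q = w_q1·S + w_q2·E + w_q3·P + w_q4·O.

    Every aspect with nonzero weight must have a score; aspects with zero
    weight (excluded) may be absent and contribute nothing.
    """
    total = 0.0
    for name, score, weight in zip(ASPECTS, (S, E, P, O), weights.aspect):
        if weight == 0:
            continue
        if score is None:
            raise ParameterError(
                f"aspect {name!r} has weight {weight} but no score"
            )
        total += weight * score
    return total
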