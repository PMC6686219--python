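"""Sub-score formulas, the two-level weighting, and the composite Q."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ontoscore.labels import TokenCensus
from ontoscore.lexicon import SenseStats
from ontoscore.metrics import (
    Weights,
    accuracy,
    aspect_score,
    clarity,
    comprehensiveness,
    consistency,
    interpretability,
    lawfulness,
    normalize_weights,
    overall_quality,
    richness,
)
from ontoscore.model import (
    AxiomCensus,
    DataError,
    ElementCensus,
    FEATURE_CATALOG,
    FeatureInventory,
    ParameterError,
    UndefinedScoreError,
)


def _census(n_logical=50, n_non_logical=50):
    return AxiomCensus(n_logical=n_logical, n_non_logical=n_non_logical)


def _token_census(occurrences, t):
    counts = [(f"tok{i}", 1) for i in range(t - 1)]
    counts.append((f"tok{t-1}", occurrences - t + 1))
    return TokenCensus(
        occurrences=occurrences, t=t, d=occurrences - t,
        per_token_counts=tuple(counts),
    )


class TestLawfulness:
    def test_zero_violations_classic(self):
        assert lawfulness(_census(), 0, "classic") == 1.0

    def test_literal_is_violation_fraction(self):
        assert lawfulness(_census(), 5, "literal") == pytest.approx(0.05)

    def test_classic_is_complement(self):
        assert lawfulness(_census(), 5, "classic") == pytest.approx(0.95)

    def test_no_axioms_undefined(self):
        with pytest.raises(UndefinedScoreError):
            lawfulness(_census(0, 0), 0)

    @given(st.integers(0, 100), st.integers(1, 200))
    @settings(max_examples=100, deadline=None)
    def test_modes_are_complements(self, violations, n_total):
        census = AxiomCensus(n_logical=n_total, n_non_logical=0)
        total = lawfulness(census, violations, "literal") + lawfulness(
            census, violations, "classic"
        )
        assert total == pytest.approx(1.0)


class TestRichness:
    def test_empty_inventory(self):
        assert richness(FeatureInventory(used=frozenset())) == 0.0

    def test_saturated_inventory(self):
        assert richness(FeatureInventory(used=frozenset(FEATURE_CATALOG))) == 1.0

    def test_partial_inventory(self):
        used = frozenset(FEATURE_CATALOG[:13])
        assert richness(FeatureInventory(used=used)) == pytest.approx(13 / 39)


class TestInterpretability:
    def test_full_coverage(self):
        stats = SenseStats(t=10, t_sense=10, total_senses=20)
        assert interpretability(stats, "literal") == 0.0
        assert interpretability(stats, "classic") == 1.0

    def test_literal_as_printed(self):
        stats = SenseStats(t=4, t_sense=3, total_senses=3)
        assert interpretability(stats, "literal") == pytest.approx(0.25)

    def test_no_coverage_classic(self):
        stats = SenseStats(t=4, t_sense=0, total_senses=0)
        assert interpretability(stats, "classic") == 0.0

    @given(st.integers(1, 50), st.data())
    @settings(max_examples=100, deadline=None)
    def test_modes_are_complements(self, t, data):
        t_sense = data.draw(st.integers(0, t))
        stats = SenseStats(t=t, t_sense=t_sense, total_senses=t_sense * 2)
        total = interpretability(stats, "literal") + interpretability(
            stats, "classic"
        )
        assert total == pytest.approx(1.0)


class TestClarityConsistency:
    def test_clarity_moderate_ambiguity(self):
        stats = SenseStats(t=5, t_sense=5, total_senses=10)  # avg 2
        assert clarity(stats) == pytest.approx(0.6)

    def test_clarity_no_senses_is_perfect(self):
        stats = SenseStats(t=5, t_sense=0, total_senses=0)
        assert clarity(stats) == 1.0

    def test_clarity_clamped_at_zero(self):
        stats = SenseStats(t=2, t_sense=2, total_senses=10)  # avg 5, raw -1.5
        assert clarity(stats, clamp_to_unit=False) == pytest.approx(-1.5)
        assert clarity(stats, clamp_to_unit=True) == 0.0

    def test_consistency_all_unique(self):
        assert consistency(_token_census(5, 5)) == 1.0

    def test_consistency_penalizes_duplicates(self):
        assert consistency(_token_census(3, 2)) == pytest.approx(0.5)

    def test_consistency_clamped_at_zero(self):
        census = _token_census(30, 10)  # d = 20, raw -1.0
        assert consistency(census, clamp_to_unit=False) == pytest.approx(-1.0)
        assert consistency(census, clamp_to_unit=True) == 0.0


class TestComprehensiveness:
    def test_against_classic_baseline(self):
        elements = ElementCensus(80, 10, 5, 5)
        assert comprehensiveness(elements, 500.0) == pytest.approx(0.2)

    def test_may_exceed_one_against_library_average(self):
        elements = ElementCensus(1_000_000, 0, 0, 0)
        assert comprehensiveness(elements, 169_862.0) == pytest.approx(
            5.8871, abs=1e-4
        )

    def test_empty_ontology_scores_zero(self):
        assert comprehensiveness(ElementCensus(0, 0, 0, 0), 500.0) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ParameterError):
            comprehensiveness(ElementCensus(1, 0, 0, 0), 0.0)


class TestAccuracy:
    def test_averages_over_reviewers(self):
        assert accuracy([8, 6], 10) == pytest.approx(0.7)

    def test_single_perfect_reviewer(self):
        assert accuracy([10], 10) == 1.0

    def test_all_false(self):
        assert accuracy([0, 0, 0], 5) == 0.0

    def test_no_reviewers_undefined(self):
        with pytest.raises(UndefinedScoreError):
            accuracy([], 10)

    def test_true_count_above_total_rejected(self):
        with pytest.raises(DataError):
            accuracy([11], 10)


class TestWeighting:
    def test_aspect_score_weighted_sum(self):
        assert aspect_score([(1.0, 0.5), (1.0, 0.5)]) == 1.0
        assert aspect_score([(0.8, 0.5), (0.4, 0.5)]) == pytest.approx(0.6)

    def test_aspect_score_auto_normalized_thirds(self):
        score = aspect_score([(0.9, 1), (0.3, 1), (0.6, 1)], auto_normalize=True)
        assert score == pytest.approx(0.6)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ParameterError):
            aspect_score([(1.0, 0.0), (0.5, 0.0)])

    def test_exclusion_with_renormalization(self):
        weights = normalize_weights(
            Weights(), active_aspects={"syntactic", "semantic", "pragmatic"}
        )
        assert weights.aspect == pytest.approx((1 / 3, 1 / 3, 1 / 3, 0.0))

    def test_explicit_weights_pass_through_unrescaled(self):
        raw = Weights(aspect=(0.15, 0.51, 0.33, 0.0), auto_normalize=False)
        weights = normalize_weights(
            raw, active_aspects={"syntactic", "semantic", "pragmatic"}
        )
        assert weights.aspect == (0.15, 0.51, 0.33, 0.0)

    def test_no_exclusions_equal_quarters(self):
        weights = normalize_weights(
            Weights(), active_aspects={"syntactic", "semantic", "pragmatic", "social"}
        )
        assert weights.aspect == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_negative_weight_rejected(self):
        with pytest.raises(ParameterError):
            Weights(aspect=(-0.1, 0.5, 0.3, 0.3))


class TestOverallQuality:
    def test_demonstration_weights(self):
        weights = Weights(aspect=(0.15, 0.51, 0.33, 0.0), auto_normalize=False)
        assert overall_quality(1.0, 1.0, 1.0, None, weights) == pytest.approx(
            0.99, abs=1e-12
        )

    def test_all_zero_scores(self):
        assert overall_quality(0.0, 0.0, 0.0, 0.0, Weights()) == 0.0

    def test_missing_weighted_aspect_rejected(self):
        with pytest.raises(ParameterError):
            overall_quality(1.0, 1.0, None, None, Weights())

    def test_matches_brute_force_dot_product(self):
        rng = random.Random(17)
        for _ in range(1000):
            scores = [rng.random() for _ in range(4)]
            raw = [rng.random() for _ in range(4)]
            weights = Weights(aspect=tuple(raw), auto_normalize=False)
            expected = sum(s * w for s, w in zip(scores, raw))
            assert overall_quality(*scores, weights) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0, 1), min_size=4, max_size=4),
        st.integers(0, 3),
        st.floats(0.01, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_aspect(self, scores, index, bump):
        weights = Weights()
        bumped = list(scores)
        bumped[index] = min(1.0, bumped[index] + bump)
        assert overall_quality(*bumped, weights) >= overall_quality(
            *scores, weights
        ) - 1e-12

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_weight_rescaling(self, factor):
        scores = (0.7, 0.4, 0.9, 0.2)
        base = Weights(aspect=(0.1, 0.2, 0.3, 0.4))
        scaled = Weights(aspect=tuple(w * factor for w in base.aspect))
        active = {"syntactic", "semantic", "pragmatic", "social"}
        q1 = overall_quality(*scores, normalize_weights(base, active))
        q2 = overall_quality(*scores, normalize_weights(scaled, active))
        assert q1 == pytest.approx(q2)

    def test_exclusion_equals_direct_computation(self):
        scores = {"S": 0.8, "E": 0.6, "P": 0.4}
        weights = normalize_weights(
            Weights(), active_aspects={"syntactic", "semantic", "pragmatic"}
        )
        q = overall_quality(scores["S"], scores["E"], scores["P"], None, weights)
        assert q == pytest.approx(sum(scores.values()) / 3)
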