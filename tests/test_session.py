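"""Session orchestration: scorecard composition, snapshots, reports."""

import csv
import json
import warnings

import pytest
import yaml

from ontoscore import (
    MetricMode,
    SessionConfig,
    Weights,
    build_scorecard,
    census_axioms,
    census_elements,
    census_tokens,
    count_dl_violations,
    clarity,
    consistency,
    comprehensiveness,
    extract_labels,
    interpretability,
    lawfulness,
    load_ontology,
    load_snapshot,
    process_records,
    render_report,
    richness,
    save_snapshot,
    sense_stats,
    survey_features,
)
from ontoscore.model import ConfigError, SnapshotError


def _config(ontology_file, **overrides):
    base = dict(
        ontology_path=str(ontology_file),
        baseline_average=500.0,
        excluded_aspects=frozenset({"social"}),
    )
    base.update(overrides)
    return SessionConfig(**base)


def _card(ontology_file, lexicon, **overrides):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_scorecard(_config(ontology_file, **overrides), lexicon=lexicon)


def test_scorecard_equals_hand_chained_stages(ontology_file, lexicon):
    card = _card(ontology_file, lexicon)
    model = load_ontology(ontology_file)
    ax = census_axioms(model)
    violations = count_dl_violations(model)
    records = process_records(extract_labels(model))
    token_census = census_tokens(records)
    stats = sense_stats(lexicon, token_census)
    assert card.SL == pytest.approx(lawfulness(ax, violations), abs=1e-12)
    assert card.SR == pytest.approx(richness(survey_features(model)), abs=1e-12)
    assert card.EI == pytest.approx(interpretability(stats), abs=1e-12)
    assert card.EA == pytest.approx(clarity(stats), abs=1e-12)
    assert card.EC == pytest.approx(consistency(token_census), abs=1e-12)
    assert card.PO == pytest.approx(
        comprehensiveness(census_elements(model), 500.0), abs=1e-12
    )
    assert card.S == pytest.approx((card.SL + card.SR) / 2, abs=1e-12)
    assert card.E == pytest.approx((card.EI + card.EC + card.EA) / 3, abs=1e-12)
    assert card.Q == pytest.approx((card.S + card.E + card.P) / 3, abs=1e-12)


def test_social_excluded_card_has_no_social_score(ontology_file, lexicon):
    card = _card(ontology_file, lexicon)
    assert card.O is None
    assert card.OT is None
    assert "social" in card.excluded_aspects
    assert card.weights.aspect[3] == 0.0


def test_social_with_manual_inputs(ontology_file, lexicon):
    card = _card(
        ontology_file, lexicon, excluded_aspects=frozenset(),
        authority=0.8, history=0.4,
    )
    assert card.O == pytest.approx(0.6)
    assert card.weights.aspect == pytest.approx((0.25,) * 4)


def test_social_without_inputs_auto_dropped_with_warning(ontology_file, lexicon):
    config = _config(ontology_file, excluded_aspects=frozenset())
    with pytest.warns(UserWarning, match="social"):
        card = build_scorecard(config, lexicon=lexicon)
    assert card.O is None


def test_missing_baseline_with_pragmatic_active_is_config_error(
    ontology_file, lexicon
):
    config = _config(ontology_file, baseline_average=None)
    with pytest.raises(ConfigError, match="baseline"):
        build_scorecard(config, lexicon=lexicon)


def test_review_files_feed_accuracy(ontology_file, lexicon, tmp_path):
    from ontoscore import export_statements, verbalize_ontology

    model = load_ontology(ontology_file)
    statement_set = verbalize_ontology(model)
    raw = tmp_path / "raw.csv"
    export_statements(statement_set, raw)
    rows = list(csv.reader(open(raw)))
    for row in rows[1:]:
        row[3] = "true"
    filled = tmp_path / "alice.csv"
    with open(filled, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)
    card = _card(ontology_file, lexicon, review_files={"alice": str(filled)})
    n_logical = census_axioms(model).n_logical
    assert card.PU == pytest.approx(len(statement_set.statements) / n_logical)
    assert card.inputs["per_reviewer_accuracy"]["alice"] == card.PU


def test_literal_modes_recorded_and_applied(ontology_file, lexicon):
    literal = _card(
        ontology_file, lexicon,
        modes=MetricMode("literal", "literal", clamp_to_unit=True),
    )
    classic = _card(ontology_file, lexicon)
    assert literal.SL == pytest.approx(1 - classic.SL, abs=1e-12)
    assert literal.EI == pytest.approx(1 - classic.EI, abs=1e-12)
    assert literal.modes.lawfulness_mode == "literal"


def test_end_to_end_determinism(ontology_file, lexicon):
    card1 = _card(ontology_file, lexicon)
    card2 = _card(ontology_file, lexicon)
    assert card1.scores() == card2.scores()
    assert render_report(card1, "json") == render_report(card2, "json")


class TestSnapshot:
    def test_round_trip_score_equality(self, ontology_file, lexicon, tmp_path):
        card = _card(ontology_file, lexicon)
        path = tmp_path / "snap.json"
        save_snapshot(card, path)
        loaded = load_snapshot(path)
        for name, value in card.scores().items():
            reloaded = loaded.scores()[name]
            if value is None:
                assert reloaded is None
            else:
                assert abs(reloaded - value) < 1e-12
        assert loaded.excluded_aspects == card.excluded_aspects
        assert loaded.modes == card.modes

    def test_truncated_file_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema_version": 1, "scores": {')
        with pytest.raises(SnapshotError):
            load_snapshot(path)

    def test_schema_version_mismatch(self, ontology_file, lexicon, tmp_path):
        card = _card(ontology_file, lexicon)
        path = tmp_path / "snap.json"
        save_snapshot(card, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(SnapshotError, match="99"):
            load_snapshot(path)

    def test_two_snapshots_differ_only_in_timestamp(
        self, ontology_file, lexicon, tmp_path
    ):
        card = _card(ontology_file, lexicon)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_snapshot(card, p1)
        save_snapshot(card, p2)
        d1 = json.loads(p1.read_text())
        d2 = json.loads(p2.read_text())
        d1.pop("timestamp")
        d2.pop("timestamp")
        assert d1 == d2


class TestReport:
    def test_flags_comprehensiveness_above_one(self, ontology_file, lexicon):
        card = _card(ontology_file, lexicon, baseline_average=2.0)
        assert card.PO > 1
        report = render_report(card, "text")
        assert "exceeds 1" in report

    def test_json_report_round_trips_scores(self, ontology_file, lexicon):
        card = _card(ontology_file, lexicon)
        parsed = json.loads(render_report(card, "json"))
        assert parsed["scores"]["Q"] == card.Q

    def test_excluded_aspects_listed(self, ontology_file, lexicon):
        report = render_report(_card(ontology_file, lexicon), "text")
        assert "excluded aspects: social" in report


def test_config_yaml_round_trip(ontology_file, lexicon_csv, tmp_path):
    config = SessionConfig(
        ontology_path=str(ontology_file),
        baseline_average=500.0,
        excluded_aspects=frozenset({"social"}),
        lexicon_path=str(lexicon_csv),
        weights=Weights(aspect=(0.15, 0.51, 0.33, 0.0), auto_normalize=False),
    )
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(config.to_dict()))
    reloaded = SessionConfig.from_file(path)
    assert reloaded == config
    assert reloaded.digest() == config.digest()


def test_invalid_manual_score_rejected(ontology_file):
    with pytest.raises(ConfigError, match="relevancy"):
        SessionConfig(ontology_path=str(ontology_file), relevancy=1.5)
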