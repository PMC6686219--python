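"""Session orchestration: configuration → score card → report/snapshot.

One :class:`SessionConfig` describes a complete scoring run: the ontology
file, label parsing options, equation modes, the two-level weights with
aspect exclusions, the comprehensiveness baseline, manual sub-scores
(relevancy, authority, history) and per-reviewer review files.
:func:`build_scorecard` executes the full pipeline deterministically;
snapshots archive the result as JSON and reload score-identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io import (
    census_axioms,
    census_elements,
    count_dl_violations,
    extract_labels,
    load_ontology,
    merge_imports,
    survey_features,
)
from .labels import ParseOptions, census_tokens, process_records
from .lexicon import (
    FixtureLexicon,
    LexicalDatabase,
    WordNetLexicon,
    label_sense_total,
    sense_stats,
)
from .metrics import (
    ASPECTS,
    MetricMode,
    ScoreCard,
    Weights,
    aspect_score,
    clarity,
    consistency,
    comprehensiveness,
    interpretability,
    lawfulness,
    normalize_weights,
    overall_quality,
    richness,
)
from .model import ConfigError, OntoscoreError, SnapshotError, UndefinedScoreError
from .review import ReviewSet, accuracy_from_review, import_judgments
from .verbalize import verbalize_ontology

SNAPSHOT_SCHEMA_VERSION = 1


@dataclass
class SessionConfig:
    """Everything needed to reproduce one scoring session."""

    ontology_path: str
    format_hint: str | None = None
    follow_imports: bool = False
    import_map: dict[str, str] = field(default_factory=dict)
    parse_options: ParseOptions = field(default_factory=ParseOptions)
    label_properties: list[str] | None = None
    language_preference: list[str | None] | None = None
    modes: MetricMode = field(default_factory=MetricMode)
    weights: Weights = field(default_factory=Weights)
    excluded_aspects: frozenset[str] = frozenset()
    baseline_average: float | None = None
    relevancy: float | None = None
    authority: float | None = None
    history: float | None = None
    lexicon_backend: str = "fixture"  # fixture | wordnet
    lexicon_path: str | None = None
    review_files: dict[str, str] = field(default_factory=dict)
    accuracy_denominator: str = "all_logical"
    seed: int | None = None  # used only when scoring generated fixtures

    def __post_init__(self) -> None:
        unknown = set(self.excluded_aspects) - set(ASPECTS)
        if unknown:
            raise ConfigError(f"unknown excluded aspects: {sorted(unknown)}")
        for name in ("relevancy", "authority", "history"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.accuracy_denominator not in ("all_logical", "judged_only"):
            raise ConfigError(
                f"unknown accuracy denominator {self.accuracy_denominator!r}"
            )
        if self.lexicon_backend not in ("fixture", "wordnet"):
            raise ConfigError(f"unknown lexicon backend {self.lexicon_backend!r}")

    # -- serialization

    def to_dict(self) -> dict:
        data = asdict(self)
        data["excluded_aspects"] = sorted(self.excluded_aspects)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SessionConfig":
        data = dict(data)
        if "parse_options" in data and isinstance(data["parse_options"], dict):
            data["parse_options"] = ParseOptions(**data["parse_options"])
        if "modes" in data and isinstance(data["modes"], dict):
            data["modes"] = MetricMode(**data["modes"])
        if "weights" in data and isinstance(data["weights"], dict):
            w = dict(data["weights"])
            for key in ("aspect", "syntactic", "semantic", "pragmatic", "social"):
                if key in w:
                    w[key] = tuple(w[key])
            data["weights"] = Weights(**w)
        if "excluded_aspects" in data:
            data["excluded_aspects"] = frozenset(data["excluded_aspects"])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        """Load a YAML or JSON config file."""
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _resolve_lexicon(config: SessionConfig) -> LexicalDatabase:
    if config.lexicon_backend == "wordnet":
        return WordNetLexicon()
    if config.lexicon_path is None:
        raise ConfigError(
            "fixture lexicon backend needs lexicon_path (token,sense_count CSV)"
        )
    return FixtureLexicon.from_csv(config.lexicon_path)


def _stage(name: str, exc: Exception) -> OntoscoreError:
    wrapped = type(exc) if isinstance(exc, OntoscoreError) else OntoscoreError
    return wrapped(f"[{name}] {exc}")


def build_scorecard(
    config: SessionConfig, lexicon: LexicalDatabase | None = None
) -> ScoreCard:
    """Run the full pipeline: load → labels → senses → metrics → Q.

    A ``lexicon`` object passed directly overrides the configured backend
    (the normal library-use path).  Every intermediate census lands in the
    card's inputs digest; the run is deterministic for fixed inputs.
    """
    try:
        model = load_ontology(config.ontology_path, config.format_hint)
        model = merge_imports(
            model, follow=config.follow_imports, import_map=config.import_map or None
        )
    except OntoscoreError as exc:
        raise _stage("ontology_io", exc) from exc

    ax_census = census_axioms(model)
    el_census = census_elements(model)
    inventory = survey_features(model)
    violations = count_dl_violations(model)

    records = extract_labels(
        model, config.label_properties, config.language_preference
    )
    process_records(records, config.parse_options)
    token_census = census_tokens(records)

    if lexicon is None:
        try:
            lexicon = _resolve_lexicon(config)
        except OntoscoreError as exc:
            raise _stage("lexicon", exc) from exc
    for record in records:
        record.accumulated_senses = label_sense_total(lexicon, record.tokens)
    try:
        stats = sense_stats(lexicon, token_census)
    except UndefinedScoreError as exc:
        raise _stage("lexicon", exc) from exc

    modes = config.modes
    active = set(ASPECTS) - set(config.excluded_aspects)

    # syntactic
    try:
        SL = lawfulness(ax_census, violations, modes.lawfulness_mode)
    except OntoscoreError as exc:
        raise _stage("metrics", exc) from exc
    SR = richness(inventory)
    # semantic
    EI = interpretability(stats, modes.interpretability_mode)
    EA = clarity(stats, modes.clamp_to_unit)
    EC = consistency(token_census, modes.clamp_to_unit)
    raw_EA = clarity(stats, clamp_to_unit=False)
    raw_EC = consistency(token_census, clamp_to_unit=False)
    if modes.clamp_to_unit and (raw_EA < 0 or raw_EC < 0):
        warnings.warn(
            f"clamped to [0,1]: raw clarity {raw_EA:.4f}, "
            f"raw consistency {raw_EC:.4f}",
            stacklevel=2,
        )

    w = config.weights
    S = aspect_score(
        [(SL, w.syntactic[0]), (SR, w.syntactic[1])], w.auto_normalize
    )
    E = aspect_score(
        [(EI, w.semantic[0]), (EC, w.semantic[1]), (EA, w.semantic[2])],
        w.auto_normalize,
    )

    # pragmatic
    PO = PU = PR = P = None
    per_reviewer: dict[str, float] = {}
    if "pragmatic" in active:
        if config.baseline_average is None:
            raise ConfigError(
                "[metrics] pragmatic aspect is active but baseline_average "
                "is not configured"
            )
        PO = comprehensiveness(el_census, config.baseline_average)
        if config.review_files:
            try:
                statement_set = verbalize_ontology(model)
                review_set = ReviewSet(n_statements=len(statement_set.statements))
                for reviewer_id, path in sorted(config.review_files.items()):
                    review_set.add(
                        import_judgments(path, reviewer_id, statement_set)
                    )
                PU, per_reviewer = accuracy_from_review(
                    review_set, ax_census.n_logical, config.accuracy_denominator
                )
            except OntoscoreError as exc:
                raise _stage("review", exc) from exc
        PR = config.relevancy
        subs = [(PO, w.pragmatic[0])]
        if PU is not None:
            subs.append((PU, w.pragmatic[1]))
        if PR is not None:
            subs.append((PR, w.pragmatic[2]))
        P = aspect_score(subs, w.auto_normalize)

    # social
    OT = config.authority
    OH = config.history
    O = None
    if "social" in active:
        subs = []
        if OT is not None:
            subs.append((OT, w.social[0]))
        if OH is not None:
            subs.append((OH, w.social[1]))
        if subs:
            O = aspect_score(subs, w.auto_normalize)
        else:
            warnings.warn(
                "social aspect has no authority/history inputs; excluding it",
                stacklevel=2,
            )
            active.discard("social")
    if "pragmatic" not in active:
        PO = PU = PR = P = None

    weights = normalize_weights(w, active)
    Q = overall_quality(S, E, P, O, weights)

    inputs = {
        "ontology_iri": model.ontology_iri,
        "axiom_census": {
            "n_logical": ax_census.n_logical,
            "n_non_logical": ax_census.n_non_logical,
            "n_total": ax_census.n_total,
        },
        "element_census": {
            "n_classes": el_census.n_classes,
            "n_individuals": el_census.n_individuals,
            "n_object_properties": el_census.n_object_properties,
            "n_data_properties": el_census.n_data_properties,
            "n_elements": el_census.n_elements,
        },
        "features_used": sorted(inventory.used),
        "n_features_used": inventory.n_used,
        "n_features_possible": inventory.n_possible,
        "dl_violations": violations,
        "token_census": {
            "occurrences": token_census.occurrences,
            "t": token_census.t,
            "d": token_census.d,
        },
        "sense_stats": {
            "t": stats.t,
            "t_sense": stats.t_sense,
            "total_senses": stats.total_senses,
            "t_avg_sense": stats.t_avg_sense,
        },
        "raw_clarity": raw_EA,
        "raw_consistency": raw_EC,
        "baseline_average": config.baseline_average,
        "per_reviewer_accuracy": per_reviewer,
        "lexicon": getattr(lexicon, "name", "custom"),
        "config_digest": config.digest(),
    }
    return ScoreCard(
        SL=SL, SR=SR, S=S,
        EI=EI, EC=EC, EA=EA, E=E,
        PO=PO, PU=PU, PR=PR, P=P,
        OT=OT if "social" in active else None,
        OH=OH if "social" in active else None,
        O=O, Q=Q,
        excluded_aspects=frozenset(set(ASPECTS) - active),
        modes=modes,
        weights=weights,
        inputs=inputs,
    )


# ---------------------------------------------------------------------------
# snapshots


def save_snapshot(card: ScoreCard, path) -> None:
    """Archive a score card as JSON (schema-versioned, timestamped)."""
    payload = {
        "schema_version": SNAPSHOT_SCHEMA_VERSION,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "scores": card.scores(),
        "excluded_aspects": sorted(card.excluded_aspects),
        "modes": asdict(card.modes),
        "weights": asdict(card.weights),
        "inputs": card.inputs,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_snapshot(path) -> ScoreCard:
    """Reload an archived score card; scores round-trip to 1e-12."""
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise SnapshotError(f"cannot read snapshot {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != SNAPSHOT_SCHEMA_VERSION:
        raise SnapshotError(
            f"snapshot schema version {version!r} is not supported "
            f"(expected {SNAPSHOT_SCHEMA_VERSION})"
        )
    weights_data = dict(payload["weights"])
    for key in ("aspect", "syntactic", "semantic", "pragmatic", "social"):
        weights_data[key] = tuple(weights_data[key])
    return ScoreCard(
        **payload["scores"],
        excluded_aspects=frozenset(payload["excluded_aspects"]),
        modes=MetricMode(**payload["modes"]),
        weights=Weights(**weights_data),
        inputs=payload.get("inputs", {}),
    )


# ---------------------------------------------------------------------------
# reports


def render_report(card: ScoreCard, format: str = "text") -> str:
    """Render a score card as plain text or JSON.

    The report shows every sub-score with its weight and mode, flags a
    comprehensiveness above 1 (ontology larger than the library baseline),
    and lists excluded aspects.
    """
    if format == "json":
        return json.dumps(
            {
                "scores": card.scores(),
                "excluded_aspects": sorted(card.excluded_aspects),
                "modes": asdict(card.modes),
                "weights": asdict(card.weights),
                "flags": _flags(card),
                "inputs": card.inputs,
            },
            indent=2,
            sort_keys=True,
        )
    if format != "text":
        raise ConfigError(f"unknown report format {format!r}")
    w = card.weights
    lines = ["Semiotic quality report", "======================="]
    lines.append(
        f"syntactic S = {_fmt(card.S)}  (aspect weight {w.aspect[0]:.4g})"
    )
    lines.append(
        f"  lawfulness SL = {_fmt(card.SL)}  "
        f"(weight {w.syntactic[0]:.4g}, mode {card.modes.lawfulness_mode})"
    )
    lines.append(
        f"  richness   SR = {_fmt(card.SR)}  (weight {w.syntactic[1]:.4g})"
    )
    lines.append(
        f"semantic  E = {_fmt(card.E)}  (aspect weight {w.aspect[1]:.4g})"
    )
    lines.append(
        f"  interpretability EI = {_fmt(card.EI)}  "
        f"(weight {w.semantic[0]:.4g}, mode {card.modes.interpretability_mode})"
    )
    lines.append(
        f"  consistency      EC = {_fmt(card.EC)}  (weight {w.semantic[1]:.4g})"
    )
    lines.append(
        f"  clarity          EA = {_fmt(card.EA)}  (weight {w.semantic[2]:.4g})"
    )
    lines.append(
        f"pragmatic P = {_fmt(card.P)}  (aspect weight {w.aspect[2]:.4g})"
    )
    lines.append(
        f"  comprehensiveness PO = {_fmt(card.PO)}  (weight {w.pragmatic[0]:.4g})"
    )
    lines.append(
        f"  accuracy          PU = {_fmt(card.PU)}  (weight {w.pragmatic[1]:.4g})"
    )
    lines.append(
        f"  relevancy         PR = {_fmt(card.PR)}  (weight {w.pragmatic[2]:.4g})"
    )
    lines.append(
        f"social    O = {_fmt(card.O)}  (aspect weight {w.aspect[3]:.4g})"
    )
    lines.append(f"  authority OT = {_fmt(card.OT)}  (weight {w.social[0]:.4g})")
    lines.append(f"  history   OH = {_fmt(card.OH)}  (weight {w.social[1]:.4g})")
    lines.append("-----------------------")
    lines.append(f"overall quality Q = {_fmt(card.Q)}")
    if card.excluded_aspects:
        lines.append("excluded aspects: " + ", ".join(sorted(card.excluded_aspects)))
    for flag in _flags(card):
        lines.append(f"flag: {flag}")
    return "\n".join(lines) + "\n"


def _fmt(value: float | None) -> str:
    return "n/a" if value is None else f"{value:.6f}"


def _flags(card: ScoreCard) -> list[str]:
    flags = []
    if card.PO is not None and card.PO > 1:
        flags.append(
            f"comprehensiveness PO = {card.PO:.4f} exceeds 1: the ontology "
            "has more elements than the library baseline average"
        )
    raw_ea = card.inputs.get("raw_clarity")
    if card.modes.clamp_to_unit and raw_ea is not None and raw_ea < 0:
        flags.append(f"clarity clamped to 0 (raw {raw_ea:.4f})")
    raw_ec = card.inputs.get("raw_consistency")
    if card.modes.clamp_to_unit and raw_ec is not None and raw_ec < 0:
        flags.append(f"consistency clamped to 0 (raw {raw_ec:.4f})")
    return flags
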