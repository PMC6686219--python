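import csv

import pytest

from ontoscore.synth import SynthSpec, fixture_lexicon, generate_ontology


@pytest.fixture
def default_spec():
    return SynthSpec(seed=7)


@pytest.fixture
def ontology_file(tmp_path, default_spec):
    path = tmp_path / "synth.ttl"
    generate_ontology(default_spec, path)
    return path


@pytest.fixture
def lexicon(default_spec):
    return fixture_lexicon(default_spec.vocabulary)


@pytest.fixture
def lexicon_csv(tmp_path, default_spec):
    path = tmp_path / "lexicon.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["token", "sense_count"])
        for word, count in sorted(default_spec.vocabulary.items()):
            writer.writerow([word, count])
    return path


@pytest.fixture
def write_turtle(tmp_path):
    """Write an inline Turtle snippet (with standard prefixes) to a file."""

    counter = iter(range(1000))

    def _write(body: str):
        path = tmp_path / f"inline{next(counter)}.ttl"
        preamble = (
            "@prefix ex: <http://example.org/t#> .\n"
            "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
            "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .\n"
            "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
            "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .\n\n"
        )
        path.write_text(preamble + body, encoding="utf-8")
        return path

    return _write
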