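"""Translate logical axioms into English review statements.

Every supported logical axiom becomes one plain-English sentence a domain
expert can judge true or false; entity labels (never IRIs) appear in the
text.  The accounting line shows that supported statements plus
unsupported axioms always equal the logical-axiom count.
"""

import tempfile
from pathlib import Path

from ontoscore import census_axioms, load_ontology, verbalize_ontology
from ontoscore.synth import SynthSpec, generate_ontology

with tempfile.TemporaryDirectory() as tmp:
    ttl_path = Path(tmp) / "demo.ttl"
    generate_ontology(SynthSpec(seed=3), ttl_path)
    model = load_ontology(ttl_path)

statements = verbalize_ontology(model)
for statement in statements.statements[:8]:
    print(f"[{statement.axiom_type}] {statement.sentence}")
print("...")
print(
    f"{len(statements.statements)} statements + "
    f"{statements.n_unsupported} unsupported = "
    f"{census_axioms(model).n_logical} logical axioms"
)
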