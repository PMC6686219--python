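"""Aspect weighting, exclusion, and the literal/classic equation modes.

The composite quality Q is a weighted sum of the aspect scores.  With the
social aspect excluded and explicit demonstration weights 0.15 (syntactic),
0.51 (semantic) and 0.33 (pragmatic) used as-is, perfect aspect scores give
Q = 0.99 — the weights sum to 0.99, not 1.  The second part shows the two
readings of the lawfulness equation: the literal form is the violation
fraction (higher = worse); the default classic form is its complement.
"""

from ontoscore import Weights, lawfulness, overall_quality
from ontoscore.model import AxiomCensus

weights = Weights(aspect=(0.15, 0.51, 0.33, 0.0), auto_normalize=False)
q = overall_quality(1.0, 1.0, 1.0, None, weights)
print(f"Q with perfect aspects and demonstration weights: {q:.2f}")

census = AxiomCensus(n_logical=80, n_non_logical=20)  # 100 axioms
for violations in (0, 5):
    literal = lawfulness(census, violations, "literal")
    classic = lawfulness(census, violations, "classic")
    print(
        f"{violations} violations of 100 axioms: "
        f"literal SL = {literal:.2f}, classic SL = {classic:.2f} "
        f"(complements sum to {literal + classic:.0f})"
    )
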