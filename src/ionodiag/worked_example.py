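"""Published worked example of the diagnosis on the Québec potato survey.

The most imbalanced specimen of the survey (largest Aitchison distance to
its nearest balanced reference) and that reference, as 6-part compositions
``(N, P, K, Mg, Ca, Fv)`` rounded to four decimals. They exercise the whole
diagnostic chain at desk scale: the perturbation vector taking the observed
composition onto the reference, the 5-nutrient Aitchison distance, and the
excess/deficiency ranking.
"""

from __future__ import annotations

from .coda import PARTS, close

__all__ = ["OBSERVED", "REFERENCE", "PRINTED_PERTURBATION", "PRINTED_DISTANCE"]

#: The most imbalanced observed leaf composition (N, P, K, Mg, Ca, Fv).
#: Published values sum to 0.9992 from 4-decimal rounding; closure restores
#: unit sum without altering any ratio, clr value or distance.
OBSERVED = close([0.0601, 0.0037, 0.0355, 0.0032, 0.0048, 0.8919], PARTS)

#: Its nearest balanced (true-negative) reference composition.
REFERENCE = close([0.0561, 0.0036, 0.0603, 0.0052, 0.0184, 0.8565], PARTS)

#: The perturbation vector as published alongside the two compositions.
PRINTED_PERTURBATION = (0.0919, 0.0965, 0.1696, 0.1629, 0.3832, 0.0959)

#: The published 5-nutrient Aitchison distance between the two.
PRINTED_DISTANCE = 1.135
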