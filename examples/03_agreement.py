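"""Agreement metrics: modified intersection-over-union and Cohen's kappa.

The modified IoU |P∩A|/|A| measures how much of an annotated region a
prediction recovers (annotation recall); kappa measures chance-corrected
agreement of presence/absence calls between two raters.
"""

import numpy as np

from morphohet.agreement import cohen_kappa, modified_iou, training_agreement_gate
from morphohet.types import Morphotype

# predicted mask covers 90% of the annotation plus some overprediction
A = {(r, c) for r in range(10) for c in range(10)}          # 100 annotated px
P = {(r, c) for r in range(9) for c in range(10)} | {(20, 20), (21, 21)}
score = modified_iou(P, A)
print(f"modified IoU = {score:.2f}: the prediction recovers {score:.0%} of the "
      "annotated region; overprediction outside A is not penalized.")

scores = {m: 0.95 for m in Morphotype}
scores[Morphotype.SE] = 0.90
print(f"training gate with SE at exactly 0.90 -> {training_agreement_gate(scores)} "
      "(the gate requires strictly > 0.9 for every morphotype)")

rng = np.random.default_rng(0)
truth = rng.uniform(size=200) < 0.4
rater_b = np.where(rng.uniform(size=200) < 0.85, truth, ~truth)  # 15% disagreement
res = cohen_kappa(truth, rater_b, morphotype=Morphotype.MU)
print(f"Cohen's kappa over {res.n_items} sections = {res.kappa:.3f}: "
      "chance-corrected agreement (1 = perfect, 0 = chance level).")
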