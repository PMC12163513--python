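"""Inter-rater and AI-vs-annotation agreement metrics.

Two complementary notions of agreement are used.  For training-time
segmentation quality, a modified intersection-over-union |P∩A|/|A| —
the recall of the annotated region A by the predicted region P,
deliberately asymmetric — must exceed 0.9 for every morphotype before a
model is accepted.  For human raters, pairwise Cohen's kappa is computed
per morphotype on presence/absence calls, regardless of prevalence;
ranked calls (dominant/secondary/tertiary) are compared separately by a
simple concordance rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .types import Morphotype, RaterCall, ValidationError

TRAINING_IOU_GATE = 0.9


def _as_pixel_set(region) -> set:
    if isinstance(region, np.ndarray):
        if region.dtype != bool:
            raise ValidationError("mask arrays must be boolean")
        return set(map(tuple, np.argwhere(region)))
    return set(region)


def modified_iou(P, A) -> float:
    """|P∩A| / |A|: fraction of the annotated region recovered by the prediction.

    ``P`` and ``A`` are pixel sets (iterables of coordinates) or boolean
    masks on the same raster frame.  Equals 1 whenever A ⊆ P.  Undefined
    (error) for an empty annotation.
    """
    P, A = _as_pixel_set(P), _as_pixel_set(A)
    if not A:
        raise ValidationError("annotated region A is empty; score undefined")
    return len(P & A) / len(A)


def training_agreement_gate(scores: dict[Morphotype, float]) -> bool:
    """True iff every per-morphotype score is strictly greater than 0.9."""
    if not scores:
        raise ValidationError("no per-morphotype scores given")
    return all(s > TRAINING_IOU_GATE for s in scores.values())


@dataclass
class KappaResult:
    rater_a: str
    rater_b: str
    morphotype: Morphotype
    kappa: float  # NaN when undefined
    n_items: int
    undefined: bool = False


def cohen_kappa(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    morphotype: Morphotype | None = None,
    rater_a: str = "a",
    rater_b: str = "b",
) -> KappaResult:
    """Cohen's kappa for paired binary presence/absence calls.

    kappa = (p_o - p_e) / (1 - p_e) with the marginal-product expected
    agreement p_e.  When both raters are constant (p_e = 1) the statistic
    is undefined and flagged rather than coerced.
    """
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("calls must be equal-length non-empty 1D vectors")
    n = a.size
    p_o = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        return KappaResult(rater_a, rater_b, morphotype, float("nan"), n, undefined=True)
    kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(rater_a, rater_b, morphotype, float(kappa), n)


def pairwise_kappa(calls: list[RaterCall]) -> pd.DataFrame:
    """Pairwise per-morphotype kappa over all rater pairs in a call table.

    Presence calls are aligned on the sections both raters scored.
    Returns a tidy frame (rater_a, rater_b, morphotype, kappa, n_items,
    undefined).
    """
    df = pd.DataFrame(
        {
            "rater_id": [c.rater_id for c in calls],
            "section_id": [c.section_id for c in calls],
            "morphotype": [c.morphotype for c in calls],
            "present": [c.present for c in calls],
        }
    )
    if df.empty:
        raise ValidationError("no rater calls given")
    raters = sorted(df["rater_id"].unique())
    rows = []
    for ra, rb in combinations(raters, 2):
        for morph in Morphotype:
            sub = df[df["morphotype"] == morph]
            wide = (
                sub.pivot_table(
                    index="section_id", columns="rater_id", values="present",
                    aggfunc="any", fill_value=False,
                )
                .reindex(columns=[ra, rb])
            )
            # restrict to sections both raters actually scored for this morphotype
            scored_a = set(sub.loc[sub["rater_id"] == ra, "section_id"])
            scored_b = set(sub.loc[sub["rater_id"] == rb, "section_id"])
            shared = sorted(scored_a & scored_b)
            if not shared:
                continue
            wide = wide.loc[shared]
            res = cohen_kappa(
                wide[ra].to_numpy(), wide[rb].to_numpy(),
                morphotype=morph, rater_a=ra, rater_b=rb,
            )
            rows.append(
                {
                    "rater_a": ra, "rater_b": rb, "morphotype": morph.name,
                    "kappa": res.kappa, "n_items": res.n_items,
                    "undefined": res.undefined,
                }
            )
    return pd.DataFrame(rows)


def concordance_rate(
    ai_calls: list[tuple[str, str, Morphotype]],
    pathologist_calls: list[tuple[str, str, Morphotype]],
) -> tuple[float, int, int]:
    """Fraction of ranked call slots on which the two sources agree.

    Calls are (section_id, rank, morphotype) triples; every slot present in
    either source must be present in both.  Returns
    (fraction, n_matching, n_total).
    """
    ai = {(s, r): m for s, r, m in ai_calls}
    path = {(s, r): m for s, r, m in pathologist_calls}
    if set(ai) != set(path):
        missing = set(ai) ^ set(path)
        raise ValidationError(f"unpaired call slots: {sorted(missing)[:5]}")
    if not ai:
        raise ValidationError("no call slots to compare")
    n_total = len(ai)
    n_match = sum(ai[k] == path[k] for k in ai)
    return n_match / n_total, n_match, n_total
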