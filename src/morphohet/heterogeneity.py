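"""Dominance rankings, dominant-morphotype combinations, and the
normalized Shannon index (NSI).

The Shannon index of a six-way morphotype proportion vector,
``H = -sum(p_k ln p_k)``, is normalized by its maximum ``ln 6`` (~1.79,
attained by the uniform profile) to give the NSI in [0, 1]: 0 for a
section composed of a single morphotype, 1 for equal 16.67% proportions
of all six.  The tumor NSI is the NSI of the arithmetic mean of the
section proportion vectors.

A tumor's dominant-morphotype combination (DMC) is the multiset of its
four section-level dominant morphotypes; its distribution pattern is the
multiplicity partition (4, 3+1, 2+2, 2+1+1 or 1+1+1+1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .types import Morphotype, SectionProfile, ValidationError

#: maximum Shannon entropy over six classes, printed as 1.79
H_MAX = float(np.log(6.0))

NSI_LOW_THRESHOLD = 0.3
NSI_HIGH_THRESHOLD = 0.7


def _check_proportions(proportions) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.shape[0] != 6:
        raise ValidationError(f"expected a length-6 proportion vector, got shape {p.shape}")
    if (p < 0).any():
        raise ValidationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"proportions sum to {p.sum():.8f}, expected 1 within 1e-6")
    return p


def shannon_index(proportions) -> float:
    """Shannon entropy H = -sum(p ln p) in nats; zero entries contribute 0."""
    p = _check_proportions(proportions)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() + 0.0)  # +0.0 avoids returning -0.0


def nsi(proportions) -> float:
    """Normalized Shannon index H / ln 6, in [0, 1]."""
    return min(shannon_index(proportions) / H_MAX, 1.0)


@dataclass
class DominanceRanking:
    """Morphotypes of one section ordered by decreasing proportion.

    Only morphotypes with proportion > 0 appear.  Exact ties are broken by
    the canonical morphotype order (CT, TB, MU, PP, DE, SE) and flagged.
    """

    section_id: str
    ordered_morphotypes: list[Morphotype]
    tie_flag: bool

    @property
    def dominant(self) -> Morphotype:
        return self.ordered_morphotypes[0]

    @property
    def secondary(self) -> Morphotype | None:
        return self.ordered_morphotypes[1] if len(self.ordered_morphotypes) > 1 else None

    @property
    def tertiary(self) -> Morphotype | None:
        return self.ordered_morphotypes[2] if len(self.ordered_morphotypes) > 2 else None


def dominance_ranking(profile: SectionProfile) -> DominanceRanking:
    """Rank a section's morphotypes: dominant, secondary, tertiary, ...

    Raises on an empty (all-filtered) profile.
    """
    if profile.empty:
        raise ValidationError(f"section {profile.section_id!r}: empty profile has no ranking")
    p = profile.proportions
    present = [m for m in Morphotype if p[m.value - 1] > 0]
    # stable sort on -proportion keeps canonical order within exact ties
    ordered = sorted(present, key=lambda m: -p[m.value - 1])
    props = [p[m.value - 1] for m in ordered]
    tie = any(a == b for a, b in zip(props, props[1:]))
    return DominanceRanking(profile.section_id, ordered, tie)


def dmc_pattern(dominants: list[Morphotype]) -> tuple[Counter, str]:
    """Multiset of the four section dominants and its distribution pattern.

    The pattern class is the multiplicity partition: "4", "3+1", "2+2",
    "2+1+1" or "1+1+1+1" (the last is representable though typically
    unobserved in real tumors).
    """
    if len(dominants) != 4:
        raise ValidationError(f"need exactly 4 section dominants, got {len(dominants)}")
    multiset = Counter(dominants)
    pattern = "+".join(str(c) for c in sorted(multiset.values(), reverse=True))
    return multiset, pattern


def dmc_string(multiset: Counter) -> str:
    """Canonical text form of a DMC, e.g. ``3xCT+1xPP``."""
    items = sorted(multiset.items(), key=lambda kv: (-kv[1], kv[0].value))
    return "+".join(f"{count}x{m.name}" for m, count in items)


def nsi_class(tumor_nsi: float) -> str:
    """Heterogeneity class: low (< 0.3), medium ([0.3, 0.7]), high (> 0.7)."""
    if not 0 <= tumor_nsi <= 1:
        raise ValidationError(f"NSI must be in [0, 1], got {tumor_nsi}")
    if tumor_nsi < NSI_LOW_THRESHOLD:
        return "low"
    if tumor_nsi <= NSI_HIGH_THRESHOLD:
        return "medium"
    return "high"


@dataclass
class TumorSummary:
    """Tumor-level aggregation of up to four section profiles."""

    tumor_id: str
    mean_profile: np.ndarray  # mean of non-empty section proportion vectors
    tumor_nsi: float
    section_nsis: dict[str, float]
    n_valid_sections: int
    dmc_multiset: Counter | None = None  # only with 4 valid sections
    pattern_class: str | None = None
    n_distinct_dominants: int | None = None
    nsi_class: str = field(init=False)
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        self.mean_profile = np.asarray(self.mean_profile, dtype=float)
        self.nsi_class = nsi_class(self.tumor_nsi)


def tumor_summary(profiles: list[SectionProfile]) -> TumorSummary:
    """Aggregate a tumor's section profiles.

    The tumor profile is the arithmetic mean of the non-empty section
    proportion vectors and the tumor NSI is the NSI of that mean.  DMC
    fields are filled only when all four sections are valid; tumors with
    fewer stay in proportion/NSI analyses but are excluded from DMC
    pattern tabulation.
    """
    valid = [p for p in profiles if not p.empty]
    if not valid:
        raise ValidationError("tumor has no non-empty section profiles")
    tumor_ids = {p.tumor_id for p in profiles}
    if len(tumor_ids) != 1:
        raise ValidationError(f"profiles span multiple tumors: {sorted(tumor_ids)}")
    mean_profile = np.mean([p.proportions for p in valid], axis=0)
    summary = TumorSummary(
        tumor_id=valid[0].tumor_id,
        mean_profile=mean_profile,
        tumor_nsi=nsi(mean_profile),
        section_nsis={p.section_id: nsi(p.proportions) for p in valid},
        n_valid_sections=len(valid),
    )
    if len(valid) == 4:
        dominants = [dominance_ranking(p).dominant for p in valid]
        multiset, pattern = dmc_pattern(dominants)
        summary.dmc_multiset = multiset
        summary.pattern_class = pattern
        summary.n_distinct_dominants = len(multiset)
    return summary


def cluster_tumor_profiles(
    summaries: list[TumorSummary],
    k: int = 9,
    method: str = "ward",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerative clustering of tumor mean profiles into ``k`` clusters.

    Ward linkage on Euclidean distance by default; deterministic given the
    inputs, so duplicated profiles always land in the same cluster.
    Assignments (1..k) are returned and also written to ``cluster_id``.
    """
    n = len(summaries)
    if k > n:
        raise ValidationError(f"k={k} exceeds number of tumors ({n})")
    X = np.vstack([s.mean_profile for s in summaries])
    if n == 1:
        labels = np.array([1])
    else:
        Z = linkage(X, method=method, metric=metric)
        labels = fcluster(Z, t=k, criterion="maxclust")
    for s, lab in zip(summaries, labels):
        s.cluster_id = int(lab)
    return labels


def group_median_profiles(summaries: list[TumorSummary]) -> dict[str, np.ndarray]:
    """Median mean-profile per DMC group (keyed by canonical DMC string).

    Provided as an alternative clustering substrate: cluster the per-group
    medians instead of per-tumor profiles.
    """
    groups: dict[str, list[np.ndarray]] = {}
    for s in summaries:
        if s.dmc_multiset is None:
            continue
        groups.setdefault(dmc_string(s.dmc_multiset), []).append(s.mean_profile)
    return {k: np.median(np.vstack(v), axis=0) for k, v in sorted(groups.items())}
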