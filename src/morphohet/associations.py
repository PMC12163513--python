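"""Association testing between morphotype quantities and clinical variables.

Categorical-vs-categorical comparisons use Pearson's chi-square (no
continuity correction; small expected counts are flagged, not silently
switched to exact tests).  Continuous morphotype proportions are compared
across groups with the Mann-Whitney U test (two groups) or the
Kruskal-Wallis test (more than two), with pairwise Mann-Whitney follow-ups
emitted only when the omnibus test is significant.  Multiplicity is
controlled by the Benjamini-Hochberg step-up procedure; the significance
threshold is an adjusted value below 0.10 (FDR < 10%).  The FDR family
is all outcome x covariate tests within one pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import Morphotype, ValidationError

FDR_LEVEL = 0.10
OMNIBUS_ALPHA = 0.05

WALL_LAYERS = ("mucosa", "submucosa", "muscularis", "fat")
#: collapse rule: mucosa+submucosa = superficial, muscularis+fat = deep
WALL_DEPTH = {"mucosa": "superficial", "submucosa": "superficial",
              "muscularis": "deep", "fat": "deep"}


@dataclass
class AssociationResult:
    outcome: str
    covariate: str
    test: str  # chi_square | kruskal_wallis | mann_whitney
    statistic: float
    p_value: float
    n_per_group: dict = field(default_factory=dict)
    p_adjusted: float | None = None
    significant: bool | None = None
    low_expected_cells: int = 0  # chi-square cells with expected count < 5
    pairwise: list["AssociationResult"] = field(default_factory=list)


def test_categorical(
    table, outcome: str = "outcome", covariate: str = "covariate"
) -> AssociationResult:
    """Pearson's chi-square on a contingency table of counts (>= 2x2).

    Zero row/column marginals are rejected; cells with expected count < 5
    are counted in ``low_expected_cells`` as a reliability flag.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValidationError(f"contingency table must be at least 2x2, got {obs.shape}")
    if (obs < 0).any():
        raise ValidationError("contingency table must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has a zero marginal")
    stat, p, _, expected = stats.chi2_contingency(obs, correction=False)
    return AssociationResult(
        outcome=outcome,
        covariate=covariate,
        test="chi_square",
        statistic=float(stat),
        p_value=float(p),
        n_per_group={str(i): int(obs[i].sum()) for i in range(obs.shape[0])},
        low_expected_cells=int((expected < 5).sum()),
    )


def test_proportion_vs_groups(
    values,
    groups,
    outcome: str = "proportion",
    covariate: str = "group",
    omnibus_alpha: float = OMNIBUS_ALPHA,
) -> AssociationResult:
    """Compare a continuous quantity across covariate groups.

    Two groups: Mann-Whitney U.  More than two: Kruskal-Wallis, followed by
    pairwise Mann-Whitney tests only when the omnibus p-value is below
    ``omnibus_alpha``.  Every group needs at least two observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must be equal-length")
    levels = sorted(pd.unique(groups).tolist())
    samples = {lv: values[groups == lv] for lv in levels}
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    for lv, s in samples.items():
        if s.size < 2:
            raise ValidationError(f"group {lv!r} has n={s.size} < 2")
    n_per_group = {str(lv): int(s.size) for lv, s in samples.items()}
    if len(levels) == 2:
        stat, p = stats.mannwhitneyu(samples[levels[0]], samples[levels[1]],
                                     alternative="two-sided")
        return AssociationResult(outcome, covariate, "mann_whitney",
                                 float(stat), float(p), n_per_group)
    stat, p = stats.kruskal(*samples.values())
    result = AssociationResult(outcome, covariate, "kruskal_wallis",
                               float(stat), float(p), n_per_group)
    if p < omnibus_alpha:
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a, b = levels[i], levels[j]
                s, pp = stats.mannwhitneyu(samples[a], samples[b],
                                           alternative="two-sided")
                result.pairwise.append(
                    AssociationResult(
                        outcome, f"{covariate}:{a} vs {b}", "mann_whitney",
                        float(s), float(pp),
                        {str(a): int(samples[a].size), str(b): int(samples[b].size)},
                    )
                )
    return result


def adjust_fdr(p_values, fdr_level: float = FDR_LEVEL) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, boolean significance calls at
    adjusted < ``fdr_level``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj, p_adj < fdr_level


def wall_location_test(location_calls: pd.DataFrame) -> AssociationResult:
    """Morphotype x colonic-wall-depth contingency test.

    ``location_calls`` has one row per detection with columns ``morphotype``
    and ``layer`` (mucosa, submucosa, muscularis, fat).  Layers are
    collapsed to superficial (mucosa+submucosa) vs deep (muscularis+fat)
    before a Pearson chi-square; a layer absent from the data drops out of
    the collapse without error.
    """
    df = location_calls.copy()
    unknown = set(df["layer"].unique()) - set(WALL_LAYERS)
    if unknown:
        raise ValidationError(f"unknown wall layer(s) {sorted(unknown)}; allowed: {WALL_LAYERS}")
    df["depth"] = df["layer"].map(WALL_DEPTH)
    table = pd.crosstab(df["morphotype"], df["depth"])
    # guard: the test needs both depths and >= 2 morphotypes represented
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    return test_categorical(table.to_numpy(), outcome="morphotype", covariate="wall_depth")


def association_battery(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("gender", "t_stage", "n_stage", "m_stage",
                                   "ajcc_stage", "grade", "site", "msi"),
    fdr_level: float = FDR_LEVEL,
) -> pd.DataFrame:
    """Run the full morphotype/NSI x clinical-covariate test battery.

    ``cohort`` is one row per tumor with columns ``p_CT..p_SE``,
    ``tumor_nsi`` and the clinical covariates.  Each outcome is tested
    against each covariate (Mann-Whitney / Kruskal-Wallis by the number of
    covariate levels); all resulting p-values form one BH family.
    Returns a tidy frame with columns outcome, covariate, test, statistic,
    p, p_adj, significant, plus gated pairwise rows marked by a
    ``pairwise_of`` column.
    """
    outcomes = [f"p_{m.name}" for m in Morphotype] + ["tumor_nsi"]
    results: list[AssociationResult] = []
    for outc in outcomes:
        if outc not in cohort.columns:
            continue
        for cov in covariates:
            if cov not in cohort.columns:
                continue
            sub = cohort[[outc, cov]].dropna()
            counts = sub[cov].value_counts()
            levels = counts[counts >= 2].index
            sub = sub[sub[cov].isin(levels)]
            if sub[cov].nunique() < 2:
                continue
            results.append(
                test_proportion_vs_groups(
                    sub[outc].to_numpy(), sub[cov].to_numpy(),
                    outcome=outc, covariate=cov,
                )
            )
    if not results:
        return pd.DataFrame(columns=["outcome", "covariate", "test", "statistic",
                                     "p", "p_adj", "significant", "pairwise_of"])
    p_adj, sig = adjust_fdr([r.p_value for r in results], fdr_level)
    rows = []
    for r, pa, s in zip(results, p_adj, sig):
        r.p_adjusted, r.significant = float(pa), bool(s)
        rows.append({"outcome": r.outcome, "covariate": r.covariate, "test": r.test,
                     "statistic": r.statistic, "p": r.p_value, "p_adj": r.p_adjusted,
                     "significant": r.significant, "pairwise_of": ""})
        for pw in r.pairwise:
            rows.append({"outcome": pw.outcome, "covariate": pw.covariate,
                         "test": pw.test, "statistic": pw.statistic, "p": pw.p_value,
                         "p_adj": np.nan, "significant": np.nan,
                         "pairwise_of": f"{r.outcome}~{r.covariate}"})
    return pd.DataFrame(rows)
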