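"""Pipeline orchestration: quantify -> heterogeneity -> associations ->
survival, plus the summary tables behind the dominance/DMC figures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import heterogeneity as het
from . import io as mio
from . import quantify as q
from .associations import association_battery
from .survival import strata_frame, stratified_survival_report
from .types import Morphotype, SectionProfile, ValidationError

logger = logging.getLogger(__name__)

PROP_COLUMNS = [f"p_{m.name}" for m in Morphotype]


@dataclass
class RunResult:
    section_profiles: pd.DataFrame
    tumor_summary: pd.DataFrame
    associations: pd.DataFrame
    survival: pd.DataFrame
    summaries: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _profiles_frame(profiles: list[SectionProfile], extra: dict) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"tumor_id": p.tumor_id, "section_id": p.section_id, "role": p.role}
        row.update({c: p.proportions[i] for i, c in enumerate(PROP_COLUMNS)})
        row["tumor_area_px"] = p.tumor_area_px
        row["retained_area_px"] = p.retained_area_px
        row.update(extra.get(p.section_id, {}))
        rows.append(row)
    cols = ["tumor_id", "section_id", "role", *PROP_COLUMNS,
            "tumor_area_px", "retained_area_px", "n_regions_kept", "n_regions_dropped"]
    return pd.DataFrame(rows, columns=cols)


def summaries_frame(summaries: list[het.TumorSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"tumor_id": s.tumor_id}
        row.update({c: s.mean_profile[i] for i, c in enumerate(PROP_COLUMNS)})
        row.update(
            tumor_nsi=s.tumor_nsi, nsi_class=s.nsi_class,
            n_valid_sections=s.n_valid_sections,
            dmc=het.dmc_string(s.dmc_multiset) if s.dmc_multiset else "",
            pattern_class=s.pattern_class or "",
            n_distinct_dominants=s.n_distinct_dominants,
            cluster_id=s.cluster_id,
        )
        rows.append(row)
    cols = ["tumor_id", *PROP_COLUMNS, "tumor_nsi", "nsi_class", "n_valid_sections",
            "dmc", "pattern_class", "n_distinct_dominants", "cluster_id"]
    return pd.DataFrame(rows, columns=cols)


def run_all(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> RunResult:
    """Run every stage on a study bundle (real or simulated).

    The bundle must hold ``sections.csv`` and the referenced rasters;
    ``clinical.csv`` is optional — without it the association and survival
    stages are skipped with a logged warning while quantification and
    heterogeneity still run.
    """
    study = Path(study_dir)
    cfg = dict(config or {})
    min_frac = float(cfg.get("min_frac", q.DEFAULT_MIN_FRAC))
    connectivity = int(cfg.get("connectivity", 8))
    cluster_k = int(cfg.get("cluster_k", 9))
    fdr_level = float(cfg.get("fdr_level", 0.10))
    warnings: list[str] = []

    sections = mio.read_sections_table(study / "sections.csv")
    profiles: list[SectionProfile] = []
    extra: dict[str, dict] = {}
    for row in sections.itertuples(index=False):
        lm = mio.read_label_map(study / row.path, row.section_id, row.tumor_id, row.role)
        prof, kept, dropped = q.quantify_section(lm, min_frac=min_frac,
                                                 connectivity=connectivity)
        profiles.append(prof)
        extra[prof.section_id] = {"n_regions_kept": len(kept),
                                  "n_regions_dropped": len(dropped)}
    prof_df = _profiles_frame(profiles, extra)

    summaries = []
    for tumor_id, group in _groupby_tumor(profiles):
        try:
            summaries.append(het.tumor_summary(group))
        except ValidationError as exc:
            warnings.append(f"tumor {tumor_id}: {exc}")
            logger.warning("tumor %s skipped: %s", tumor_id, exc)
    if summaries:
        k = min(cluster_k, len(summaries))
        het.cluster_tumor_profiles(summaries, k=k)
    summary_df = summaries_frame(summaries)

    assoc_df = pd.DataFrame(columns=["outcome", "covariate", "test", "statistic",
                                     "p", "p_adj", "significant", "pairwise_of"])
    surv_df = strata_frame([])
    clinical_path = study / "clinical.csv"
    if clinical_path.exists() and not summary_df.empty:
        clinical = mio.clinical_frame(mio.read_clinical_table(clinical_path))
        cohort = summary_df.merge(clinical, on="tumor_id", how="inner")
        assoc_df = association_battery(cohort, fdr_level=fdr_level)
        try:
            surv_df = strata_frame(stratified_survival_report(cohort))
        except ValidationError as exc:
            warnings.append(f"survival stage skipped: {exc}")
            logger.warning("survival stage skipped: %s", exc)
    else:
        warnings.append("clinical.csv missing; associations and survival skipped")
        logger.warning("clinical.csv missing; associations and survival skipped")

    result = RunResult(prof_df, summary_df, assoc_df, surv_df,
                       summaries=summaries, warnings=warnings)
    if out_dir is not None:
        mio.write_results_bundle(
            out_dir,
            section_profiles=prof_df, tumor_summary=summary_df,
            associations=assoc_df, survival=surv_df,
            seed=seed, config=cfg,
        )
    return result


def _groupby_tumor(profiles: list[SectionProfile]):
    by: dict[str, list[SectionProfile]] = {}
    for p in profiles:
        by.setdefault(p.tumor_id, []).append(p)
    return sorted(by.items())


def figure_tables(result: RunResult) -> dict[str, pd.DataFrame]:
    """Summary tables of dominance and heterogeneity structure.

    Returns:

    * ``dominance_frequency`` — morphotype x rank (dominant/secondary/
      tertiary) counts at section level, plus tumor-level dominant counts;
    * ``dmc_groups`` — frequency of each dominant-morphotype combination
      with its pattern class;
    * ``nsi_by_dmc`` — tumor NSI summary statistics per DMC group;
    * ``dominant_cooccurrence`` — 6x6 symmetric matrix counting tumors in
      which each (unordered) pair of morphotypes both appear as section
      dominants (diagonal: tumors where the morphotype dominates).
    """
    names = [m.name for m in Morphotype]
    rank_counts = pd.DataFrame(0, index=names,
                               columns=["dominant", "secondary", "tertiary"])
    prof_df = result.section_profiles
    for row in prof_df.itertuples(index=False):
        props = np.array([getattr(row, c) for c in PROP_COLUMNS])
        if props.sum() == 0:
            continue
        sp = SectionProfile(row.section_id, row.tumor_id, row.role, props,
                            int(row.tumor_area_px), int(row.retained_area_px))
        ranking = het.dominance_ranking(sp)
        for rank_name, m in zip(("dominant", "secondary", "tertiary"),
                                ranking.ordered_morphotypes):
            rank_counts.loc[m.name, rank_name] += 1
    rank_counts.index.name = "morphotype"

    dmc_rows = []
    cooc = pd.DataFrame(0, index=names, columns=names)
    nsi_rows = []
    for s in result.summaries:
        if s.dmc_multiset is None:
            continue
        key = het.dmc_string(s.dmc_multiset)
        dmc_rows.append({"dmc": key, "pattern_class": s.pattern_class})
        nsi_rows.append({"dmc": key, "tumor_nsi": s.tumor_nsi})
        doms = sorted(set(s.dmc_multiset), key=lambda m: m.value)
        for i, a in enumerate(doms):
            for b in doms[i:]:
                cooc.loc[a.name, b.name] += 1
                if a != b:
                    cooc.loc[b.name, a.name] += 1
    dmc_df = (
        pd.DataFrame(dmc_rows)
        .groupby(["dmc", "pattern_class"], as_index=False)
        .size()
        .rename(columns={"size": "n_tumors"})
        .sort_values(["n_tumors", "dmc"], ascending=[False, True])
        .reset_index(drop=True)
        if dmc_rows else pd.DataFrame(columns=["dmc", "pattern_class", "n_tumors"])
    )
    nsi_df = (
        pd.DataFrame(nsi_rows).groupby("dmc")["tumor_nsi"]
        .agg(["count", "median", "min", "max"]).reset_index()
        if nsi_rows else pd.DataFrame(columns=["dmc", "count", "median", "min", "max"])
    )
    cooc.index.name = "morphotype"
    return {
        "dominance_frequency": rank_counts.reset_index(),
        "dmc_groups": dmc_df,
        "nsi_by_dmc": nsi_df,
        "dominant_cooccurrence": cooc.reset_index(),
    }
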