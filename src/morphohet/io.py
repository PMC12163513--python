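"""Reading and writing of study artifacts.

Label maps are single-channel 8-bit PNG or TIFF rasters with values 0-6.
Tables are plain CSV with documented headers:

* ``sections.csv``: tumor_id, section_id, role, path
* ``clinical.csv``: columns of :class:`~morphohet.types.ClinicalRecord`
* ``rater_calls.csv``: rater_id, section_id, morphotype, present, rank
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .types import (
    ClinicalRecord,
    LabelMap,
    Morphotype,
    RaterCall,
    ValidationError,
)

CLINICAL_COLUMNS = [
    "tumor_id", "age", "gender", "t_stage", "n_stage", "m_stage",
    "ajcc_stage", "grade", "site", "msi",
    "os_time", "os_event", "rfs_time", "rfs_event",
]


def read_label_map(
    path: str | os.PathLike,
    section_id: str,
    tumor_id: str,
    role: str,
    pixel_area: float = 1.0,
) -> LabelMap:
    """Read a morphotype label raster from a PNG/TIFF file.

    Values outside 0..6 and non-integer rasters are rejected with the
    offending value and its location.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"label map file not found: {path}")
    pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 1:
        pixels = pixels[:, :, 0]
    if pixels.ndim != 2:
        raise ValidationError(
            f"{path}: expected single-channel raster, got shape {pixels.shape}"
        )
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValidationError(f"{path}: raster dtype {pixels.dtype} is not integer")
    return LabelMap(
        pixels=pixels.astype(np.uint8),
        section_id=section_id,
        tumor_id=tumor_id,
        role=role,
        pixel_area=pixel_area,
    )


def write_label_map(label_map: LabelMap, path: str | os.PathLike) -> None:
    """Write a label raster as 8-bit PNG or TIFF (by extension)."""
    iio.imwrite(Path(path), label_map.pixels.astype(np.uint8))


def read_sections_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read sections.csv linking tumors to their four anatomical sections."""
    df = pd.read_csv(path, dtype=str)
    required = {"tumor_id", "section_id", "role", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sections table missing columns: {sorted(missing)}")
    dup = df["section_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate section_id values: {sorted(df.loc[dup, 'section_id'].unique())}"
        )
    return df


def read_clinical_table(path: str | os.PathLike) -> list[ClinicalRecord]:
    """Read and validate clinical.csv; one :class:`ClinicalRecord` per row.

    Errors report the 1-based data row number of the offending record.
    """
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    dup = df["tumor_id"].astype(str).duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate tumor_id values: {sorted(df.loc[dup, 'tumor_id'].astype(str).unique())}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                ClinicalRecord(
                    tumor_id=str(row.tumor_id),
                    age=float(row.age),
                    gender=str(row.gender),
                    t_stage=str(row.t_stage),
                    n_stage=str(row.n_stage),
                    m_stage=str(row.m_stage),
                    ajcc_stage=str(row.ajcc_stage),
                    grade=int(row.grade),
                    site=str(row.site),
                    msi=str(row.msi),
                    os_time=float(row.os_time),
                    os_event=int(row.os_event),
                    rfs_time=float(row.rfs_time),
                    rfs_event=int(row.rfs_event),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"clinical table row {i}: {exc}") from None
    return records


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame in canonical column order."""
    return pd.DataFrame([vars(r) for r in records], columns=CLINICAL_COLUMNS)


def read_rater_calls(path: str | os.PathLike) -> list[RaterCall]:
    """Read rater_calls.csv (rater x section x morphotype presence/rank)."""
    df = pd.read_csv(path)
    required = {"rater_id", "section_id", "morphotype", "present", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"rater calls table missing columns: {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            calls.append(
                RaterCall(
                    rater_id=str(row.rater_id),
                    section_id=str(row.section_id),
                    morphotype=Morphotype.from_code(str(row.morphotype)),
                    present=bool(row.present),
                    rank=str(row.rank),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"rater calls row {i}: {exc}") from None
    return calls


def read_config(path: str | os.PathLike) -> dict:
    """Read a YAML config file of pipeline settings."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed float format + LF endings keep equal runs byte-identical
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_results_bundle(
    out_dir: str | os.PathLike,
    *,
    section_profiles: pd.DataFrame,
    tumor_summary: pd.DataFrame,
    associations: pd.DataFrame,
    survival: pd.DataFrame,
    seed: int | None = None,
    config: dict | None = None,
    version: str | None = None,
) -> dict[str, Path]:
    """Write the standard result tables plus a run-metadata file.

    Re-running with identical inputs and seed yields byte-identical tables.
    Empty cohorts produce header-only tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "section_profiles": out / "sections_profiles.csv",
        "tumor_summary": out / "tumor_summary.csv",
        "associations": out / "associations.csv",
        "survival": out / "survival_strata.csv",
    }
    _write_csv(section_profiles, paths["section_profiles"])
    _write_csv(tumor_summary, paths["tumor_summary"])
    _write_csv(associations, paths["associations"])
    _write_csv(survival, paths["survival"])

    from . import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True)
    meta = {
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config or {},
        "version": version or __version__,
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["run_metadata"] = meta_path
    return paths
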