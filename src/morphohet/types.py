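"""Core domain types for morphological-heterogeneity analysis.

The vocabulary is the six colorectal-adenocarcinoma morphotypes: complex
tubular (CT), solid/trabecular (TB), mucinous (MU), papillary (PP),
desmoplastic (DE) and serrated (SE).  Their order is fixed and total —
it defines raster label values (CT=1 .. SE=6), the column order of every
proportion vector and the tie-break order of dominance rankings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Morphotype",
    "MORPHOTYPES",
    "SECTION_ROLES",
    "LabelMap",
    "ClinicalRecord",
    "RaterCall",
    "Region",
    "SectionProfile",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant.

    Validation is total: malformed input always produces one of these,
    never a silent default.
    """


class Morphotype(enum.IntEnum):
    """The six morphotypes, in canonical order; the value is the raster label."""

    CT = 1  # complex tubular
    TB = 2  # solid/trabecular
    MU = 3  # mucinous
    PP = 4  # papillary (input alias: PA)
    DE = 5  # desmoplastic
    SE = 6  # serrated

    @classmethod
    def from_code(cls, code: str) -> "Morphotype":
        code = code.strip().upper()
        if code == "PA":  # historical alias for papillary
            code = "PP"
        try:
            return cls[code]
        except KeyError:
            raise ValidationError(
                f"unknown morphotype code {code!r}; allowed: "
                f"{[m.name for m in cls]} (alias PA for PP)"
            ) from None


MORPHOTYPES: tuple[Morphotype, ...] = tuple(Morphotype)

#: anatomical roles of the four tumor blocks sampled per case
SECTION_ROLES = ("serosa", "mesocolon", "luminal", "central")

_GENDERS = ("M", "F")
_T_STAGES = ("T1", "T2", "T3", "T4")
_N_STAGES = ("N0", "N1", "N2")
_M_STAGES = ("M0", "M1")
_AJCC_STAGES = ("I", "II", "III", "IV")
_GRADES = (1, 2, 3)
_SITES = ("right", "transverse", "left", "rectosigmoid", "rectum")
_MSI = ("MSI", "MSS")
_RANKS = ("dominant", "secondary", "tertiary", "none")


@dataclass
class LabelMap:
    """Per-section integer raster of morphotype classes.

    ``pixels`` is a 2D array over {0..6}: 0 is non-tumor/background, 1–6 the
    morphotypes in canonical order.  Coordinates are 0-based, row-major.
    """

    pixels: np.ndarray
    section_id: str
    tumor_id: str
    role: str
    pixel_area: float = 1.0  # physical area per pixel, um^2

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"label map {self.section_id!r}: raster must be 2D and non-empty, "
                f"got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError(
                f"label map {self.section_id!r}: raster must be integer, "
                f"got dtype {self.pixels.dtype}"
            )
        bad = (self.pixels < 0) | (self.pixels > 6)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"label map {self.section_id!r}: value {int(self.pixels[r, c])} "
                f"at (row={int(r)}, col={int(c)}) outside allowed range 0..6"
            )
        if self.role not in SECTION_ROLES:
            raise ValidationError(
                f"label map {self.section_id!r}: role {self.role!r} not in {SECTION_ROLES}"
            )
        if self.pixel_area <= 0:
            raise ValidationError("pixel_area must be positive")

    @property
    def tumor_area_px(self) -> int:
        """Total classified tumor area: count of pixels with value 1-6."""
        return int(np.count_nonzero(self.pixels))


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class ClinicalRecord:
    """One tumor's clinical covariates and right-censored survival outcomes."""

    tumor_id: str
    age: float
    gender: str
    t_stage: str
    n_stage: str
    m_stage: str
    ajcc_stage: str
    grade: int
    site: str
    msi: str
    os_time: float
    os_event: int
    rfs_time: float
    rfs_event: int

    def __post_init__(self) -> None:
        tid = self.tumor_id
        _require(self.age >= 0, f"{tid}: age must be >= 0")
        _require(self.gender in _GENDERS, f"{tid}: gender {self.gender!r} not in {_GENDERS}")
        _require(self.t_stage in _T_STAGES, f"{tid}: t_stage {self.t_stage!r} not in {_T_STAGES}")
        _require(self.n_stage in _N_STAGES, f"{tid}: n_stage {self.n_stage!r} not in {_N_STAGES}")
        _require(self.m_stage in _M_STAGES, f"{tid}: m_stage {self.m_stage!r} not in {_M_STAGES}")
        _require(
            self.ajcc_stage in _AJCC_STAGES,
            f"{tid}: ajcc_stage {self.ajcc_stage!r} not in {_AJCC_STAGES}",
        )
        self.grade = int(self.grade)
        _require(self.grade in _GRADES, f"{tid}: grade {self.grade!r} not in {_GRADES}")
        _require(self.site in _SITES, f"{tid}: site {self.site!r} not in {_SITES}")
        _require(self.msi in _MSI, f"{tid}: msi {self.msi!r} not in {_MSI}")
        for name in ("os_time", "rfs_time"):
            _require(getattr(self, name) >= 0, f"{tid}: {name} must be >= 0")
        for name in ("os_event", "rfs_event"):
            v = getattr(self, name)
            _require(v in (0, 1), f"{tid}: {name} must be 0 or 1, got {v!r}")


@dataclass
class RaterCall:
    """A rater's presence/rank call for one morphotype on one section."""

    rater_id: str
    section_id: str
    morphotype: Morphotype
    present: bool
    rank: str = "none"

    def __post_init__(self) -> None:
        _require(self.rank in _RANKS, f"rank {self.rank!r} not in {_RANKS}")
        _require(
            self.rank == "none" or self.present,
            f"rater {self.rater_id!r}, section {self.section_id!r}: "
            f"rank {self.rank!r} requires present=True",
        )


@dataclass(frozen=True)
class Region:
    """A connected component of one morphotype within a section raster."""

    morphotype: Morphotype
    area_px: int
    fragment_id: int
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    def __post_init__(self) -> None:
        _require(self.area_px >= 1, "region area_px must be >= 1")


@dataclass
class SectionProfile:
    """Six-way morphotype proportion vector of one section, post-filtering.

    ``proportions`` follows the canonical order (CT, TB, MU, PP, DE, SE) and
    sums to 1 over the retained area; an all-filtered section is flagged
    ``empty`` and excluded downstream.
    """

    section_id: str
    tumor_id: str
    role: str
    proportions: np.ndarray
    tumor_area_px: int
    retained_area_px: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        _require(
            self.proportions.shape == (6,),
            f"section {self.section_id!r}: proportions must be length 6",
        )
        _require((self.proportions >= 0).all(), "proportions must be non-negative")
        if self.retained_area_px > 0:
            _require(
                abs(self.proportions.sum() - 1.0) <= 1e-9,
                f"section {self.section_id!r}: proportions sum to "
                f"{self.proportions.sum()}, expected 1",
            )

    @property
    def empty(self) -> bool:
        return self.retained_area_px == 0
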