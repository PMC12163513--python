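"""Region extraction, small-region filtering and section proportion profiles.

A section raster is decomposed into connected components ("fragments") per
morphotype; fragments smaller than 5% of the section's classified tumor
area are discarded to suppress spurious small predictions, and proportions
are computed over the retained area.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .types import LabelMap, Morphotype, Region, SectionProfile, ValidationError

logger = logging.getLogger(__name__)

#: default minimum fragment size, as a fraction of section tumor area
DEFAULT_MIN_FRAC = 0.05

_STRUCTS = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def extract_regions(label_map: LabelMap, connectivity: int = 8) -> list[Region]:
    """Connected components of each morphotype label.

    Parameters
    ----------
    connectivity
        4 (edge-adjacent) or 8 (edge- or corner-adjacent, default: standard
        for blob-like histology regions).

    Returns regions with globally unique ``fragment_id`` per section; the
    union of region pixels equals all non-zero pixels.  An all-background
    map yields an empty list.
    """
    if connectivity not in _STRUCTS:
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = _STRUCTS[connectivity]
    regions: list[Region] = []
    fragment_id = 0
    for morph in Morphotype:
        mask = label_map.pixels == morph.value
        if not mask.any():
            continue
        labeled, n = ndimage.label(mask, structure=structure)
        areas = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        for comp, sl in enumerate(ndimage.find_objects(labeled), start=1):
            regions.append(
                Region(
                    morphotype=morph,
                    area_px=int(areas[comp - 1]),
                    fragment_id=fragment_id,
                    bounding_box=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                )
            )
            fragment_id += 1
    return regions


def filter_small_regions(
    regions: list[Region],
    tumor_area_px: int,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[Region]:
    """Keep only fragments occupying at least ``min_frac`` of the tumor area.

    The threshold is inclusive ("at least"): a fragment is kept iff
    ``area_px >= min_frac * tumor_area_px``.  Idempotent; the output is a
    subset of the input; raising ``min_frac`` never enlarges the result.
    """
    if tumor_area_px <= 0:
        raise ValidationError("tumor_area_px must be positive")
    if not 0 <= min_frac <= 1:
        raise ValidationError(f"min_frac must be in [0, 1], got {min_frac}")
    threshold = min_frac * tumor_area_px
    return [r for r in regions if r.area_px >= threshold]


def section_profile(
    label_map: LabelMap, retained_regions: list[Region]
) -> SectionProfile:
    """Morphotype proportion vector of a section over its retained area.

    ``proportions[k]`` is the retained area of morphotype k divided by the
    total retained area.  With no retained regions the profile is flagged
    empty (all-zero vector) and excluded from downstream tumor summaries.
    """
    areas = np.zeros(6)
    for r in retained_regions:
        areas[r.morphotype.value - 1] += r.area_px
    total = areas.sum()
    if total == 0:
        logger.warning(
            "section %s: no regions retained; profile flagged empty",
            label_map.section_id,
        )
        props = np.zeros(6)
    else:
        props = areas / total
    return SectionProfile(
        section_id=label_map.section_id,
        tumor_id=label_map.tumor_id,
        role=label_map.role,
        proportions=props,
        tumor_area_px=label_map.tumor_area_px,
        retained_area_px=int(total),
    )


def quantify_section(
    label_map: LabelMap,
    min_frac: float = DEFAULT_MIN_FRAC,
    connectivity: int = 8,
) -> tuple[SectionProfile, list[Region], list[Region]]:
    """Full per-section quantification: extract, filter, profile.

    Returns ``(profile, kept_regions, dropped_regions)``.
    """
    regions = extract_regions(label_map, connectivity=connectivity)
    kept = filter_small_regions(regions, label_map.tumor_area_px, min_frac)
    kept_ids = {r.fragment_id for r in kept}
    dropped = [r for r in regions if r.fragment_id not in kept_ids]
    return section_profile(label_map, kept), kept, dropped
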