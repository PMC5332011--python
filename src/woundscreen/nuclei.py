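"""Nucleus detection, validity gating and the Low Cell Count viability bin.

A well is imaged as 30 adjacent nuclear-stain fields.  Objects are detected
per field by auto-thresholding; an object counts as a valid nucleus when its
area lies within [60, 1400] px (inclusive by default) and its mean intensity
is strictly below the 12-bit saturation value 4095.  The per-well total over
all fields is gated at 3,300 nuclei (110 cells/field x 30 fields, just under
60% of the screen's median density of 187.5 cells/field); wells below the
gate are binned Low Cell Count, and that bin takes precedence over any
migration bin downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

LOW_CELL_COUNT = "LowCellCount"
NORMAL = "normal"


@dataclass(frozen=True)
class ViabilityParams:
    min_area_px: int = 60
    max_area_px: int = 1_400
    max_mean_intensity: float = 4_095.0
    fields_per_well: int = 30
    low_count_total: int = 3_300
    low_count_per_field: int = 110
    inclusive_bounds: bool = True
    enforce_consistency: bool = True

    def __post_init__(self) -> None:
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if (self.enforce_consistency
                and self.low_count_total != self.low_count_per_field * self.fields_per_well):
            raise ValueError(
                f"low_count_total ({self.low_count_total}) != low_count_per_field x "
                f"fields_per_well ({self.low_count_per_field * self.fields_per_well}); "
                "set enforce_consistency=False to override")


@dataclass(frozen=True)
class NucleusObject:
    area_px: int
    mean_intensity: float
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("nucleus area must be positive")


_EIGHT = np.ones((3, 3), dtype=bool)


def bright_object_mask(image: np.ndarray, min_contrast: float = 0.5) -> np.ndarray:
    """Otsu foreground mask with a guard against unimodal images.

    Otsu always returns a threshold, so on an image containing only
    background its mask is the background's own noise tail.  The guard
    requires the foreground/background mean separation to span at least
    ``min_contrast`` of the image's dynamic range; otherwise the image is
    declared object-free and an all-false mask is returned.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    mask = img > threshold_otsu(img)
    if not mask.any() or mask.all():
        return np.zeros(img.shape, dtype=bool)
    if img[mask].mean() - img[~mask].mean() < min_contrast * np.ptp(img):
        return np.zeros(img.shape, dtype=bool)
    return mask


def detect_nuclei(image: np.ndarray,
                  params: ViabilityParams = ViabilityParams()) -> list[NucleusObject]:
    """Detect candidate nuclei in one field (unfiltered).

    Otsu threshold, 8-connected labelling, then per-object area, mean
    intensity and centroid.  Objects of every size are returned — the
    validity gates of :func:`count_valid_nuclei` do the filtering.  Touching
    nuclei merge into one object — a documented limitation of connectivity
    labelling.  A contrast-free or background-only image yields an empty
    list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    mask = bright_object_mask(img)
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(img), labels, idx)
    means = ndi.mean(img, labels, idx)
    cents = ndi.center_of_mass(mask, labels, idx)
    return [NucleusObject(area_px=int(a), mean_intensity=float(m),
                          centroid=(float(cr), float(cc)))
            for a, m, (cr, cc) in zip(areas, means, cents)]


def is_valid_nucleus(obj: NucleusObject, params: ViabilityParams = ViabilityParams()) -> bool:
    if params.inclusive_bounds:
        in_size = params.min_area_px <= obj.area_px <= params.max_area_px
    else:
        in_size = params.min_area_px < obj.area_px < params.max_area_px
    return in_size and obj.mean_intensity < params.max_mean_intensity


def count_valid_nuclei(objects: list[NucleusObject],
                       params: ViabilityParams = ViabilityParams()) -> int:
    """Count objects passing the size and saturation gates."""
    return sum(is_valid_nucleus(o, params) for o in objects)


def well_total(field_counts: list[int],
               params: ViabilityParams = ViabilityParams(),
               scale_to_full: bool = False) -> float:
    """Sum valid counts over a well's fields.

    With ``scale_to_full`` the sum is rescaled to ``fields_per_well`` when
    fewer fields were imaged (off by default; the assay images all 30).
    """
    if not field_counts:
        raise ValueError("well has no imaged fields")
    total = float(sum(field_counts))
    if scale_to_full and len(field_counts) != params.fields_per_well:
        total *= params.fields_per_well / len(field_counts)
    return total


def bin_cell_count(well_total: float,
                   params: ViabilityParams = ViabilityParams()) -> str:
    """'LowCellCount' iff the well's valid-nucleus total is strictly below the
    gate, else 'normal'."""
    return LOW_CELL_COUNT if well_total < params.low_count_total else NORMAL
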