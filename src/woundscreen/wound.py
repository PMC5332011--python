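"""Wound-area measurement for scratch-assay images.

The pipeline mirrors the classic high-content protocol: smooth, flatten the
background, auto-threshold for light (cell-covered) objects, dilate the cell
mask by 4 px so the measured wound never includes cell edges, invert to get
the cell-free region, and drop connected components below a timepoint-specific
minimum size — 10,000 px at t=0 (removes monolayer tears) and 100 px at 24 h
(removes residual slivers; bright debris is already part of the cell mask).
The migrated area is Am = A0 - A24 and is deliberately not clipped at zero:
a negative Am records wound enlargement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu


class DegenerateImageWarning(UserWarning):
    """The image has no intensity contrast; wound area reported as 0."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the wound segmentation pipeline.

    ``smooth_kernel_px`` is the median-filter window (odd; 1 disables).
    ``flatten_kernel_px`` is the Gaussian scale of the background estimate
    subtracted before thresholding (0 disables; synthetic images carry no
    shading so flattening is off by default).  ``dilation_px`` is the radius
    of the square element grown onto the cell mask.
    """

    smooth_kernel_px: int = 3
    flatten_kernel_px: int = 0
    dilation_px: int = 4
    min_region_A0_px: int = 10_000
    min_region_A24_px: int = 100
    threshold_method: str = "otsu"

    def __post_init__(self) -> None:
        if self.smooth_kernel_px < 1 or self.smooth_kernel_px % 2 == 0:
            raise ValueError("smooth_kernel_px must be a positive odd integer")
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")
        if not self.min_region_A0_px >= self.min_region_A24_px > 0:
            raise ValueError("require min_region_A0_px >= min_region_A24_px > 0")
        if self.threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")

    def min_region(self, timepoint: str) -> int:
        if timepoint == "A0":
            return self.min_region_A0_px
        if timepoint == "A24":
            return self.min_region_A24_px
        raise ValueError(f"timepoint must be 'A0' or 'A24', got {timepoint!r}")


@dataclass
class WoundMeasurement:
    """Per-well wound areas and the derived migrated area, in pixels^2."""

    A0_px: float
    A24_px: float
    pixel_size_um: float = 2.97
    qc_flag: str = "ok"

    @property
    def Am_px(self) -> float:
        return migrated_area(self.A0_px, self.A24_px)

    def area_mm2(self, area_px: float) -> float:
        """Convert a pixel area to mm^2 at this measurement's pixel size."""
        return area_px * (self.pixel_size_um / 1000.0) ** 2


_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity for component labelling


def measure_wound_area(image: np.ndarray, timepoint: str,
                       params: SegmentationParams = SegmentationParams()) -> int:
    """Measure the cell-free wound area (px^2) of one scratch image.

    ``timepoint`` selects the minimum component size: 'A0' or 'A24'.  A
    constant (contrast-free) image cannot be thresholded; it yields area 0
    with a :class:`DegenerateImageWarning` instead of raising.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    min_region = params.min_region(timepoint)

    if params.smooth_kernel_px > 1:
        img = ndi.median_filter(img, size=params.smooth_kernel_px)
    if params.flatten_kernel_px > 0:
        background = ndi.gaussian_filter(img, sigma=params.flatten_kernel_px)
        img = np.clip(img - background + background.mean(), 0, None)

    if np.ptp(img) == 0:
        warnings.warn("constant image: threshold degenerate, wound area set to 0",
                      DegenerateImageWarning, stacklevel=2)
        return 0

    cells = img > threshold_otsu(img)
    if params.dilation_px > 0:
        size = 2 * params.dilation_px + 1
        cells = ndi.binary_dilation(cells, structure=np.ones((size, size), bool))
    cell_free = ~cells

    labels, n = ndi.label(cell_free, structure=_EIGHT)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(sizes[sizes >= min_region].sum())


def measure_wound_pair(image_a0, image_a24,
                       params: SegmentationParams = SegmentationParams(),
                       pixel_size_um: float = 2.97) -> WoundMeasurement:
    """Measure both timepoints of a wound pair."""
    return WoundMeasurement(
        A0_px=measure_wound_area(image_a0, "A0", params),
        A24_px=measure_wound_area(image_a24, "A24", params),
        pixel_size_um=pixel_size_um)


def migrated_area(A0_px: float, A24_px: float) -> float:
    """Am = A0 - A24; negative values (wound enlargement) pass through."""
    if A0_px < 0 or A24_px < 0:
        raise ValueError("areas must be non-negative")
    return A0_px - A24_px


#: nominal scratch geometry: 0.38 x 3.8 mm at 2.97 um/pixel
NOMINAL_SCRATCH_MM = (0.38, 3.8)


def nominal_scratch_area_px(pixel_size_um: float = 2.97) -> float:
    """Pixel area of the nominal scratch rectangle at a given pixel size."""
    w_mm, l_mm = NOMINAL_SCRATCH_MM
    return (w_mm * 1000 / pixel_size_um) * (l_mm * 1000 / pixel_size_um)


def flag_scratch_failure(measurement: WoundMeasurement,
                         min_valid_A0_px: float) -> str:
    """Automated surrogate for by-eye exclusion: a t=0 wound far below the
    nominal scratch area means the scratch failed; the well is excluded from
    downstream normalization."""
    return "failed_scratch" if measurement.A0_px < min_valid_A0_px else "ok"


# ---------------------------------------------------------------------------
# sentinel-plate A0 substitution


def sentinel_A0(plate_measurements: pd.DataFrame) -> pd.Series:
    """Extract per-well-position A0 values from a sentinel plate.

    The scratch tool wounds every plate of a batch with the same pin head, so
    one specially seeded plate imaged at t=0 supplies A0 for all plates of
    the batch.  ``plate_measurements`` needs columns ``well`` and ``A0_px``;
    returns a Series indexed by well.
    """
    if plate_measurements.empty:
        raise ValueError("sentinel plate has no measured A0 wells")
    s = plate_measurements.set_index("well")["A0_px"].astype(float)
    if s.index.has_duplicates:
        raise ValueError("sentinel plate lists a well twice")
    return s


def sentinel_cv(shared_a0: pd.Series) -> float:
    """Coefficient of variation (s.d./mean) of sentinel A0 across pins, as a
    fraction.  Reported as a batch-level QC figure."""
    mean = shared_a0.mean()
    if mean == 0:
        raise ValueError("sentinel A0 mean is zero")
    return float(shared_a0.std(ddof=1) / mean)


def apply_sentinel(wells: pd.DataFrame, shared_a0: pd.Series) -> pd.DataFrame:
    """Fill each well's A0 from the sentinel plate wherever A0 is missing.

    Raises ``KeyError`` naming the well position when the sentinel plate has
    no A0 for a well that needs one.
    """
    out = wells.copy()
    missing = out["A0_px"].isna()
    for idx in out.index[missing]:
        well = out.at[idx, "well"]
        if well not in shared_a0.index:
            raise KeyError(f"sentinel plate has no A0 for well {well}")
        out.at[idx, "A0_px"] = shared_a0[well]
    return out


def measurements_to_frame(records: list[tuple[str, str, WoundMeasurement]]) -> pd.DataFrame:
    """Tabulate (plate, well, measurement) triples as the interchange CSV rows."""
    return pd.DataFrame(
        [{"plate_id": p, "well": w, "A0_px": m.A0_px, "A24_px": m.A24_px,
          "Am_px": m.Am_px, "qc_flag": m.qc_flag} for p, w, m in records])
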