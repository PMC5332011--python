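"""Synthetic microscopy images and plate-level screen data with known ground truth.

Every downstream stage of the scratch-wound screen pipeline (wound segmentation,
nuclei counting, morphometrics, hit calling) is exercised against data produced
here, so each generator records the exact truth it embedded: cell-free pixel
areas for wound pairs, per-nucleus geometry for counting fields, per-cell
ellipse parameters for morphometry, and per-siRNA effect classes for plates.

Wound images emulate a 4x widefield acquisition (2.97 um/pixel) of a confluent
fluorescent monolayer carrying a rectangular scratch of nominally 0.38 x 3.8 mm
(~128 x 1280 px); morphology fields emulate a 20x acquisition (0.59 um/pixel).
The monolayer is rendered as clipped, blurred speckle above a dark background —
downstream thresholding needs a bright/dark contrast, not realistic cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "ImageSpec",
    "WoundTruth",
    "CellTruth",
    "CellFieldTruth",
    "EffectModel",
    "generate_wound_pair",
    "generate_nuclei_image",
    "generate_cell_field",
    "random_cell_field",
    "generate_screen_dataset",
]

#: intensity of the cell-covered monolayer / cell interiors (16-bit scale)
FOREGROUND_LEVEL = 2000.0
SATURATION = 65535


class GeometryError(ValueError):
    """A requested geometry does not fit inside the image."""


class CapacityError(RuntimeError):
    """Requested objects could not be placed without overlap."""


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and intensity model of one synthetic acquisition.

    ``pixel_size_um`` defaults to the 4x wound-imaging scale; use 0.59 for
    20x morphology fields.  ``noise_sd`` = 0 yields exactly two-level images,
    which the segmentation oracle tests rely on.
    """

    height_px: int
    width_px: int
    pixel_size_um: float = 2.97
    background_level: float = 200.0
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass
class WoundTruth:
    """Ground truth for one wound image pair.

    ``wound_rect_px`` is the half-open rectangle (row0, col0, row1, col1) of
    the cell-free scratch at t=0.  After generation the exact cell-free pixel
    areas of both timepoints are filled in: ``a0_cellfree_px`` includes tear
    holes, ``a24_cellfree_px`` is the remaining wound minus bright debris.
    ``a0_wound_px`` / ``a24_wound_px`` are the scratch rectangles alone, which
    satisfy a24_wound = (1 - closure_fraction) * a0_wound exactly whenever
    closure_fraction * height is integral.
    """

    wound_rect_px: tuple[int, int, int, int]
    closure_fraction: float
    debris_specks: int = 0
    tear_specks: int = 0
    # filled by generate_wound_pair
    a0_wound_px: int | None = None
    a24_wound_px: int | None = None
    a0_cellfree_px: int | None = None
    a24_cellfree_px: int | None = None
    a24_rect_px: tuple[int, int, int, int] | None = None
    tear_rects: list[tuple[int, int, int, int]] = field(default_factory=list)
    debris_rects: list[tuple[int, int, int, int]] = field(default_factory=list)
    debris_px: int = 0

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.wound_rect_px
        if not (r1 > r0 and c1 > c0):
            raise GeometryError("wound rectangle must have positive extent")
        if not 0.0 <= self.closure_fraction <= 1.0:
            raise ValueError("closure_fraction must lie in [0, 1]")
        if self.debris_specks < 0 or self.tear_specks < 0:
            raise ValueError("speck counts must be non-negative")


@dataclass(frozen=True)
class CellTruth:
    """One synthetic cell: an ellipse with a mean F-actin intensity."""

    centroid: tuple[float, float]
    area_px: float
    length_px: float
    breadth_px: float
    orientation: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("cell area must be positive")
        if self.length_px < self.breadth_px:
            raise ValueError("length_px must be >= breadth_px")


@dataclass
class CellFieldTruth:
    """Ground truth for a field of non-overlapping cells."""

    cells: list[CellTruth]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class EffectModel:
    """Statistical model of siRNA effects on a mock-normalised migration scale.

    Library siRNAs fall into four truth classes.  Effects are multiplicative
    on the mock-relative migration score (mock = 1.0); noise is additive
    Gaussian.  Well-level noise is shared between the two technical replicate
    plates (both replicates derive from the same transfection mix), replicate
    noise is independent per replicate.  Lethal siRNAs scale the endpoint cell
    count by ``lethal_count_factor`` and also impair migration, so that the
    viability gate's precedence over migration bins is exercised.
    """

    p_inhibitor: float = 0.05
    p_accelerator: float = 0.05
    p_lethal: float = 0.02
    inhibitor_effect: float = 0.5
    accelerator_effect: float = 1.5
    lethal_count_factor: float = 0.3
    well_noise_sd: float = 0.1
    replicate_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_inhibitor, self.p_accelerator, self.p_lethal)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("class probabilities must lie in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("class probabilities must sum to <= 1")
        if min(self.inhibitor_effect, self.accelerator_effect, self.lethal_count_factor) <= 0:
            raise ValueError("effect factors must be positive")
        if self.well_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise s.d.s must be non-negative")


# ---------------------------------------------------------------------------
# wound image pairs


def _speckle_field(shape, level, sd, rng):
    """Clipped, blurred speckle above ``level`` — a cheap monolayer texture."""
    if sd == 0:
        return np.full(shape, level, dtype=float)
    speckle = rng.normal(0.0, sd * 2.0, size=shape)
    speckle = ndi.gaussian_filter(speckle, sigma=1.5)
    return np.clip(level + speckle, 0, SATURATION)


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, SATURATION).astype(np.uint16)


def _place_rects(rng, n, area_lo, area_hi, allowed, taken, margin, max_tries=500):
    """Place ``n`` non-overlapping rectangles with areas in [area_lo, area_hi]
    inside the boolean ``allowed`` region, at least ``margin`` px from pixels
    already marked in ``taken``.  Returns the rect list and updates ``taken``."""
    h, w = allowed.shape
    rects = []
    clear = allowed & ~ndi.binary_dilation(taken, iterations=margin) if taken.any() else allowed
    for _ in range(n):
        for _attempt in range(max_tries):
            area = int(rng.integers(area_lo, area_hi + 1))
            rh = int(rng.integers(max(2, int(math.sqrt(area) / 2)), int(math.sqrt(area) * 2) + 1))
            rw = max(1, area // rh)
            r0 = int(rng.integers(0, max(1, h - rh)))
            c0 = int(rng.integers(0, max(1, w - rw)))
            sl = (slice(r0, r0 + rh), slice(c0, c0 + rw))
            if clear[sl].all():
                rects.append((r0, c0, r0 + rh, c0 + rw))
                taken[sl] = True
                block = (slice(max(0, r0 - margin), r0 + rh + margin),
                         slice(max(0, c0 - margin), c0 + rw + margin))
                clear[block] = False
                break
        else:
            raise CapacityError("could not place a non-overlapping rectangle")
    return rects


def generate_wound_pair(spec: ImageSpec, truth: WoundTruth):
    """Render the t=0 and t=24h images of one scratch wound.

    The wound closes symmetrically from both long edges by
    ``closure_fraction`` of its area.  Tear holes (cell-free, 100-9999 px)
    are placed in the monolayer of the t=0 image only; bright debris specks
    (<= 50 px each) are placed inside the remaining wound of the t=24h image.
    Returns ``(image_a0, image_a24, truth)`` with the truth's exact cell-free
    areas filled in.
    """
    r0, c0, r1, c1 = truth.wound_rect_px
    h, w = spec.shape
    if not (0 <= r0 and r1 <= h and 0 <= c0 and c1 <= w):
        raise GeometryError("wound rectangle lies outside the image")

    rng = np.random.default_rng(spec.seed)
    wound_h, wound_w = r1 - r0, c1 - c0

    monolayer = _speckle_field(spec.shape, FOREGROUND_LEVEL, spec.noise_sd, rng)
    background = _speckle_field(spec.shape, spec.background_level, spec.noise_sd, rng)

    # --- A0: open wound plus tear holes in the monolayer
    cellfree0 = np.zeros(spec.shape, dtype=bool)
    cellfree0[r0:r1, c0:c1] = True
    taken = cellfree0.copy()
    margin = 12  # keep tears clearly separate from the wound and each other
    tear_rects = _place_rects(rng, truth.tear_specks, 100, 9_999, np.ones(spec.shape, bool),
                              taken, margin)
    for tr0, tc0, tr1, tc1 in tear_rects:
        cellfree0[tr0:tr1, tc0:tc1] = True
    img_a0 = np.where(cellfree0, background, monolayer)

    # --- A24: wound narrowed symmetrically from both long edges
    n_close = int(round(truth.closure_fraction * wound_h))
    top = n_close // 2
    bot = n_close - top
    nr0, nr1 = r0 + top, r1 - bot
    cellfree24 = np.zeros(spec.shape, dtype=bool)
    if nr1 > nr0:
        cellfree24[nr0:nr1, c0:c1] = True
    a24_rect = (nr0, c0, max(nr0, nr1), c1)

    debris_px = 0
    debris_rects: list[tuple[int, int, int, int]] = []
    if truth.debris_specks and nr1 > nr0:
        allowed = np.zeros(spec.shape, dtype=bool)
        # keep debris a few px inside the wound so specks stay isolated islands
        pad = 8
        if nr1 - nr0 > 2 * pad and c1 - c0 > 2 * pad:
            allowed[nr0 + pad:nr1 - pad, c0 + pad:c1 - pad] = True
        taken24 = np.zeros(spec.shape, dtype=bool)
        debris_rects.extend(_place_rects(rng, truth.debris_specks, 16, 50, allowed, taken24, 6))
        for dr0, dc0, dr1, dc1 in debris_rects:
            cellfree24[dr0:dr1, dc0:dc1] = False
            debris_px += (dr1 - dr0) * (dc1 - dc0)
    img_a24 = np.where(cellfree24, background, monolayer)

    out = replace_truth(truth,
                        a0_wound_px=wound_h * wound_w,
                        a24_wound_px=max(0, nr1 - nr0) * wound_w,
                        a0_cellfree_px=int(cellfree0.sum()),
                        a24_cellfree_px=int(cellfree24.sum()),
                        a24_rect_px=a24_rect,
                        tear_rects=tear_rects,
                        debris_rects=debris_rects,
                        debris_px=debris_px)
    return _to_uint16(img_a0), _to_uint16(img_a24), out


def replace_truth(truth: WoundTruth, **kw) -> WoundTruth:
    out = WoundTruth(truth.wound_rect_px, truth.closure_fraction,
                     truth.debris_specks, truth.tear_specks)
    for k, v in kw.items():
        setattr(out, k, v)
    return out


# ---------------------------------------------------------------------------
# nuclei fields and whole-cell fields


def _sample_ellipse(rng, area_lo, area_hi, max_aspect):
    area = float(rng.uniform(area_lo, area_hi))
    aspect = float(rng.uniform(1.0, max_aspect))
    a = math.sqrt(area * aspect / math.pi)  # semi-major
    b = area / (math.pi * a)                # semi-minor
    return a, b


def _place_ellipses(rng, shape, n, area_range, max_aspect, gap=3.0, max_tries=400):
    """Rejection-place ``n`` non-overlapping ellipses; returns (a, b, r, c, theta)."""
    h, w = shape
    placed = []  # (r, c, radius)
    out = []
    for _ in range(n):
        for _attempt in range(max_tries):
            a, b = _sample_ellipse(rng, *area_range, max_aspect)
            theta = float(rng.uniform(0, math.pi))
            r = float(rng.uniform(a + 2, h - a - 2))
            c = float(rng.uniform(a + 2, w - a - 2))
            if all((r - pr) ** 2 + (c - pc) ** 2 > (a + prad + gap) ** 2
                   for pr, pc, prad in placed):
                placed.append((r, c, a))
                out.append((a, b, r, c, theta))
                break
        else:
            raise CapacityError(
                f"could not place {n} non-overlapping objects in a {h}x{w} field")
    return out


def generate_nuclei_image(spec: ImageSpec, n_cells: int,
                          size_range_px: tuple[float, float] = (100.0, 400.0),
                          intensity: float = 3000.0):
    """Render a nuclear-stain field of ``n_cells`` non-overlapping bright
    elliptical nuclei with areas drawn in ``size_range_px``.

    Returns ``(image, CellFieldTruth)`` where each truth entry records the
    realised (rasterised) area.  Raises :class:`CapacityError` when the field
    cannot hold the requested count without overlap.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(spec.seed)
    img = _speckle_field(spec.shape, spec.background_level, spec.noise_sd, rng)
    cells: list[CellTruth] = []
    for a, b, r, c, theta in _place_ellipses(rng, spec.shape, n_cells,
                                             size_range_px, max_aspect=1.6):
        rr, cc = draw_ellipse(r, c, a, b, shape=spec.shape, rotation=theta)
        level = intensity * float(rng.uniform(0.85, 1.15))
        img[rr, cc] = level + (rng.normal(0, spec.noise_sd, rr.size) if spec.noise_sd else 0.0)
        cells.append(CellTruth(centroid=(r, c), area_px=float(rr.size),
                               length_px=2 * a, breadth_px=2 * b,
                               orientation=theta, mean_intensity=level))
    return _to_uint16(img), CellFieldTruth(cells)


def random_cell_field(spec: ImageSpec, n_cells: int,
                      area_range_px: tuple[float, float] = (1500.0, 4000.0),
                      aspect_range: tuple[float, float] = (1.0, 1.5),
                      intensity_range: tuple[float, float] = (1200.0, 2200.0)) -> CellFieldTruth:
    """Draw a random non-overlapping whole-cell truth layout for a field."""
    rng = np.random.default_rng(spec.seed)
    cells = []
    placed = []
    h, w = spec.shape
    for _ in range(n_cells):
        for _attempt in range(400):
            area = float(rng.uniform(*area_range_px))
            aspect = float(rng.uniform(*aspect_range))
            a = math.sqrt(area * aspect / math.pi)
            b = area / (math.pi * a)
            theta = float(rng.uniform(0, math.pi))
            r = float(rng.uniform(a + 3, h - a - 3))
            c = float(rng.uniform(a + 3, w - a - 3))
            if all((r - pr) ** 2 + (c - pc) ** 2 > (a + prad + 4) ** 2
                   for pr, pc, prad in placed):
                placed.append((r, c, a))
                cells.append(CellTruth((r, c), area, 2 * a, 2 * b, theta,
                                       float(rng.uniform(*intensity_range))))
                break
        else:
            raise CapacityError("could not place the requested cells")
    return CellFieldTruth(cells)


def generate_cell_field(spec: ImageSpec, truth: CellFieldTruth,
                        factin_texture_sd: float = 150.0):
    """Render registered nuclear / whole-cell / F-actin channels for a truth field.

    Each cell is an ellipse; its nucleus is a concentric ellipse at 35% of the
    cell axes.  The F-actin channel gives every cell its truth mean intensity
    with Gaussian within-cell variation of ``factin_texture_sd`` (set 0 for
    perfectly flat texture).  Raises ``ValueError`` if any two cells overlap.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nuclear = _speckle_field(spec.shape, spec.background_level, spec.noise_sd, rng)
    wholecell = _speckle_field(spec.shape, spec.background_level, spec.noise_sd, rng)
    factin = _speckle_field(spec.shape, spec.background_level, spec.noise_sd, rng)
    occupancy = np.zeros(spec.shape, dtype=np.uint8)
    for cell in truth.cells:
        r, c = cell.centroid
        a, b = cell.length_px / 2, cell.breadth_px / 2
        rr, cc = draw_ellipse(r, c, a, b, shape=spec.shape, rotation=cell.orientation)
        occupancy[rr, cc] += 1
        if np.any(occupancy[rr, cc] > 1):
            raise ValueError("cells overlap: invalid truth field")
        wholecell[rr, cc] = FOREGROUND_LEVEL
        tex = rng.normal(0.0, factin_texture_sd, rr.size) if factin_texture_sd else 0.0
        factin[rr, cc] = cell.mean_intensity + tex
        nr, nc = draw_ellipse(r, c, 0.35 * a, 0.35 * b, shape=spec.shape,
                              rotation=cell.orientation)
        nuclear[nr, nc] = 3000.0
    return _to_uint16(nuclear), _to_uint16(wholecell), _to_uint16(factin)


# ---------------------------------------------------------------------------
# plate-level screen simulator

#: endpoint cell count of a healthy well: 187.5 cells/field x 30 fields
BASE_CELL_COUNT = 5625.0
#: baseline migrated-area surrogate for a mock well, in px^2
BASE_AM_PX = 80_000.0
COUNT_NOISE_SD = 0.05

_CLASS_ORDER = ("neutral", "inhibitor", "accelerator", "lethal")


def _plate_rng(seed: int, plate_index: int) -> np.random.Generator:
    # child streams keyed by (root seed, plate index): subsets reproduce exactly
    return np.random.default_rng([seed, plate_index])


def generate_screen_dataset(n_plates: int, layout, effects: EffectModel):
    """Simulate a primary-style screen: ``n_plates`` library plates, each run
    as technical replicates 'A' and 'B' sharing one transfection mix.

    ``layout`` is a :class:`woundscreen.layout.PlateLayout`.  Returns
    ``(well_table, truth_table)`` as DataFrames.  The well table carries one
    row per (plate, replicate, well) with a migrated-area surrogate ``Am_px``
    and an endpoint ``cell_count``; the truth table carries one row per
    library siRNA with its effect class and multiplicative effect.
    """
    import pandas as pd

    if not layout.mock_wells():
        raise ValueError("layout defines no mock wells: normalization impossible")

    control_effect = {"mock": 1.0, "siCDC42": 0.35, "siCDH5": 0.5,
                      "non_targeting_ref": 1.15}
    p_neutral = 1.0 - effects.p_inhibitor - effects.p_accelerator - effects.p_lethal
    probs = (p_neutral, effects.p_inhibitor, effects.p_accelerator, effects.p_lethal)
    class_effect = {"neutral": 1.0, "inhibitor": effects.inhibitor_effect,
                    "accelerator": effects.accelerator_effect,
                    # lethal wells also migrate poorly; the viability gate must win
                    "lethal": effects.inhibitor_effect}

    rows, truth_rows = [], []
    for p in range(n_plates):
        rng = _plate_rng(effects.seed, p)
        plate_id = f"P{p + 1:03d}"
        for well in layout.wells():
            role = layout.role(well)
            if role == "library":
                true_class = str(rng.choice(_CLASS_ORDER, p=probs))
                sirna_id = f"s-{plate_id}-{well}"
                gene_id = f"g-{plate_id}-{well}"
                effect = class_effect[true_class]
                truth_rows.append({"sirna_id": sirna_id, "gene_id": gene_id,
                                   "true_class": true_class, "true_effect": effect})
            else:
                true_class, sirna_id, gene_id = role, role, role
                effect = control_effect[role]
            count_factor = effects.lethal_count_factor if true_class == "lethal" else 1.0
            well_eps = rng.normal(0.0, effects.well_noise_sd)
            count_eps = rng.normal(0.0, COUNT_NOISE_SD)
            for rep in ("A", "B"):
                score = effect + well_eps + rng.normal(0.0, effects.replicate_noise_sd)
                count = BASE_CELL_COUNT * count_factor * (
                    1.0 + count_eps + rng.normal(0.0, effects.replicate_noise_sd / 2))
                rows.append({"plate_id": plate_id, "replicate": rep, "well": well,
                             "role": role, "sirna_id": sirna_id, "gene_id": gene_id,
                             "Am_px": max(score, 0.0) * BASE_AM_PX,
                             "cell_count": max(0, int(round(count))),
                             "qc_flag": "ok"})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _control_block_rows(plate_id, layout, rng, effects, rows, extra=None):
    """Append control-well rows for one simulated plate (both replicates)."""
    control_effect = {"mock": 1.0, "siCDC42": 0.35, "siCDH5": 0.5,
                      "non_targeting_ref": 1.15}
    for well in layout.wells():
        role = layout.role(well)
        if role == "library":
            continue
        well_eps = rng.normal(0.0, effects.well_noise_sd)
        count_eps = rng.normal(0.0, COUNT_NOISE_SD)
        for rep in ("A", "B"):
            score = control_effect[role] + well_eps + rng.normal(0.0, effects.replicate_noise_sd)
            count = BASE_CELL_COUNT * (1.0 + count_eps
                                       + rng.normal(0.0, effects.replicate_noise_sd / 2))
            rows.append({"plate_id": plate_id, "replicate": rep, "well": well,
                         "role": role, "sirna_id": role, "gene_id": role,
                         "Am_px": max(score, 0.0) * BASE_AM_PX,
                         "cell_count": max(0, int(round(count))),
                         "qc_flag": "ok", **(extra or {})})


def generate_deconvolution_dataset(n_genes: int, layout, effects: EffectModel,
                                   reproducing_probs=(0.35, 0.30, 0.22, 0.07, 0.015),
                                   p_toxic: float = 0.045,
                                   impaired_effect: float = 0.45):
    """Simulate a secondary (deconvolution) screen of ``n_genes`` Impaired
    candidates: four single duplexes per gene on library wells, technical
    replicates 'A'/'B'.

    ``reproducing_probs`` are the probabilities that 0..4 of a gene's four
    duplexes reproduce the Impaired phenotype; with probability ``p_toxic``
    the gene is instead non-specifically toxic (one lethal duplex, three
    quiet).  Returns ``(well_table, truth_table)`` where the truth carries
    each gene's expected confidence class.
    """
    import pandas as pd

    from .screen_stats import CONFIDENCE_BY_COUNT, TOXIC

    lib_wells = layout.library_wells()
    genes_per_plate = len(lib_wells) // 4
    rng = np.random.default_rng([effects.seed, 990_001])
    rows, truth_rows = [], []
    remaining = list(range(n_genes))
    plate_no = 0
    rp = np.asarray(reproducing_probs, dtype=float)
    rp = rp / rp.sum() * (1.0 - p_toxic)
    outcome_probs = np.append(rp, p_toxic)  # 0..4 reproducing, then toxic
    while remaining:
        plate_no += 1
        plate_id = f"D{plate_no:03d}"
        batch, remaining = remaining[:genes_per_plate], remaining[genes_per_plate:]
        _control_block_rows(plate_id, layout, rng, effects, rows)
        for slot, g in enumerate(batch):
            gene_id = f"gene{g:04d}"
            outcome = int(rng.choice(6, p=outcome_probs))
            if outcome == 5:
                duplex_effects = [1.0] * 4
                lethal_idx = {int(rng.integers(4))}
                expected = TOXIC
            else:
                reproducing = rng.choice(4, size=outcome, replace=False)
                duplex_effects = [impaired_effect if d in reproducing else 1.0
                                  for d in range(4)]
                lethal_idx = set()
                expected = CONFIDENCE_BY_COUNT[outcome]
            truth_rows.append({"gene_id": gene_id, "original_phenotype": "Inhibited",
                               "expected_confidence": expected,
                               "n_reproducing_true": 0 if outcome == 5 else outcome})
            for d in range(4):
                well = lib_wells[slot * 4 + d]
                sirna_id = f"{gene_id}-d{d + 1}"
                lethal = d in lethal_idx
                effect = duplex_effects[d]
                count_factor = effects.lethal_count_factor if lethal else 1.0
                well_eps = rng.normal(0.0, effects.well_noise_sd)
                count_eps = rng.normal(0.0, COUNT_NOISE_SD)
                for rep in ("A", "B"):
                    score = effect + well_eps + rng.normal(0.0, effects.replicate_noise_sd)
                    count = BASE_CELL_COUNT * count_factor * (
                        1.0 + count_eps + rng.normal(0.0, effects.replicate_noise_sd / 2))
                    rows.append({"plate_id": plate_id, "replicate": rep, "well": well,
                                 "role": "library", "sirna_id": sirna_id,
                                 "gene_id": gene_id, "Am_px": max(score, 0.0) * BASE_AM_PX,
                                 "cell_count": max(0, int(round(count))),
                                 "qc_flag": "ok"})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_tertiary_dataset(class_counts: dict[str, int], layout,
                              effects: EffectModel,
                              impaired_effect: float = 0.45,
                              spared_effect: float = 0.95,
                              n_bio_replicates: int = 2):
    """Simulate the tertiary two-cell-type re-screen.

    ``class_counts`` maps each tertiary truth class ('common', 'BEC_dominant',
    'LEC_dominant', 'not_impaired') to a gene count.  Each gene is screened as
    a SMARTpool in both cell types, in ``n_bio_replicates`` biological
    replicates each with technical replicates 'A'/'B'.  Returns
    ``(well_tables, truth_table)`` with ``well_tables`` a dict keyed by cell
    type ('LEC', 'BEC').
    """
    import pandas as pd

    true_effects = {
        "common": {"LEC": impaired_effect, "BEC": impaired_effect},
        "BEC_dominant": {"LEC": spared_effect, "BEC": impaired_effect},
        "LEC_dominant": {"LEC": impaired_effect, "BEC": spared_effect},
        "not_impaired": {"LEC": 1.0, "BEC": 1.0},
    }
    unknown = set(class_counts) - set(true_effects)
    if unknown:
        raise ValueError(f"unknown tertiary classes: {sorted(unknown)}")
    genes = [(f"tgene{i:04d}", cls)
             for i, cls in enumerate(cls for cls, n in sorted(class_counts.items())
                                     for _ in range(n))]
    truth = pd.DataFrame([{"gene_id": g, "true_class": cls} for g, cls in genes])
    lib_wells = layout.library_wells()
    tables = {}
    for ct_idx, cell_type in enumerate(("LEC", "BEC")):
        rows = []
        for bio in range(1, n_bio_replicates + 1):
            rng = np.random.default_rng([effects.seed, 880_000 + 10 * ct_idx + bio])
            for start in range(0, len(genes), len(lib_wells)):
                plate_id = f"T{cell_type}{bio}{start // len(lib_wells) + 1:02d}"
                _control_block_rows(plate_id, layout, rng, effects, rows,
                                    extra={"bio_replicate": bio})
                for slot, (gene_id, cls) in enumerate(genes[start:start + len(lib_wells)]):
                    effect = true_effects[cls][cell_type]
                    well_eps = rng.normal(0.0, effects.well_noise_sd)
                    count_eps = rng.normal(0.0, COUNT_NOISE_SD)
                    for rep in ("A", "B"):
                        score = effect + well_eps + rng.normal(0.0, effects.replicate_noise_sd)
                        count = BASE_CELL_COUNT * (1.0 + count_eps
                                                   + rng.normal(0.0, effects.replicate_noise_sd / 2))
                        rows.append({"plate_id": plate_id, "replicate": rep,
                                     "bio_replicate": bio, "well": lib_wells[slot],
                                     "role": "library", "sirna_id": gene_id,
                                     "gene_id": gene_id,
                                     "Am_px": max(score, 0.0) * BASE_AM_PX,
                                     "cell_count": max(0, int(round(count))),
                                     "qc_flag": "ok"})
        tables[cell_type] = pd.DataFrame(rows)
    return tables, truth
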