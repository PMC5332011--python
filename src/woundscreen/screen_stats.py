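"""Plate- and screen-level statistics for the three-tier migration screen.

Primary tier: per-plate mock-median normalisation, technical-replicate
averaging, screen-wide robust z (median/MAD x 1.4826), and binning at strict
|z| > 2 with the Low Cell Count viability bin taking precedence.  Plate QC
uses SSMD against both positive controls (pass when the better one is >= 1)
and the Pearson correlation of replicate library wells.

Secondary (deconvolution) tier: the four duplexes of each SMARTpool are
binned on the normalised migration scale (Impaired < 0.6, Accelerated > 1.3,
strict) and a confidence class is assigned from how many duplexes reproduce
the gene's original phenotype; a pool whose only signal is a single Low Cell
Count duplex is classed as non-specific toxicity.

Tertiary tier: genes are called per cell type with the secondary Impaired
threshold and partitioned into common / BEC-dominant / LEC-dominant /
not-impaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .nuclei import LOW_CELL_COUNT

MAD_CONSISTENCY = 1.4826

# bin labels
INHIBITED = "Inhibited"
ACCELERATED = "Accelerated"
IMPAIRED = "Impaired"
NONE = "none"

CONFIDENCE_BY_COUNT = {0: "none", 1: "low", 2: "medium", 3: "high", 4: "very_high"}
TOXIC = "toxic"

TERTIARY_CLASSES = ("common", "BEC_dominant", "LEC_dominant", "not_impaired")


class NormalizationError(ValueError):
    """A plate lacks the mock wells needed for normalisation."""


class DegenerateSpreadError(ValueError):
    """Zero spread: robust z or SSMD undefined."""


# ---------------------------------------------------------------------------
# normalisation and robust z


def normalize_migration(plate_wells: pd.DataFrame, am_col: str = "Am_px",
                        role_col: str = "role", qc_col: str = "qc_flag") -> pd.DataFrame:
    """Normalise one plate's migrated areas to its mock-well median.

    Adds a ``norm_migration`` column (mock median maps to exactly 1.0).
    Wells flagged other than 'ok' are excluded from the mock median; at least
    two usable mock wells are required.
    """
    ok = plate_wells[qc_col].eq("ok") if qc_col in plate_wells else True
    mocks = plate_wells.loc[plate_wells[role_col].eq("mock") & ok, am_col]
    if len(mocks) < 2:
        raise NormalizationError(
            f"plate has {len(mocks)} usable mock wells; >= 2 required")
    mock_median = float(mocks.median())
    if mock_median == 0:
        raise NormalizationError("mock median migrated area is zero")
    out = plate_wells.copy()
    out["norm_migration"] = out[am_col] / mock_median
    return out


def normalize_screen(wells: pd.DataFrame, plate_cols=("plate_id", "replicate"),
                     **kw) -> pd.DataFrame:
    """Apply :func:`normalize_migration` per physical plate (plate x replicate)."""
    parts = [normalize_migration(g, **kw) for _, g in wells.groupby(list(plate_cols))]
    return pd.concat(parts).sort_index()


def robust_z(values, scale: float = MAD_CONSISTENCY) -> np.ndarray:
    """Robust z-scores: (x - median) / (scale * MAD).

    ``scale`` = 1.4826 makes MAD consistent with the normal s.d.; pass 1 for
    the unscaled form.  Requires >= 3 values and nonzero MAD.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("robust z needs at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateSpreadError("MAD is zero: robust z undefined")
    return (x - med) / (scale * mad)


# ---------------------------------------------------------------------------
# binning


def bin_primary(z: float, cell_count_bin: str = "normal",
                threshold: float = 2.0) -> str:
    """Primary-screen bin for one siRNA: LowCellCount wins outright; else
    Inhibited when z < -2, Accelerated when z > 2 (strict), else none."""
    if cell_count_bin == LOW_CELL_COUNT:
        return LOW_CELL_COUNT
    if z < -threshold:
        return INHIBITED
    if z > threshold:
        return ACCELERATED
    return NONE


def bin_secondary(norm_migration: float, cell_count_bin: str = "normal",
                  impaired_below: float = 0.6, accelerated_above: float = 1.3) -> str:
    """Deconvolution-screen bin on the normalised migration scale (strict
    thresholds); the viability gate again takes precedence."""
    if cell_count_bin == LOW_CELL_COUNT:
        return LOW_CELL_COUNT
    if norm_migration < impaired_below:
        return IMPAIRED
    if norm_migration > accelerated_above:
        return ACCELERATED
    return NONE


# ---------------------------------------------------------------------------
# QC: SSMD and replicate correlation


def plate_ssmd(pos_values, neg_values, robust: bool = False) -> float:
    """Strictly standardised mean difference between a plate's negative
    (mock) and positive (migration-reducing) control wells.

    ssmd = (mean(neg) - mean(pos)) / sqrt(var(neg) + var(pos)) with n-1
    variances, so an effective inhibitory positive control scores positive.
    ``robust=True`` substitutes median and scaled-MAD^2.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("SSMD needs >= 2 wells per control group")
    if robust:
        loc_n, loc_p = np.median(neg), np.median(pos)
        var_n = (MAD_CONSISTENCY * np.median(np.abs(neg - loc_n))) ** 2
        var_p = (MAD_CONSISTENCY * np.median(np.abs(pos - loc_p))) ** 2
    else:
        loc_n, loc_p = neg.mean(), pos.mean()
        var_n, var_p = neg.var(ddof=1), pos.var(ddof=1)
    denom = var_n + var_p
    if denom == 0:
        raise DegenerateSpreadError("both control groups have zero variance")
    return float((loc_n - loc_p) / np.sqrt(denom))


@dataclass
class QCReport:
    """Per-plate QC: SSMD of each positive control and replicate correlation."""

    plate_id: str
    ssmd_cdc42: float
    ssmd_cdh5: float
    replicate_pearson_r: float = np.nan
    ssmd_best: float = field(init=False)
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.ssmd_best = max(self.ssmd_cdc42, self.ssmd_cdh5)
        self.passed = bool(self.ssmd_best >= 1.0)


def replicate_correlation(plate_a_values, plate_b_values) -> float:
    """Pearson r over paired, unexcluded library wells of a replicate pair."""
    a = np.asarray(plate_a_values, dtype=float)
    b = np.asarray(plate_b_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate value vectors must be paired")
    if a.size < 3:
        raise ValueError("replicate correlation needs >= 3 paired wells")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateSpreadError("zero variance in a replicate: r undefined")
    return float(sstats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# deconvolution confidence


@dataclass
class DuplexPanel:
    """The four single-duplex outcomes for one gene in the deconvolution
    screen, with its original (primary-screen) phenotype."""

    gene_id: str
    duplex_bins: tuple[str, str, str, str]
    original_phenotype: str  # 'Inhibited' or 'Accelerated'

    def __post_init__(self) -> None:
        if len(self.duplex_bins) != 4:
            raise ValueError("a deconvolution panel needs exactly 4 duplex bins")

    @property
    def reproducing_bin(self) -> str:
        # an 'Inhibited' pool reproduces via the secondary 'Impaired' bin
        return IMPAIRED if self.original_phenotype == INHIBITED else ACCELERATED

    @property
    def n_reproducing(self) -> int:
        return sum(b == self.reproducing_bin for b in self.duplex_bins)


def assign_deconv_confidence(panel: DuplexPanel) -> str:
    """Confidence class of one deconvolved SMARTpool.

    'toxic' requires exactly one LowCellCount duplex with no phenotype in the
    other three; otherwise the class follows the reproducing-duplex count:
    0 -> none, 1 -> low, 2 -> medium, 3 -> high, 4 -> very_high.
    """
    bins = panel.duplex_bins
    n_low = sum(b == LOW_CELL_COUNT for b in bins)
    n_quiet = sum(b == NONE for b in bins)
    if n_low == 1 and n_quiet == 3:
        return TOXIC
    return CONFIDENCE_BY_COUNT[panel.n_reproducing]


_TABLE_BINS = ("Toxic", "0/4", "1/4", "2/4", "3/4", "4/4")
_CONF_TO_TABLE = {TOXIC: "Toxic", "none": "0/4", "low": "1/4", "medium": "2/4",
                  "high": "3/4", "very_high": "4/4"}


def summarize_confidence_table(panels: list[DuplexPanel]) -> pd.DataFrame:
    """Cross-tabulate deconvolved genes by original phenotype and confidence
    bin; see :func:`confidence_table_from_counts` for the output shape."""
    counts = pd.DataFrame(0, index=[IMPAIRED, ACCELERATED], columns=_TABLE_BINS)
    for panel in panels:
        row = IMPAIRED if panel.original_phenotype == INHIBITED else ACCELERATED
        counts.loc[row, _CONF_TO_TABLE[assign_deconv_confidence(panel)]] += 1
    return confidence_table_from_counts(counts)


def confidence_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Append the Total column and the Percentage row (column totals as % of
    the grand total, 1 decimal) to a phenotype x bin count table."""
    table = counts.astype(float).copy()
    table["Total"] = table.sum(axis=1)
    grand = table["Total"].sum()
    if grand == 0:
        raise ValueError("empty confidence table")
    pct = (table.drop(columns="Total").sum(axis=0) / grand * 100).round(1)
    table.loc["Percentage"] = list(pct) + [100.0]
    return table


def high_confidence_count(table: pd.DataFrame, phenotype: str = IMPAIRED) -> int:
    """Genes of a phenotype validated with 3/4 or 4/4 duplexes."""
    return int(table.loc[phenotype, ["3/4", "4/4"]].sum())


def medium_high_count(table: pd.DataFrame, phenotype: str = IMPAIRED) -> int:
    """Genes of a phenotype validated with at least 2/4 duplexes — the set
    carried into the tertiary screen."""
    return int(table.loc[phenotype, ["2/4", "3/4", "4/4"]].sum())


def medium_high_validation_pct(table: pd.DataFrame) -> float:
    """Percentage of all deconvolved genes validating with >= 2/4 duplexes."""
    grand = table.loc[table.index != "Percentage", "Total"].sum()
    n = table.loc[table.index != "Percentage", ["2/4", "3/4", "4/4"]].to_numpy().sum()
    return round(float(n / grand * 100), 1)


def percent(n: float, total: float, ndigits: int = 1) -> float:
    """n as a percentage of total, rounded as printed in screen reports."""
    if total == 0:
        raise ValueError("total must be nonzero")
    return round(n / total * 100, ndigits)


# ---------------------------------------------------------------------------
# tertiary cross-cell-type classification


@dataclass
class TertiaryCall:
    gene_id: str
    impaired_LEC: bool
    impaired_BEC: bool
    cls: str = field(init=False)

    def __post_init__(self) -> None:
        if self.impaired_LEC and self.impaired_BEC:
            self.cls = "common"
        elif self.impaired_BEC:
            self.cls = "BEC_dominant"
        elif self.impaired_LEC:
            self.cls = "LEC_dominant"
        else:
            self.cls = "not_impaired"


def classify_tertiary(gene_id: str, norm_LEC: float, norm_BEC: float,
                      impaired_below: float = 0.6) -> TertiaryCall:
    """Classify one gene from its replicate-averaged normalised migration in
    each cell type, using the secondary Impaired threshold (strict)."""
    for name, v in (("LEC", norm_LEC), ("BEC", norm_BEC)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"gene {gene_id}: missing {name} migration score")
    return TertiaryCall(gene_id, impaired_LEC=norm_LEC < impaired_below,
                        impaired_BEC=norm_BEC < impaired_below)


def tertiary_partition(calls: list[TertiaryCall]) -> pd.Series:
    """Counts per tertiary class, plus the percentage of impaired genes that
    are common to both cell types."""
    counts = pd.Series({cls: sum(c.cls == cls for c in calls)
                        for cls in TERTIARY_CLASSES}, dtype=int)
    impaired = int(counts[["common", "BEC_dominant", "LEC_dominant"]].sum())
    out = counts.astype(float)
    out["n_impaired_any"] = impaired
    out["common_pct"] = percent(counts["common"], impaired) if impaired else np.nan
    return out
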