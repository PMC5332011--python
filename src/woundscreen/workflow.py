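"""Tier-level orchestration: chain normalisation, QC, viability gating,
binning and the tier-specific classification over a well table, and write the
interchange CSVs.

Each screen tier consumes a per-well table (one row per plate x replicate x
well, with ``Am_px`` and ``cell_count``) — produced either by the image
pipeline or by the plate simulator — and emits scores, bins and a QC report.
Physical plates (a plate x replicate pair) failing the SSMD >= 1 gate are
dropped with a logged reason; the surviving replicate(s) carry the plate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import screen_stats as st
from .layout import PlateLayout, default_layout, parse_layout
from .nuclei import ViabilityParams, bin_cell_count
from .synthetic import (EffectModel, generate_deconvolution_dataset,
                        generate_screen_dataset, generate_tertiary_dataset)

log = logging.getLogger("woundscreen")


@dataclass
class RunConfig:
    """Configuration of one tier run (thresholds per tier, seed, paths)."""

    tier: str = "primary"
    seed: int = 0
    n_plates: int = 4
    n_genes: int = 100
    tertiary_class_counts: dict = dc_field(default_factory=lambda: {
        "common": 34, "BEC_dominant": 12, "LEC_dominant": 10, "not_impaired": 21})
    effects: EffectModel = dc_field(default_factory=EffectModel)
    viability: ViabilityParams = dc_field(default_factory=ViabilityParams)
    layout: PlateLayout = dc_field(default_factory=default_layout)
    z_threshold: float = 2.0
    impaired_below: float = 0.6
    accelerated_above: float = 1.3
    input_csv: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.tier not in ("primary", "secondary", "tertiary"):
            raise ValueError(f"unknown tier {self.tier!r}")


def load_config(text: str) -> RunConfig:
    """Build a RunConfig from YAML text (flat keys matching the dataclass;
    ``effects`` and ``layout`` as nested blocks)."""
    doc = yaml.safe_load(text) or {}
    kw = {}
    if "effects" in doc:
        kw["effects"] = EffectModel(**doc.pop("effects"))
    if "layout" in doc:
        kw["layout"] = parse_layout(yaml.safe_dump(doc.pop("layout")))
    kw.update(doc)
    return RunConfig(**kw)


# ---------------------------------------------------------------------------
# shared plate-level steps


def plate_qc(wells: pd.DataFrame) -> pd.DataFrame:
    """SSMD QC per physical plate plus replicate correlation per plate pair.

    Expects normalised wells.  Returns one row per (plate_id, replicate) with
    ssmd_cdc42 / ssmd_cdh5 / ssmd_best / passed / replicate_pearson_r.
    """
    rows = []
    for (pid, rep), g in wells.groupby(["plate_id", "replicate"], sort=True):
        mocks = g.loc[g["role"] == "mock", "norm_migration"]
        report = st.QCReport(
            plate_id=f"{pid}-{rep}",
            ssmd_cdc42=st.plate_ssmd(g.loc[g["role"] == "siCDC42", "norm_migration"], mocks),
            ssmd_cdh5=st.plate_ssmd(g.loc[g["role"] == "siCDH5", "norm_migration"], mocks))
        rows.append({"plate_id": pid, "replicate": rep,
                     "ssmd_cdc42": report.ssmd_cdc42, "ssmd_cdh5": report.ssmd_cdh5,
                     "ssmd_best": report.ssmd_best, "passed": report.passed})
    qc = pd.DataFrame(rows)
    r_by_plate = {}
    for pid, g in wells[wells["role"] == "library"].groupby("plate_id"):
        piv = g.pivot_table(index="well", columns="replicate",
                            values="norm_migration", aggfunc="first")
        if {"A", "B"} <= set(piv.columns):
            paired = piv.dropna(subset=["A", "B"])
            if len(paired) >= 3:
                r_by_plate[pid] = st.replicate_correlation(paired["A"], paired["B"])
    qc["replicate_pearson_r"] = qc["plate_id"].map(r_by_plate)
    for row in qc.itertuples():
        log.info("plate %s rep %s: SSMD best %.2f -> %s", row.plate_id, row.replicate,
                 row.ssmd_best, "pass" if row.passed else "FAIL")
    return qc


def _drop_failed_plates(wells: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    failed = qc.loc[~qc["passed"], ["plate_id", "replicate"]]
    for row in failed.itertuples():
        log.warning("dropping failed plate %s replicate %s (SSMD < 1)",
                    row.plate_id, row.replicate)
    keep = wells.merge(qc[["plate_id", "replicate", "passed"]],
                       on=["plate_id", "replicate"], how="left")
    return keep[keep["passed"].fillna(True)].drop(columns="passed")


def _viability_bins(wells: pd.DataFrame, viability: ViabilityParams,
                    by: str = "sirna_id") -> pd.Series:
    """Replicate-averaged endpoint cell count per siRNA -> viability bin."""
    counts = wells.groupby(by)["cell_count"].mean()
    return counts.map(lambda c: bin_cell_count(c, viability))


# ---------------------------------------------------------------------------
# tiers


def run_primary(well_table: pd.DataFrame, truth: pd.DataFrame | None = None,
                viability: ViabilityParams = ViabilityParams(),
                z_threshold: float = 2.0) -> dict:
    """Primary-tier chain: normalise, QC, drop failed plates, viability gate,
    replicate-average, screen-wide robust z, bin.

    Returns a dict with ``wells`` (normalised), ``qc``, ``scores`` (one row
    per library siRNA) and, when a truth table is supplied, ``recovery``.
    """
    wells = st.normalize_screen(well_table)
    qc = plate_qc(wells)
    wells = _drop_failed_plates(wells, qc)
    lib = wells[wells["role"] == "library"]
    vbins = _viability_bins(lib, viability)
    scores = (lib.groupby(["sirna_id", "gene_id"])["norm_migration"].mean()
              .reset_index().set_index("sirna_id"))
    scores["cell_count_bin"] = vbins
    scores["robust_z"] = st.robust_z(scores["norm_migration"])
    scores["primary_bin"] = [
        st.bin_primary(z, b, threshold=z_threshold)
        for z, b in zip(scores["robust_z"], scores["cell_count_bin"])]
    out = {"wells": wells, "qc": qc, "scores": scores}
    if truth is not None:
        out["recovery"] = recovery_report(scores, truth)
    return out


def recovery_report(scores: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate assigned primary bins against simulator truth classes."""
    joined = scores.join(truth.set_index("sirna_id")["true_class"], how="inner")
    return pd.crosstab(joined["true_class"], joined["primary_bin"])


def run_secondary(well_table: pd.DataFrame,
                  original_phenotypes: pd.Series | None = None,
                  viability: ViabilityParams = ViabilityParams(),
                  impaired_below: float = 0.6,
                  accelerated_above: float = 1.3) -> dict:
    """Deconvolution-tier chain: normalise, QC, bin each duplex, assemble
    4-duplex panels per gene, assign confidence, summarise as the
    phenotype x bin table.

    ``original_phenotypes`` maps gene_id -> 'Inhibited'/'Accelerated' (default
    'Inhibited' for every gene).
    """
    wells = st.normalize_screen(well_table)
    qc = plate_qc(wells)
    wells = _drop_failed_plates(wells, qc)
    lib = wells[wells["role"] == "library"]
    vbins = _viability_bins(lib, viability)
    duplex = (lib.groupby(["gene_id", "sirna_id"])["norm_migration"].mean()
              .reset_index().set_index("sirna_id"))
    duplex["cell_count_bin"] = vbins
    duplex["bin"] = [st.bin_secondary(m, b, impaired_below, accelerated_above)
                     for m, b in zip(duplex["norm_migration"], duplex["cell_count_bin"])]
    panels = []
    for gene_id, g in duplex.groupby("gene_id"):
        if len(g) != 4:
            raise ValueError(f"gene {gene_id} has {len(g)} duplexes; expected 4")
        phenotype = (original_phenotypes.get(gene_id, st.INHIBITED)
                     if original_phenotypes is not None else st.INHIBITED)
        panels.append(st.DuplexPanel(gene_id, tuple(g.sort_index()["bin"]), phenotype))
    confidences = pd.Series({p.gene_id: st.assign_deconv_confidence(p) for p in panels},
                            name="confidence")
    return {"wells": wells, "qc": qc, "duplex_bins": duplex, "panels": panels,
            "confidence": confidences,
            "table": st.summarize_confidence_table(panels)}


def run_tertiary(well_tables: dict[str, pd.DataFrame],
                 impaired_below: float = 0.6) -> dict:
    """Tertiary-tier chain for the two cell types: normalise, average
    technical then biological replicates, classify every gene and partition.

    ``well_tables`` maps 'LEC'/'BEC' to well tables carrying a
    ``bio_replicate`` column.
    """
    missing = {"LEC", "BEC"} - set(well_tables)
    if missing:
        raise ValueError(f"missing cell type tables: {sorted(missing)}")
    gene_scores = {}
    for cell_type, table in well_tables.items():
        wells = st.normalize_screen(table, plate_cols=("plate_id", "replicate"))
        lib = wells[wells["role"] == "library"]
        # technical replicates first, then biological replicates
        tech = lib.groupby(["gene_id", "bio_replicate"])["norm_migration"].mean()
        gene_scores[cell_type] = tech.groupby("gene_id").mean()
    merged = pd.DataFrame({"norm_LEC": gene_scores["LEC"], "norm_BEC": gene_scores["BEC"]})
    if merged.isna().any().any():
        bad = merged.index[merged.isna().any(axis=1)].tolist()
        raise ValueError(f"genes missing in one cell type: {bad}")
    calls = [st.classify_tertiary(g, row.norm_LEC, row.norm_BEC, impaired_below)
             for g, row in merged.iterrows()]
    merged["class"] = [c.cls for c in calls]
    return {"scores": merged, "calls": calls,
            "partition": st.tertiary_partition(calls)}


# ---------------------------------------------------------------------------
# top-level driver and I/O


def write_image(directory, plate: str, well: str, channel: str, timepoint: str,
                image: np.ndarray) -> Path:
    """Write one 16-bit grayscale TIFF under the screen naming convention."""
    path = Path(directory) / f"{plate}_{well}_{channel}_{timepoint}.tif"
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    return path


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def _write_outputs(outdir, frames: dict[str, pd.DataFrame]) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in frames.items():
        df.to_csv(out / f"{name}.csv")


def run_tier(config: RunConfig) -> dict:
    """Execute one full tier: load or simulate the well table, run the tier
    chain, and (when ``config.outdir`` is set) write the CSV outputs."""
    config = replace(config, effects=replace(config.effects, seed=config.seed))
    if config.tier == "primary":
        if config.input_csv:
            table = pd.read_csv(config.input_csv)
            truth = None
        else:
            table, truth = generate_screen_dataset(config.n_plates, config.layout,
                                                   config.effects)
        result = run_primary(table, truth, config.viability, config.z_threshold)
        frames = {"well_scores": result["wells"], "qc_report": result["qc"],
                  "primary_scores": result["scores"]}
        if "recovery" in result:
            frames["truth_recovery"] = result["recovery"]
    elif config.tier == "secondary":
        if config.input_csv:
            table = pd.read_csv(config.input_csv)
        else:
            table, _truth = generate_deconvolution_dataset(config.n_genes, config.layout,
                                                           config.effects)
        result = run_secondary(table, viability=config.viability,
                               impaired_below=config.impaired_below,
                               accelerated_above=config.accelerated_above)
        frames = {"qc_report": result["qc"], "duplex_bins": result["duplex_bins"],
                  "gene_confidence": result["confidence"].to_frame(),
                  "confidence_table": result["table"]}
    else:
        tables, _truth = generate_tertiary_dataset(config.tertiary_class_counts,
                                                   config.layout, config.effects)
        result = run_tertiary(tables, impaired_below=config.impaired_below)
        frames = {"tertiary_scores": result["scores"],
                  "tertiary_partition": result["partition"].to_frame("value")}
    if config.outdir:
        _write_outputs(config.outdir, frames)
    return result


def export_pubchem_style(scores: pd.DataFrame, hit_bins=(st.INHIBITED, st.ACCELERATED)
                         ) -> pd.DataFrame:
    """Summary table mirroring the deposited record semantics: siRNA id, gene
    id, normalised score, and a 0/1 activity outcome."""
    out = scores.reset_index()[["sirna_id", "gene_id", "norm_migration",
                                "robust_z", "primary_bin"]].copy()
    out["activity_outcome"] = out["primary_bin"].isin(hit_bins).astype(int)
    return out
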