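import numpy as np
import pandas as pd
import pytest

from woundscreen.layout import LayoutError, default_layout, layout_to_yaml, parse_layout
from woundscreen.synthetic import (EffectModel, generate_deconvolution_dataset,
                                   generate_screen_dataset, generate_tertiary_dataset)
from woundscreen.workflow import (RunConfig, export_pubchem_style, load_config,
                                  read_image, run_primary, run_secondary,
                                  run_tertiary, run_tier, write_image)


class TestLayout:
    def test_default_layout_structure(self, layout):
        assert len(layout.wells()) == 96
        assert len(layout.library_wells()) == 80
        assert len(layout.mock_wells()) == 6
        cols = {int(w[1:]) for w in layout.mock_wells()}
        assert cols <= {1, 12}

    def test_roundtrip_through_yaml(self, layout):
        text = layout_to_yaml(layout)
        parsed = parse_layout(text)
        assert parsed.roles == layout.roles

    def test_missing_mock_rejected(self, layout):
        text = layout_to_yaml(layout).replace("mock", "cdc42")
        with pytest.raises(LayoutError, match="mock"):
            parse_layout(text)

    def test_library_in_control_column_rejected(self, layout):
        text = layout_to_yaml(layout)
        bad = text.replace("[mock, lib", "[lib, lib", 1)
        with pytest.raises(LayoutError, match="control column"):
            parse_layout(bad)

    def test_malformed_grid_rejected(self):
        with pytest.raises(LayoutError, match="8 rows"):
            parse_layout("plate_layout: v1\ngrid:\n  - [mock, lib]\n")
        with pytest.raises(LayoutError, match="unknown well code"):
            parse_layout("grid:\n" + "\n".join(
                "  - [%s]" % ", ".join(["sponge"] * 12) for _ in range(8)))


@pytest.fixture(scope="module")
def primary_result(layout):
    eff = EffectModel(seed=21)
    table, truth = generate_screen_dataset(4, layout, eff)
    return run_primary(table, truth), truth


class TestPrimaryTier:
    def test_every_library_sirna_gets_exactly_one_bin(self, primary_result):
        (res, truth) = primary_result
        bins = res["scores"]["primary_bin"]
        assert len(bins) == len(truth)
        assert set(bins) <= {"Inhibited", "Accelerated", "LowCellCount", "none"}

    def test_qc_report_covers_every_physical_plate(self, primary_result):
        (res, _) = primary_result
        assert len(res["qc"]) == 8  # 4 plates x 2 replicates
        assert res["qc"]["replicate_pearson_r"].between(-1, 1).all()

    def test_recovery_report_shape(self, primary_result):
        (res, truth) = primary_result
        rec = res["recovery"]
        assert rec.to_numpy().sum() == len(truth)

    def test_failed_plate_dropped(self, layout):
        eff = EffectModel(seed=22, replicate_noise_sd=0.0)
        table, truth = generate_screen_dataset(2, layout, eff)
        # sabotage plate P001 replicate A: positive controls behave like mocks
        sel = (table["plate_id"] == "P001") & (table["replicate"] == "A") \
            & table["role"].isin(["siCDC42", "siCDH5"])
        mock_am = table.loc[(table["plate_id"] == "P001") & (table["role"] == "mock"),
                            "Am_px"].median()
        table.loc[sel, "Am_px"] = mock_am * np.array([0.99, 1.01] * (sel.sum() // 2))
        res = run_primary(table, truth)
        qc = res["qc"].set_index(["plate_id", "replicate"])
        assert not qc.loc[("P001", "A"), "passed"]
        assert ("P001", "A") not in set(
            res["wells"].set_index(["plate_id", "replicate"]).index)

    def test_pubchem_style_export(self, primary_result):
        (res, _) = primary_result
        out = export_pubchem_style(res["scores"])
        assert set(out["activity_outcome"]) <= {0, 1}
        hits = out["primary_bin"].isin(["Inhibited", "Accelerated"])
        assert (out["activity_outcome"] == hits.astype(int)).all()


class TestSecondaryTier:
    def test_confidence_recovery_and_table_shape(self, layout):
        table, truth = generate_deconvolution_dataset(
            60, layout, EffectModel(seed=23, well_noise_sd=0.03, replicate_noise_sd=0.02))
        res = run_secondary(table)
        expected = truth.set_index("gene_id")["expected_confidence"].sort_index()
        got = res["confidence"].sort_index()
        assert (got.values == expected.values).mean() > 0.9
        t = res["table"]
        assert list(t.columns) == ["Toxic", "0/4", "1/4", "2/4", "3/4", "4/4", "Total"]
        assert t.loc["Impaired", "Total"] + t.loc["Accelerated", "Total"] == 60

    def test_incomplete_panel_rejected(self, layout):
        table, _ = generate_deconvolution_dataset(8, layout, EffectModel(seed=24))
        broken = table[table["sirna_id"] != "gene0003-d2"]
        with pytest.raises(ValueError, match="gene0003"):
            run_secondary(broken)


class TestTertiaryTier:
    def test_partition_matches_truth(self, layout):
        counts = {"common": 10, "BEC_dominant": 4, "LEC_dominant": 3, "not_impaired": 5}
        tables, truth = generate_tertiary_dataset(
            counts, layout, EffectModel(seed=25, well_noise_sd=0.03,
                                        replicate_noise_sd=0.02))
        res = run_tertiary(tables)
        part = res["partition"]
        for cls, n in counts.items():
            assert part[cls] == n
        assert part["n_impaired_any"] == 17

    def test_partition_counts_sum_to_impaired(self, layout):
        tables, _ = generate_tertiary_dataset(
            {"common": 6, "BEC_dominant": 2, "LEC_dominant": 2, "not_impaired": 2},
            layout, EffectModel(seed=26))
        part = run_tertiary(tables)["partition"]
        assert (part["common"] + part["BEC_dominant"] + part["LEC_dominant"]
                == part["n_impaired_any"])

    def test_missing_cell_type_rejected(self, layout):
        tables, _ = generate_tertiary_dataset({"common": 2}, layout,
                                              EffectModel(seed=27))
        with pytest.raises(ValueError, match="BEC"):
            run_tertiary({"LEC": tables["LEC"]})


class TestRunTier:
    def test_rerun_is_byte_identical(self, tmp_path):
        for d in ("run1", "run2"):
            cfg = RunConfig(tier="primary", seed=5, n_plates=2,
                            outdir=str(tmp_path / d))
            run_tier(cfg)
        for name in ("primary_scores", "qc_report", "well_scores", "truth_recovery"):
            a = (tmp_path / "run1" / f"{name}.csv").read_bytes()
            b = (tmp_path / "run2" / f"{name}.csv").read_bytes()
            assert a == b

    def test_all_tiers_produce_outputs(self, tmp_path):
        for tier, expected in [("primary", "primary_scores.csv"),
                               ("secondary", "confidence_table.csv"),
                               ("tertiary", "tertiary_partition.csv")]:
            out = tmp_path / tier
            run_tier(RunConfig(tier=tier, seed=3, n_plates=2, n_genes=20,
                               tertiary_class_counts={"common": 4, "BEC_dominant": 2,
                                                      "LEC_dominant": 2,
                                                      "not_impaired": 2},
                               outdir=str(out)))
            assert (out / expected).exists()

    def test_config_from_yaml(self):
        cfg = load_config("tier: secondary\nseed: 9\nn_genes: 12\n"
                          "effects: {p_lethal: 0.1, seed: 0}\n")
        assert cfg.tier == "secondary" and cfg.n_genes == 12
        assert cfg.effects.p_lethal == 0.1
        with pytest.raises(ValueError):
            load_config("tier: quaternary\n")


class TestImageIO:
    def test_tiff_roundtrip_and_naming(self, tmp_path):
        img = np.arange(12, dtype=np.uint16).reshape(3, 4)
        path = write_image(tmp_path, "P001", "B03", "celltracker", "A0", img)
        assert path.name == "P001_B03_celltracker_A0.tif"
        assert np.array_equal(read_image(path), img)
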