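import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woundscreen import screen_stats as ss


class TestNormalization:
    def plate(self, mock_ams, lib_ams):
        rows = [{"role": "mock", "Am_px": a, "qc_flag": "ok"} for a in mock_ams]
        rows += [{"role": "library", "Am_px": a, "qc_flag": "ok"} for a in lib_ams]
        return pd.DataFrame(rows)

    def test_mock_median_maps_to_one(self):
        df = ss.normalize_migration(self.plate([100, 200, 300], [100, 200]))
        lib = df[df["role"] == "library"]["norm_migration"]
        assert lib.tolist() == [0.5, 1.0]
        assert df[df["role"] == "mock"]["norm_migration"].median() == 1.0

    def test_scale_invariance(self):
        base = self.plate([100, 200, 300], [150, 250])
        scaled = base.copy()
        scaled["Am_px"] *= 7.3
        a = ss.normalize_migration(base)["norm_migration"]
        b = ss.normalize_migration(scaled)["norm_migration"]
        assert np.allclose(a, b)

    def test_too_few_mocks_rejected(self):
        with pytest.raises(ss.NormalizationError):
            ss.normalize_migration(self.plate([100], [150]))

    def test_excluded_mocks_ignored(self):
        df = self.plate([100, 200, 300], [150])
        df.loc[df["Am_px"] == 300, "qc_flag"] = "failed_scratch"
        out = ss.normalize_migration(df)
        assert out.loc[out["role"] == "library", "norm_migration"].iloc[0] == 1.0


class TestRobustZ:
    def test_hand_computed_oracle(self):
        """{1,2,3,4,100}: median 3, raw MAD 1 -> z(100) = 97/1.4826."""
        z = ss.robust_z([1, 2, 3, 4, 100])
        assert z[4] == pytest.approx(97 / 1.4826)
        assert ss.robust_z([1, 2, 3, 4, 100], scale=1.0)[4] == pytest.approx(97.0)

    def test_median_scores_zero(self):
        z = ss.robust_z([1, 2, 3, 4, 100])
        assert z[2] == 0.0

    def test_symmetry(self):
        z = ss.robust_z([-3, -1, 0, 1, 3])
        assert np.allclose(z, -z[::-1])

    def test_degenerate_spread(self):
        with pytest.raises(ss.DegenerateSpreadError):
            ss.robust_z([5, 5, 5, 5, 9])
        with pytest.raises(ValueError):
            ss.robust_z([1, 2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=5, max_size=30, unique=True))
    def test_location_scale_equivariance(self, xs):
        z = ss.robust_z([float(x) for x in xs])
        z_shifted = ss.robust_z([3.0 * x + 7.0 for x in xs])
        assert np.allclose(z, z_shifted, atol=1e-8)


class TestBinning:
    @pytest.mark.parametrize("z,viability,expected", [
        (-2.46, "normal", ss.INHIBITED),   # CDC42-like score
        (-2.0, "normal", ss.NONE),         # strict boundary
        (2.0, "normal", ss.NONE),
        (2.01, "normal", ss.ACCELERATED),
        (-5.0, "LowCellCount", "LowCellCount"),  # viability precedence
        (0.0, "normal", ss.NONE)])
    def test_primary_bins(self, z, viability, expected):
        assert ss.bin_primary(z, viability) == expected

    @pytest.mark.parametrize("m,expected", [
        (0.59, ss.IMPAIRED), (0.6, ss.NONE), (1.0, ss.NONE),
        (1.3, ss.NONE), (1.31, ss.ACCELERATED)])
    def test_secondary_bins(self, m, expected):
        assert ss.bin_secondary(m) == expected

    def test_secondary_viability_precedence(self):
        assert ss.bin_secondary(0.2, "LowCellCount") == "LowCellCount"


class TestSSMD:
    def test_closed_form(self):
        """neg ~ (1.0, sd 0.1), pos ~ (0.5, sd 0.1): 0.5/sqrt(0.02) ~ 3.54."""
        neg, pos = [0.9, 1.0, 1.1], [0.4, 0.5, 0.6]
        assert ss.plate_ssmd(pos, neg) == pytest.approx(0.5 / np.sqrt(0.02))

    def test_identical_distributions_score_zero(self):
        assert ss.plate_ssmd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_shift_invariance_and_scale(self):
        neg, pos = np.array([0.9, 1.0, 1.1]), np.array([0.4, 0.5, 0.6])
        base = ss.plate_ssmd(pos, neg)
        assert ss.plate_ssmd(pos + 5, neg + 5) == pytest.approx(base)
        spread = ss.plate_ssmd(1.0 + 2 * (pos - pos.mean()) - 0.5,
                               1.0 + 2 * (neg - neg.mean()))
        assert spread == pytest.approx(base / 2)

    def test_pass_boundary(self):
        assert ss.QCReport("p", ssmd_cdc42=1.0, ssmd_cdh5=0.2).passed
        assert not ss.QCReport("p", ssmd_cdc42=0.9, ssmd_cdh5=0.5).passed
        assert ss.QCReport("p", 0.3, 0.9).ssmd_best == 0.9

    def test_degenerate(self):
        with pytest.raises(ss.DegenerateSpreadError):
            ss.plate_ssmd([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            ss.plate_ssmd([1.0], [1.0, 2.0])

    def test_robust_variant(self):
        rng = np.random.default_rng(3)
        neg = rng.normal(1.0, 0.1, 50)
        pos = rng.normal(0.5, 0.1, 50)
        assert ss.plate_ssmd(pos, neg, robust=True) == pytest.approx(
            ss.plate_ssmd(pos, neg), rel=0.3)


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        a = [0.5, 1.0, 1.5, 2.0]
        assert ss.replicate_correlation(a, a) == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = np.array([-1.0, 0.0, 1.0])
        assert ss.replicate_correlation(a, -a) == pytest.approx(-1.0)

    def test_degenerate(self):
        with pytest.raises(ss.DegenerateSpreadError):
            ss.replicate_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            ss.replicate_correlation([1, 2], [1, 2])


class TestDeconvConfidence:
    def panel(self, bins, phenotype=ss.INHIBITED):
        return ss.DuplexPanel("g", tuple(bins), phenotype)

    @pytest.mark.parametrize("bins,expected", [
        (("Impaired", "Impaired", "none", "none"), "medium"),
        (("Impaired", "none", "none", "none"), "low"),
        (("Impaired", "Impaired", "Impaired", "none"), "high"),
        (("Impaired",) * 4, "very_high"),
        (("none",) * 4, "none"),
        (("LowCellCount", "none", "none", "none"), "toxic")])
    def test_confidence_classes(self, bins, expected):
        assert ss.assign_deconv_confidence(self.panel(bins)) == expected

    def test_low_count_with_phenotype_is_not_toxic(self):
        p = self.panel(("LowCellCount", "Impaired", "Impaired", "none"))
        assert ss.assign_deconv_confidence(p) == "medium"

    def test_accelerated_phenotype_counts_accelerated_bins(self):
        p = self.panel(("Accelerated", "Accelerated", "none", "none"), ss.ACCELERATED)
        assert ss.assign_deconv_confidence(p) == "medium"
        p2 = self.panel(("Impaired", "Impaired", "none", "none"), ss.ACCELERATED)
        assert ss.assign_deconv_confidence(p2) == "none"

    def test_wrong_panel_size_rejected(self):
        with pytest.raises(ValueError):
            ss.DuplexPanel("g", ("none",) * 3, ss.INHIBITED)


class TestTertiary:
    @pytest.mark.parametrize("lec,bec,expected", [
        (0.5, 0.5, "common"), (0.9, 0.5, "BEC_dominant"),
        (0.5, 0.9, "LEC_dominant"), (0.9, 0.9, "not_impaired"),
        (0.6, 0.59, "BEC_dominant")])  # strict threshold
    def test_classes(self, lec, bec, expected):
        assert ss.classify_tertiary("g", lec, bec).cls == expected

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="BEC"):
            ss.classify_tertiary("g", 0.5, float("nan"))

    def test_partition_sums(self):
        calls = ([ss.classify_tertiary(f"g{i}", 0.5, 0.5) for i in range(4)]
                 + [ss.classify_tertiary(f"b{i}", 0.9, 0.5) for i in range(3)]
                 + [ss.classify_tertiary(f"n{i}", 1.0, 1.0) for i in range(2)])
        part = ss.tertiary_partition(calls)
        assert part["n_impaired_any"] == 7
        assert part["common_pct"] == pytest.approx(round(4 / 7 * 100, 1))


class TestConfidenceTable:
    def test_percentage_row_and_totals(self):
        counts = pd.DataFrame(
            [[2, 1, 1, 4, 1, 1], [0, 5, 3, 0, 0, 0]],
            index=["Impaired", "Accelerated"],
            columns=["Toxic", "0/4", "1/4", "2/4", "3/4", "4/4"])
        table = ss.confidence_table_from_counts(counts)
        assert table.loc["Impaired", "Total"] == 10
        assert table.loc["Accelerated", "Total"] == 8
        assert table.loc["Percentage", "2/4"] == pytest.approx(round(4 / 18 * 100, 1))
        assert table.loc["Percentage", "Total"] == 100.0

    def test_all_quiet_screen(self):
        counts = pd.DataFrame([[0, 7, 0, 0, 0, 0], [0, 3, 0, 0, 0, 0]],
                              index=["Impaired", "Accelerated"],
                              columns=["Toxic", "0/4", "1/4", "2/4", "3/4", "4/4"])
        table = ss.confidence_table_from_counts(counts)
        assert table.loc["Percentage", "0/4"] == 100.0
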