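import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse

from woundscreen.morphology import (FEATURE_NAMES, DegenerateFeatureError,
                                    compute_cell_features, measure_field,
                                    normalize_signatures, segment_cells,
                                    well_signature)
from woundscreen.synthetic import (CellFieldTruth, CellTruth, ImageSpec,
                                   generate_cell_field, random_cell_field)


def mask_from(rr, cc, shape=(301, 301)):
    m = np.zeros(shape, bool)
    m[rr, cc] = True
    return m


def uniform(shape=(301, 301), level=1000.0):
    return np.full(shape, level)


class TestClosedForms:
    def test_digital_disk_is_round(self):
        m = mask_from(*disk((150, 150), 50))
        f = compute_cell_features(m, uniform())
        assert f.shape_factor == pytest.approx(1.0, abs=0.1)
        assert f.elliptical_form_factor == pytest.approx(1.0, abs=0.1)
        assert f.area == pytest.approx(np.pi * 50 ** 2, rel=0.02)

    @pytest.mark.parametrize("rotation", [0.0, 0.6, 1.1])
    def test_three_to_one_ellipse(self, rotation):
        m = mask_from(*ellipse(150, 150, 45, 15, rotation=rotation))
        f = compute_cell_features(m, uniform())
        assert f.elliptical_form_factor == pytest.approx(3.0, rel=0.10)
        assert f.length >= f.breadth

    def test_constant_intensity_texture(self):
        m = mask_from(*disk((150, 150), 40))
        f = compute_cell_features(m, uniform(level=1234.0))
        assert f.intensity_sd == 0.0
        assert f.inverse_difference_moment == 1.0
        assert f.texture_difference_moment == 0.0
        assert f.average_intensity == 1234.0

    def test_total_intensity_identity(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(100, 2000, size=(301, 301))
        m = mask_from(*ellipse(150, 150, 40, 25))
        f = compute_cell_features(m, img)
        assert f.total_intensity == pytest.approx(f.average_intensity * f.area, rel=1e-12)

    def test_scale_invariance_of_shape_descriptors(self):
        small = compute_cell_features(mask_from(*ellipse(150, 150, 30, 15)), uniform())
        big = compute_cell_features(mask_from(*ellipse(150, 150, 60, 30)), uniform())
        assert big.area == pytest.approx(4 * small.area, rel=0.03)
        assert big.perimeter == pytest.approx(2 * small.perimeter, rel=0.03)
        assert big.shape_factor == pytest.approx(small.shape_factor, abs=0.05)
        assert big.elliptical_form_factor == pytest.approx(
            small.elliptical_form_factor, rel=0.05)

    def test_border_touching_flagged(self):
        m = np.zeros((100, 100), bool)
        m[0:30, 40:60] = True
        f = compute_cell_features(m, uniform((100, 100)))
        assert f.touches_border
        assert well_signature([f])[0] != f.area or np.isnan(well_signature([f])[0])


class TestSegmentation:
    def test_recovers_cell_count_and_areas(self):
        spec = ImageSpec(400, 400, pixel_size_um=0.59, noise_sd=20.0, seed=8)
        truth = random_cell_field(spec, 6)
        nuc, cell, fact = generate_cell_field(spec, truth)
        labels = segment_cells(nuc, cell)
        assert labels.max() == 6
        got = sorted(np.bincount(labels.ravel())[1:])
        expected = sorted(c.area_px for c in truth.cells)
        assert np.allclose(got, expected, rtol=0.10)

    def test_single_cell_area(self):
        spec = ImageSpec(200, 200, pixel_size_um=0.59, noise_sd=10.0, seed=9)
        c = CellTruth((100.0, 100.0), np.pi * 40 * 25, 80.0, 50.0, 0.4, 1500.0)
        nuc, cell, fact = generate_cell_field(spec, CellFieldTruth([c]))
        labels = segment_cells(nuc, cell)
        assert labels.max() == 1
        assert (labels == 1).sum() == pytest.approx(c.area_px, rel=0.10)

    def test_empty_field_gives_empty_mask(self):
        spec = ImageSpec(120, 120, pixel_size_um=0.59, noise_sd=10.0, seed=10)
        nuc, cell, _ = generate_cell_field(spec, CellFieldTruth([]))
        assert segment_cells(nuc, cell).max() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_cells(np.zeros((10, 10)), np.zeros((12, 10)))


class TestAggregation:
    def test_well_signature_is_mean(self):
        m1 = mask_from(*disk((60, 60), 10), shape=(200, 200))
        m2 = mask_from(*disk((140, 140), 20), shape=(200, 200))
        f1 = compute_cell_features(m1, uniform((200, 200)))
        f2 = compute_cell_features(m2, uniform((200, 200)))
        sig = well_signature([f1, f2])
        assert sig[FEATURE_NAMES.index("area")] == pytest.approx((f1.area + f2.area) / 2)

    def test_empty_well_is_missing(self):
        assert np.isnan(well_signature([])).all()

    def test_identical_cells_signature_equals_single(self):
        m = mask_from(*disk((60, 60), 15), shape=(200, 200))
        f = compute_cell_features(m, uniform((200, 200)))
        assert np.allclose(well_signature([f, f]), f.as_array())


def toy_signature_frame():
    rng = np.random.default_rng(17)
    rows = []
    for i in range(5):
        for rep in "AB":
            vals = rng.normal(10 * (i + 1), 1.0, size=len(FEATURE_NAMES))
            rows.append({"sirna_id": f"s{i}", "replicate": rep,
                         **dict(zip(FEATURE_NAMES, vals))})
    return pd.DataFrame(rows)


class TestNormalization:
    def test_matches_brute_force_median_mad(self):
        df = toy_signature_frame()
        z = normalize_signatures(df)
        averaged = df.groupby("sirna_id")[list(FEATURE_NAMES)].mean()
        for col in FEATURE_NAMES:
            x = averaged[col].to_numpy()
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            assert np.allclose(z[col], (x - med) / (1.4826 * mad))

    def test_median_signature_scores_zero(self):
        df = toy_signature_frame()
        z = normalize_signatures(df)
        assert np.allclose(z.median(axis=0), 0.0, atol=1e-12)

    def test_degenerate_feature_named(self):
        df = toy_signature_frame()
        df["area"] = 100.0
        with pytest.raises(DegenerateFeatureError, match="area"):
            normalize_signatures(df)

    def test_plain_z_option(self):
        df = toy_signature_frame()
        z = normalize_signatures(df, robust=False)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


def signatures_through_pipeline(elongated_id="s-elong", n_neutral=9, seed=40):
    """Image -> segmentation -> features -> well signatures for a small
    screen in which one siRNA induces a 3:1 elongation phenotype."""
    rows = []
    sirnas = [f"s{i:02d}" for i in range(n_neutral)] + [elongated_id]
    for i, sid in enumerate(sirnas):
        aspect = (2.8, 3.2) if sid == elongated_id else (1.05, 1.5)
        for r, rep in enumerate("AB"):
            spec = ImageSpec(360, 360, pixel_size_um=0.59, noise_sd=15.0,
                             seed=seed + 10 * i + r)
            truth = random_cell_field(spec, 5, aspect_range=aspect)
            nuc, cell, fact = generate_cell_field(spec, truth)
            cells = measure_field(segment_cells(nuc, cell), fact)
            sig = well_signature(cells)
            rows.append({"sirna_id": sid, "replicate": rep,
                         **dict(zip(FEATURE_NAMES, sig))})
    return pd.DataFrame(rows)


class TestElongationPhenotype:
    def test_elongated_knockdown_scores_like_cdc42(self):
        """An induced 3:1 elongation shows the canonical signature: high
        elliptical form factor z, strongly negative shape factor z."""
        df = signatures_through_pipeline()
        z = normalize_signatures(df)
        assert z.loc["s-elong", "elliptical_form_factor"] > 2
        assert z.loc["s-elong", "shape_factor"] < -2
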