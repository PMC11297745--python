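import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizoseit import (
    PowerLawCalibration,
    RootZoneMask,
    average_chargeability,
    averaged_relaxation_time,
    fit_powerlaw,
    image_metrics,
    integrated_chargeability,
    mask_background,
    predict_traits,
    summarize_root_zone,
)
from rhizoseit.geometry import TriMesh
from oracles import powerlaw_grid_search


@pytest.fixture()
def two_cell_mesh():
    """Two triangles with volume ratio 1:3."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [4.0, 0.0]])
    cells = np.array([[0, 1, 2], [1, 3, 2]])
    return TriMesh(nodes, cells, thickness=1.0)


class TestRootZoneIntegration:
    def test_volume_weighted_mean_hand_example(self, two_cell_mesh):
        """Cells with volumes 1:3 and chargeabilities 0.04 / 0.08 average to
        0.07."""
        mask = RootZoneMask(np.array([0, 1]), two_cell_mesh)
        m_bar = average_chargeability(np.array([0.04, 0.08]), mask)
        assert m_bar == pytest.approx(0.07)

    def test_uniform_field_identity(self, coarse_mesh, rng):
        mask = RootZoneMask(rng.choice(coarse_mesh.n_cells, 200, replace=False), coarse_mesh)
        m = np.full(coarse_mesh.n_cells, 0.0123)
        assert average_chargeability(m, mask) == pytest.approx(0.0123, rel=1e-12)

    def test_empty_mask_rejected(self, coarse_mesh):
        mask = RootZoneMask(np.array([], int), coarse_mesh)
        with pytest.raises(ValueError):
            average_chargeability(np.zeros(coarse_mesh.n_cells), mask)

    def test_integrated_chargeability_product_and_additivity(self):
        assert integrated_chargeability(0.0, 1e-4) == 0.0
        # m_bar = 0.01 over 500 cm^3 integrates to 5 cm^3
        assert integrated_chargeability(0.01, 500e-6) == pytest.approx(5.0)
        v1, v2 = 3e-4, 7e-4
        m1, m2 = 0.02, 0.05
        union = integrated_chargeability((m1 * v1 + m2 * v2) / (v1 + v2), v1 + v2)
        assert union == pytest.approx(
            integrated_chargeability(m1, v1) + integrated_chargeability(m2, v2)
        )

    def test_relaxation_time_volume_weighting(self, two_cell_mesh):
        mask = RootZoneMask(np.array([0, 1]), two_cell_mesh)
        tau = averaged_relaxation_time(np.array([2e-3, 4e-3]), mask)
        assert tau == pytest.approx((2e-3 * 0.5 + 4e-3 * 1.5) / 2.0)

    def test_relaxation_time_skips_nan_cells(self, two_cell_mesh):
        mask = RootZoneMask(np.array([0, 1]), two_cell_mesh)
        tau = averaged_relaxation_time(np.array([np.nan, 4e-3]), mask)
        assert tau == pytest.approx(4e-3)

    def test_summary_combines_all_parameters(self, two_cell_mesh):
        mask = RootZoneMask(np.array([0, 1]), two_cell_mesh)
        s = summarize_root_zone(np.array([0.04, 0.08]), np.array([2e-3, 2e-3]), mask)
        assert s.mean_chargeability == pytest.approx(0.07)
        assert s.integrated_chargeability == pytest.approx(0.07 * 2.0 * 1e6)
        assert s.mean_relaxation_time == pytest.approx(2e-3)
        assert s.n_cells == 2


class TestPredictTraits:
    def test_calibration_constants_at_unit_chargeability(self):
        """m_rz = 1 cm^3 predicts 221 cm^2 surface area and 0.169 g biomass."""
        out = predict_traits(1.0)
        assert out["surface_area_cm2"] == pytest.approx(221.0)
        assert out["biomass_g"] == pytest.approx(0.169)

    def test_zero_maps_to_zero(self):
        out = predict_traits(0.0)
        assert out["surface_area_cm2"] == 0.0 and out["biomass_g"] == 0.0

    def test_two_gram_plant(self):
        assert predict_traits(13.9)["biomass_g"] == pytest.approx(2.0, abs=0.01)

    def test_negative_chargeability_rejected(self):
        with pytest.raises(ValueError):
            predict_traits(-0.1)


class TestFitPowerlaw:
    def test_exact_data_recovered_exactly(self):
        x = np.geomspace(0.1, 30, 12)
        cal = fit_powerlaw(x, 2.0 * x**0.9)
        assert cal.coefficient == pytest.approx(2.0, rel=1e-10)
        assert cal.exponent == pytest.approx(0.9, abs=1e-10)
        assert cal.r_squared == pytest.approx(1.0)

    def test_agrees_with_grid_search_oracle(self, rng):
        """Log-space least squares matches an independent refined grid search
        on 10 random noisy datasets."""
        for _ in range(10):
            x = np.exp(rng.uniform(-1, 3, 15))
            coef = float(np.exp(rng.uniform(-1, 3)))
            exp = float(rng.uniform(0.3, 1.5))
            y = coef * x**exp * np.exp(rng.normal(0, 0.2, 15))
            cal = fit_powerlaw(x, y)
            coef_o, exp_o = powerlaw_grid_search(x, y)
            assert cal.exponent == pytest.approx(exp_o, abs=2e-3)
            assert np.log10(cal.coefficient) == pytest.approx(np.log10(coef_o), abs=2e-3)

    def test_exponent_recovery_at_study_sample_size(self, rng):
        """n = 23 plants with 20% log-normal scatter recover the generating
        exponent 0.93 within +-0.15."""
        x = np.exp(rng.uniform(np.log(0.05), np.log(14), 23))
        y = 221.0 * x**0.93 * np.exp(rng.normal(0, 0.2, 23))
        cal = fit_powerlaw(x, y)
        assert abs(cal.exponent - 0.93) < 0.15

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw([1.0, 2.0, 0.0], [1.0, 2.0, 3.0])

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_unit_rescaling_changes_only_coefficient(self, scale):
        x = np.geomspace(0.2, 20, 10)
        y = 3.0 * x**0.8
        base = fit_powerlaw(x, y)
        scaled = fit_powerlaw(x * scale, y)
        assert scaled.exponent == pytest.approx(base.exponent, abs=1e-9)
        assert scaled.coefficient == pytest.approx(
            base.coefficient * scale**-base.exponent, rel=1e-9
        )


class TestImageMetrics:
    def test_identical_images_score_one(self, coarse_mesh, rng):
        img = rng.normal(size=coarse_mesh.n_cells)
        m = image_metrics(img, img, coarse_mesh)
        assert m.pcc == pytest.approx(1.0)
        assert m.ssim == pytest.approx(1.0)

    def test_negated_anomaly_has_anticorrelation(self, coarse_mesh, rng):
        img = rng.normal(size=coarse_mesh.n_cells)
        m = image_metrics(img, -img, coarse_mesh)
        assert m.pcc == pytest.approx(-1.0)

    def test_pcc_matches_covariance_formula(self, coarse_mesh, rng):
        a = rng.normal(size=coarse_mesh.n_cells)
        b = a + rng.normal(size=coarse_mesh.n_cells)
        m = image_metrics(a, b, coarse_mesh)
        manual = np.mean((a - a.mean()) * (b - b.mean())) / (np.std(a) * np.std(b))
        assert m.pcc == pytest.approx(manual, abs=1e-12)

    def test_constant_image_flagged(self, coarse_mesh):
        with pytest.raises(ValueError, match="constant"):
            image_metrics(np.zeros(coarse_mesh.n_cells), np.ones(coarse_mesh.n_cells), coarse_mesh)


class TestMaskBackground:
    def test_all_below_threshold(self):
        assert mask_background(np.full(5, 1e-4)).all()

    def test_partition_matches_direct_comparison(self, rng):
        m = rng.uniform(0, 2e-3, 100)
        assert np.array_equal(mask_background(m), m < 1e-3)

    def test_phantom_roots_survive_masking(self, design_mesh):
        from rhizoseit import PhantomSpec, make_phantom

        ph = make_phantom(PhantomSpec(frequencies=(0.79, 1000.0)), design_mesh)
        bg = mask_background(ph.m_tot_true)
        root = np.isin(np.arange(design_mesh.n_cells), ph.mask.cells)
        assert not bg[root].any()
        assert bg[~root].all()
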