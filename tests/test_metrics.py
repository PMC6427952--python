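"""Metrics: overlap index, push-pull, feedback correlation, tuning slopes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lgnv1 import ModelConfig, WeightSet
from lgnv1.metrics import (
    EllipseFit,
    _ellipse_model,
    bandwidth_contrast_slope,
    feedback_correlation,
    fit_ellipse,
    gaussian_half_width,
    most_significant_subregion,
    overlap_from_widths,
    overlap_index,
    push_pull_from_potentials,
    push_pull_index,
    tuning_bandwidth,
)
from lgnv1.stimuli import CONTRAST_GRID, ORIENTATION_GRID


class TestOverlapIndex:
    @pytest.mark.parametrize(
        "w_on, w_off, d, expected",
        [(1.0, 1.0, 0.0, 1.0),      # complete overlap
         (1.0, 1.0, 2.0, 0.0),      # abutting sub-regions
         (1.0, 1.0, 4.0, -1.0 / 3.0)],  # separated
    )
    def test_hand_values(self, w_on, w_off, d, expected):
        assert overlap_from_widths(w_on, w_off, d) == pytest.approx(expected)

    @given(
        st.floats(0.1, 5.0), st.floats(0.1, 5.0), st.floats(0.0, 50.0)
    )
    def test_bounds(self, w_on, w_off, d):
        io = overlap_from_widths(w_on, w_off, d)
        assert -1.0 < io <= 1.0
        if d == 0.0:
            assert io == 1.0

    def test_full_pipeline_on_constructed_cell(self):
        # build a cell whose ON and OFF excitatory blocks are two displaced
        # Gaussians and check the measured geometry
        cfg = ModelConfig(n_lgn=256, n_cortex=1)
        on = _ellipse_model((16, 16), 10.0, 5.0, 8.0, 1.2, 1.8, 0.0)
        off = _ellipse_model((16, 16), 10.0, 10.0, 8.0, 1.2, 1.8, 0.0)
        zeros = np.zeros((512, 1))
        w = WeightSet(
            A_up_pos=np.concatenate([on.ravel(), off.ravel()])[:, None],
            A_up_neg=zeros, A_dn_pos=zeros.copy(), A_dn_neg=zeros.copy(),
        )
        res = overlap_index(w, cfg, 0)
        assert res is not None
        assert res.d == pytest.approx(5.0, abs=0.1)
        # half-width at 30% along x: a * sqrt(2 ln(1/0.3)) with a = 1.2
        expected_w = 1.2 * np.sqrt(2.0 * np.log(1.0 / 0.3))
        assert res.w_on == pytest.approx(expected_w, rel=0.05)
        assert res.overlap == pytest.approx(
            overlap_from_widths(res.w_on, res.w_off, res.d)
        )

    def test_wide_subregion_excluded(self):
        # a sub-region with major half axis > 3 px fails QC -> cell excluded
        cfg = ModelConfig(n_lgn=256, n_cortex=1)
        on = _ellipse_model((16, 16), 10.0, 8.0, 8.0, 5.0, 5.0, 0.0)
        off = _ellipse_model((16, 16), 10.0, 10.0, 8.0, 1.0, 1.0, 0.0)
        zeros = np.zeros((512, 1))
        w = WeightSet(
            A_up_pos=np.concatenate([on.ravel(), off.ravel()])[:, None],
            A_up_neg=zeros, A_dn_pos=zeros.copy(), A_dn_neg=zeros.copy(),
        )
        assert overlap_index(w, cfg, 0) is None


class TestEllipseFit:
    def test_parameter_recovery(self):
        img = _ellipse_model((16, 16), 12.0, 6.5, 9.0, 1.4, 2.2, 0.6)
        fit = fit_ellipse(img)
        assert fit.fit_error < 1e-6
        assert fit.x0 == pytest.approx(6.5, abs=0.05)
        assert fit.y0 == pytest.approx(9.0, abs=0.05)
        # canonicalized: a is the major half axis
        assert fit.a == pytest.approx(2.2, rel=0.02)
        assert fit.b == pytest.approx(1.4, rel=0.02)

    def test_most_significant_subregion_keeps_peak_component(self):
        block = np.zeros((16, 16))
        block[3, 3] = 1.0   # strongest peak
        block[3, 4] = 0.5
        block[12, 12] = 0.8  # separate secondary region
        region = most_significant_subregion(block)
        assert region[3, 3] == 1.0 and region[3, 4] == 0.5
        assert region[12, 12] == 0.0
        # sub-threshold (< 20% of max) weights are dropped
        block[3, 5] = 0.1
        assert most_significant_subregion(block)[3, 5] == 0.0

    def test_half_width_along_axes(self):
        fit = EllipseFit(1.0, 8.0, 8.0, a=2.0, b=1.0, theta=0.0,
                         fit_error=0.0, qc_pass=True)
        w_major = gaussian_half_width(fit, np.array([1.0, 0.0]))
        w_minor = gaussian_half_width(fit, np.array([0.0, 1.0]))
        assert w_major == pytest.approx(2.0 * np.sqrt(2 * np.log(1 / 0.3)))
        assert w_major == pytest.approx(2.0 * w_minor)


class TestPushPull:
    @pytest.mark.parametrize(
        "p_raw, n_raw, expected",
        [(1.0, -1.0, 0.0),   # perfect push-pull
         (1.0, -0.5, 0.5),
         (0.7, 0.7, 2.0)],   # no pull at all: the printed maximum
    )
    def test_hand_values(self, p_raw, n_raw, expected):
        res = push_pull_from_potentials(p_raw, n_raw)
        assert res.index == pytest.approx(expected)
        assert max(abs(res.p), abs(res.n)) == pytest.approx(1.0)

    def test_zero_potentials_excluded(self):
        assert push_pull_from_potentials(0.0, 0.0) is None

    @given(
        st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
    )
    def test_bounds(self, p_raw, n_raw):
        res = push_pull_from_potentials(p_raw, n_raw)
        if res is not None:
            assert 0.0 <= res.index <= 2.0

    def test_antisymmetric_cell_has_strong_push_pull(self, antisym_factory):
        # a cell excited by ON and inhibited by OFF at the same pixels
        # (composite column [f, -f]) is inhibited by the contrast-reversed
        # stimulus about as much as it is excited by the preferred one
        rng = np.random.default_rng(4)
        field = rng.standard_normal(16)
        field -= field.mean()
        a = np.concatenate([field, -field])
        a /= np.linalg.norm(a)
        w = antisym_factory(a[:, None])
        cfg = ModelConfig(n_lgn=16, n_cortex=1, n_steps=200)
        res = push_pull_index(w, cfg, 0)
        assert res is not None
        assert res.index < 0.5

    def test_zero_field_cell_excluded(self):
        cfg = ModelConfig(n_lgn=16, n_cortex=1)
        z = np.zeros((32, 1))
        w = WeightSet(z, z.copy(), z.copy(), z.copy())
        assert push_pull_index(w, cfg, 0) is None


class TestFeedbackCorrelation:
    def test_self_correlation_is_one(self, small_weights):
        # feedback exactly equal to the ON-minus-OFF field layout gives
        # r_off = -1 and r_on = +1 by construction
        w = small_weights.copy()
        N = w.n_lgn
        sf = w.feedforward[:N] - w.feedforward[N:]
        w.A_dn_pos = np.concatenate([np.maximum(sf, 0), np.maximum(-sf, 0)])
        w.A_dn_neg = np.concatenate([np.minimum(sf, 0), np.minimum(-sf, 0)])
        r_off, r_on = feedback_correlation(w)
        assert r_on == pytest.approx(1.0)
        assert r_off == pytest.approx(-1.0)

    def test_mirror_symmetry(self, antisym_factory):
        # anti-symmetric weights with mirror-symmetric ON/OFF fields give
        # r_on = -r_off
        rng = np.random.default_rng(0)
        half = rng.standard_normal((16, 6))
        A = np.concatenate([half, -half], axis=0)
        w = antisym_factory(A)
        r_off, r_on = feedback_correlation(w)
        assert r_on == pytest.approx(-r_off, abs=1e-12)

    def test_constant_input_rejected(self):
        z = np.zeros((32, 4))
        w = WeightSet(z, z.copy(), z.copy(), z.copy())
        with pytest.raises(ValueError, match="constant"):
            feedback_correlation(w)


class TestTuningSlope:
    @staticmethod
    def _gaussian_curve(fwhm_deg, amplitude, center=90.0):
        sigma = fwhm_deg / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        x = (ORIENTATION_GRID - center + 90.0) % 180.0 - 90.0
        return amplitude * np.exp(-(x**2) / (2.0 * sigma**2))

    def test_bandwidth_recovers_fwhm(self):
        curve = self._gaussian_curve(40.0, 2.0)
        assert tuning_bandwidth(ORIENTATION_GRID, curve) == pytest.approx(40.0, rel=1e-3)

    def test_contrast_scaled_curves_give_zero_slope(self):
        bws = [
            tuning_bandwidth(ORIENTATION_GRID, self._gaussian_curve(35.0, c))
            for c in CONTRAST_GRID
        ]
        slope = bandwidth_contrast_slope(CONTRAST_GRID, np.array(bws))
        assert slope == pytest.approx(0.0, abs=1e-6)

    def test_widening_curves_recover_slope_ten(self):
        bws = [
            tuning_bandwidth(
                ORIENTATION_GRID, self._gaussian_curve(30.0 + 10.0 * c, 1.0)
            )
            for c in CONTRAST_GRID
        ]
        slope = bandwidth_contrast_slope(CONTRAST_GRID, np.array(bws))
        assert slope == pytest.approx(10.0, rel=1e-3)

    def test_isolated_cell_prefers_its_own_grating_and_broadens(self, antisym_factory):
        # the grid search recovers the cell's orientation and frequency;
        # without network competition the soft threshold produces the
        # classic iceberg effect (tuning broadens with contrast)
        from lgnv1 import ModelConfig
        from lgnv1.metrics import contrast_invariance
        from lgnv1.rf_analysis import fit_gabor, gabor

        field = gabor((16, 16), 1.0, 7.5, 7.5, 2.0, 3.5, 0.15, np.deg2rad(40.0), 0.0)
        flat = field.ravel()
        a = np.concatenate([flat, -flat])
        a *= 2.0 / np.linalg.norm(a)
        w = antisym_factory(a[:, None])
        cfg = ModelConfig(n_lgn=256, n_cortex=1)
        res = contrast_invariance(w, cfg, 0, fit_gabor(field))
        assert res is not None
        assert res.preferred.orientation == pytest.approx(40.0, abs=5.0)
        assert res.preferred.spatial_frequency == pytest.approx(0.15, abs=0.051)
        assert res.slope > 0

    def test_silent_curve_undefined(self):
        assert np.isnan(tuning_bandwidth(ORIENTATION_GRID, np.zeros(36)))

    def test_slope_needs_two_valid_contrasts(self):
        bws = np.array([np.nan, np.nan, np.nan, np.nan, 30.0])
        assert np.isnan(bandwidth_contrast_slope(CONTRAST_GRID, bws))
        bws2 = np.array([np.nan, 30.0, np.nan, np.nan, 40.0])
        assert np.isfinite(bandwidth_contrast_slope(CONTRAST_GRID, bws2))
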