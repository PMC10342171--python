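"""Survival-fraction depth response, LQ utilities and the synthetic generator."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iortmc import survival


class TestFitDepthResponse:
    def test_noiseless_line_fits_exactly(self):
        d = np.linspace(10, 35, 12)
        fit = survival.fit_depth_response((d, 0.3 - 0.005 * d))
        assert fit.slope == pytest.approx(-0.005, abs=1e-12)
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-9)

    def test_anchored_line_endpoint_values(self):
        # the anchored response 0.16 at 24.2 mm with slope -0.007 per mm
        assert round(float(survival.anchored_line(15.0)), 2) == 0.22
        assert round(float(survival.anchored_line(33.0)), 2) == 0.10

    def test_pearson_t_and_p_consistent(self):
        rng = np.random.default_rng(1)
        d = np.linspace(15, 33, 18)
        sf = survival.anchored_line(d) + rng.normal(0, 0.03, d.size)
        fit = survival.fit_depth_response((d, np.clip(sf, 1e-3, 1)))
        expect_t = fit.pearson_r * math.sqrt(16) / math.sqrt(1 - fit.pearson_r**2)
        assert fit.t_statistic == pytest.approx(expect_t, rel=1e-9)
        assert 0.0 <= fit.p_value <= 1.0

    def test_identical_depths_rejected(self):
        with pytest.raises(ValueError):
            survival.fit_depth_response((np.full(5, 20.0), np.linspace(0.1, 0.2, 5)))


class TestNormalizeSeries:
    def _three_sessions(self, seed=2):
        # each session measures the same six depths, including the 15 mm
        # record shared by all series
        depths = np.tile(np.linspace(15.0, 33.0, 6), 3)
        sessions = np.repeat([1, 2, 3], 6)
        return survival.generate_synthetic_sf(
            depths_mm=depths, sessions=sessions, seed=seed
        )

    def test_pooled_fit_passes_through_anchor(self):
        raw = self._three_sessions()
        out = survival.normalize_series(raw, common_depth_mm=15.0, anchor=(24.2, 0.16))
        fit = survival.fit_depth_response(out)
        assert fit.predict(24.2) == pytest.approx(0.16, abs=1e-9)
        assert out.normalized

    def test_scaling_preserves_pearson_r(self):
        raw = self._three_sessions()
        out = survival.normalize_series(raw, 15.0, (24.2, 0.16))
        # the final anchoring step is a positive scaling of SF only
        r_scaled = survival.fit_depth_response(out).pearson_r
        sf = raw.sf.copy()
        for ses in raw.sessions():
            m = raw.session == ses
            near = m & (np.abs(raw.depth_mm - 15.0) <= 0.3)
            sf[m] = sf[m] / sf[near].mean()
        r_unscaled = survival.fit_depth_response((raw.depth_mm, sf)).pearson_r
        assert r_scaled == pytest.approx(r_unscaled, abs=1e-12)

    def test_series_already_through_anchor_unchanged(self):
        d = np.linspace(15, 33, 10)
        sf = survival.anchored_line(d)
        raw = survival.SurvivalSeries(d, sf, np.ones(10, dtype=int))
        out = survival.normalize_series(raw, 15.0, (24.2, 0.16))
        assert np.allclose(out.sf, sf, atol=1e-12)

    def test_missing_common_depth_names_session(self):
        d = np.array([15.0, 24.0, 20.0, 24.0])
        raw = survival.SurvivalSeries(
            d, np.full(4, 0.2), np.array([1, 1, 2, 2])
        )
        with pytest.raises(ValueError, match="2"):
            survival.normalize_series(raw, 15.0, (24.2, 0.16))


class TestLQ:
    PARAMS = survival.LQParams(alpha=0.30, beta=0.02)

    def test_five_gray_survival_matches_published_value(self):
        sf = survival.lq_survival(5.0, self.PARAMS)
        assert sf == pytest.approx(math.exp(-2.0), rel=1e-12)
        assert abs(sf - 0.13) < 0.006  # the printed two-decimal value

    def test_zero_dose_gives_unity(self):
        assert survival.lq_survival(0.0, self.PARAMS) == 1.0

    def test_pure_exponential_limit(self):
        p = survival.LQParams(alpha=0.30, beta=0.0)
        assert survival.lq_survival(4.0, p) == pytest.approx(math.exp(-1.2))

    def test_equivalent_dose_inverts_survival(self):
        assert survival.lq_equivalent_dose(
            survival.lq_survival(5.0, self.PARAMS), self.PARAMS
        ) == pytest.approx(5.0, abs=1e-9)
        assert survival.lq_equivalent_dose(1.0, self.PARAMS) == 0.0

    @given(st.floats(min_value=0.01, max_value=12.0))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_round_trip_identity(self, dose):
        sf = survival.lq_survival(dose, self.PARAMS)
        assert survival.lq_equivalent_dose(sf, self.PARAMS) == pytest.approx(
            dose, rel=1e-9
        )

    def test_survival_strictly_decreasing_in_dose(self):
        doses = np.linspace(0, 10, 50)
        sf = survival.lq_survival(doses, self.PARAMS)
        assert np.all(np.diff(sf) < 0)

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            survival.lq_equivalent_dose(0.0, self.PARAMS)
        with pytest.raises(ValueError):
            survival.lq_equivalent_dose(1.5, self.PARAMS)


class TestBiologicalDamage:
    def test_equal_sf_gives_unit_damage(self):
        d = np.array([15.3, 24.0, 30.0])
        out = survival.biological_damage_from_sf(d, np.full(3, 0.2))
        assert np.allclose(out["relative_damage"], 1.0)

    def test_reference_depth_is_anchor(self):
        d = np.array([15.3, 24.0, 30.0])
        out = survival.biological_damage_from_sf(d, np.array([0.22, 0.16, 0.12]))
        assert out["relative_damage"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("convention", survival.DAMAGE_CONVENTIONS)
    def test_damage_increases_as_sf_decreases(self, convention):
        d = np.linspace(15, 33, 10)
        sf = survival.anchored_line(d)
        out = survival.biological_damage_from_sf(d, sf, convention=convention)
        assert np.all(np.diff(out["damage"]) > 0)

    def test_zero_sf_rejected(self):
        with pytest.raises(ValueError):
            survival.biological_damage_from_sf(
                np.array([15.0, 20.0]), np.array([0.2, 0.0])
            )


class TestRbePerMm:
    def test_published_endpoints(self):
        # RBE 0.74 -> 0.84 over 15 -> 30 mm
        rate = survival.rbe_per_mm(0.74, 15.0, 0.84, 30.0)
        assert rate == pytest.approx(0.00667, abs=5e-5)
        assert abs(rate - 0.0066) < 1e-4

    def test_equal_rbe_gives_zero(self):
        assert survival.rbe_per_mm(0.8, 15.0, 0.8, 30.0) == 0.0

    @given(
        st.floats(0.5, 1.5), st.floats(10, 20), st.floats(0.5, 1.5), st.floats(25, 35)
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_sign_conventions_under_swaps(self, ra, da, rb, db):
        # swapping the two RBE values reverses the sign; relabelling both
        # endpoints together leaves the rate unchanged
        rate = survival.rbe_per_mm(ra, da, rb, db)
        assert survival.rbe_per_mm(rb, da, ra, db) == pytest.approx(
            -rate, rel=1e-9, abs=1e-12
        )
        assert survival.rbe_per_mm(rb, db, ra, da) == pytest.approx(
            rate, rel=1e-9, abs=1e-12
        )

    def test_equal_depths_rejected(self):
        with pytest.raises(ValueError):
            survival.rbe_per_mm(0.74, 20.0, 0.84, 20.0)


class TestSyntheticGenerator:
    def test_zero_noise_reproduces_exact_line(self):
        s = survival.generate_synthetic_sf(noise_sd=0.0, seed=5)
        assert np.allclose(s.sf, survival.anchored_line(s.depth_mm), atol=1e-12)

    def test_reproducible_for_fixed_seed(self):
        a = survival.generate_synthetic_sf(seed=6)
        b = survival.generate_synthetic_sf(seed=6)
        assert np.array_equal(a.sf, b.sf)

    def test_slope_recovery_over_replicates(self):
        """Fitted slope is unbiased at the study design: mean over 200
        replicates within 15% of the true slope and |bias| < SE."""
        slopes = []
        for rep in range(200):
            s = survival.generate_synthetic_sf(seed=1000 + rep)
            slopes.append(survival.fit_depth_response(s).slope)
        slopes = np.array(slopes)
        assert slopes.mean() == pytest.approx(-0.007, rel=0.15)
        se = slopes.std(ddof=1) / math.sqrt(slopes.size)
        assert abs(slopes.mean() - (-0.007)) < 2 * se

    def test_pearson_r_matches_study_design(self):
        rs = [
            survival.fit_depth_response(
                survival.generate_synthetic_sf(seed=2000 + rep)
            ).pearson_r
            for rep in range(200)
        ]
        assert np.mean(rs) == pytest.approx(-0.786, abs=0.05)

    def test_clipped_to_physical_range(self):
        s = survival.generate_synthetic_sf(noise_sd=0.5, seed=9)
        assert np.all(s.sf > 0) and np.all(s.sf <= 1.0)
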