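"""Wavelet linear models: exact-fit cases, the closed-form normal-equation
oracle, the algebraic attribution identity, and constructed-lag phases."""

import numpy as np
import pytest

from synchwave import (
    TimescaleBand,
    clean_series,
    fit_wlm,
    model_band_phase,
    predicted_mean_field,
    synchrony_explained,
    transform_series,
    wlm_analysis,
    wlm_diagnostics,
)
from synchwave.types import WaveletFieldSet

from conftest import make_series, seasonal_noise

BAND = TimescaleBand(8, 16)


def fields_of(rng, values=None, **kw):
    vals = values if values is not None else seasonal_noise(rng, **kw)
    return transform_series(clean_series(make_series(vals)))


def scaled_copy(fields, beta):
    return WaveletFieldSet(
        beta * fields.coefficients, fields.grid, fields.valid_mask,
        fields.site_ids, "across_locations",
    )


class TestFit:
    def test_exact_fit_recovers_complex_coefficient(self, rng):
        fx = fields_of(rng)
        beta = 0.5 * np.exp(1j * np.pi / 4)
        fy = scaled_copy(fx, beta)
        m = fit_wlm(fy, [fx], BAND)
        assert np.max(np.abs(m.coeffs - beta)) < 1e-8

    def test_matches_closed_form_single_predictor(self, rng):
        # beta(s) = <w~y conj(w~x)> / <|w~x|^2> pooled over sites/valid times
        fx = fields_of(rng)
        fy = fields_of(rng, values=seasonal_noise(rng, amp=1.0, noise=1.0))
        m = fit_wlm(fy, [fx], BAND)
        for c, k in enumerate(m.band_idx):
            rows = fy.valid_mask[:, k]
            wy = fy.coefficients[:, rows, k].ravel()
            wx = fx.coefficients[:, rows, k].ravel()
            closed = (wy * np.conj(wx)).sum() / (np.abs(wx) ** 2).sum()
            assert m.coeffs[0, c] == pytest.approx(closed, abs=1e-10)

    def test_orthogonal_predictors_separate(self, rng):
        x1 = seasonal_noise(rng, amp=2.0, noise=0.5)
        x2 = rng.standard_normal((5, 132))
        f1, f2 = fields_of(rng, values=x1), fields_of(rng, values=x2)
        fy = fields_of(rng, values=x1 + 0.05 * rng.standard_normal((5, 132)))
        m = fit_wlm(fy, [f1, f2], BAND, predictors=["a", "b"])
        assert np.median(np.abs(m.coeffs[0])) > 0.8
        assert np.median(np.abs(m.coeffs[1])) < 0.2

    def test_collinear_predictors_raise(self, rng):
        fx = fields_of(rng)
        with pytest.raises(ValueError, match="collinear.*timescale"):
            fit_wlm(fx, [fx, scaled_copy(fx, 2.0)], BAND)

    def test_zero_predictor_gets_zero_coefficient(self, rng):
        fx = fields_of(rng)
        fz = scaled_copy(fx, 0.0)
        fy = scaled_copy(fx, 1.0 + 0.5j)
        m = fit_wlm(fy, [fx, fz], BAND, predictors=["x", "zero"])
        assert np.max(np.abs(m.coeffs[1])) == 0.0
        m = synchrony_explained(m, fy, [fx, fz])
        assert m.sync_explained == pytest.approx(1.0, abs=1e-10)
        assert m.contributions["zero"] == 0.0

    def test_constant_per_band_option(self, rng):
        fx = fields_of(rng)
        fy = scaled_copy(fx, 0.8j)
        m = fit_wlm(fy, [fx], BAND, per_timescale=False)
        assert np.allclose(m.coeffs, m.coeffs[:, :1])
        assert m.coeffs[0, 0] == pytest.approx(0.8j, abs=1e-8)


class TestAttribution:
    def test_exact_fit_explains_everything(self, rng):
        fx = fields_of(rng)
        fy = scaled_copy(fx, 0.5 * np.exp(1j * np.pi / 4))
        m = synchrony_explained(fit_wlm(fy, [fx], BAND), fy, [fx])
        assert m.sync_explained == pytest.approx(1.0, abs=1e-8)
        pred = predicted_mean_field(m, [fx])
        obs = fy.coefficients[:, :, m.band_idx].mean(axis=0)
        assert np.max(np.abs(pred - obs)) < 1e-8

    def test_decomposition_identity_on_random_inputs(self):
        # S_mod = sum(contributions) + sum(crossterms), exactly
        for seed in range(4):
            rng = np.random.default_rng(seed)
            f1 = fields_of(rng, amp=1.0, noise=1.0)
            f2 = fields_of(rng, values=rng.standard_normal((5, 132)))
            fy = fields_of(
                rng,
                values=seasonal_noise(rng, amp=0.7, noise=1.2),
            )
            m = synchrony_explained(fit_wlm(fy, [f1, f2], BAND), fy, [f1, f2])
            mask = fy.valid_mask[:, m.band_idx]
            wmf_y = fy.coefficients[:, :, m.band_idx].mean(axis=0)
            S_obs = np.abs(wmf_y[mask]) ** 2
            S_mod = m.sync_explained * S_obs.mean()
            total = sum(m.contributions.values()) + sum(m.crossterms.values())
            assert S_mod == pytest.approx(total, abs=1e-8)
            assert all(v >= 0 for v in m.contributions.values())

    def test_predicted_field_is_linear_in_drivers(self, rng):
        x1 = seasonal_noise(rng, amp=2.0, noise=0.4)
        x2 = seasonal_noise(rng, period=10.0, amp=1.0, noise=0.4)
        f1, f2 = fields_of(rng, values=x1), fields_of(rng, values=x2)
        fy = fields_of(rng, values=x1 + x2)
        m = synchrony_explained(fit_wlm(fy, [f1, f2], BAND), fy, [f1, f2])
        comp = (
            m.coeffs[0][None, None] * f1.coefficients[:, :, m.band_idx]
            + m.coeffs[1][None, None] * f2.coefficients[:, :, m.band_idx]
        ).mean(axis=0)
        assert np.max(np.abs(m.predicted_wmf - comp)) < 1e-10

    def test_no_synchrony_to_explain_raises(self, rng):
        base = seasonal_noise(rng, n_sites=1)[0]
        f = transform_series(clean_series(make_series(np.vstack([base, -base]))))
        m = fit_wlm(f, [f], BAND)
        fy_anti = WaveletFieldSet(
            np.stack([f.coefficients[0], -f.coefficients[0]]),
            f.grid, f.valid_mask, f.site_ids, "across_locations",
        )
        with pytest.raises(ValueError, match="nothing to explain"):
            synchrony_explained(m, fy_anti, [f])

    def test_relabeling_predictors_permutes_contributions(self, rng):
        x1 = seasonal_noise(rng, amp=2.0, noise=0.5)
        x2 = rng.standard_normal((5, 132))
        f1, f2 = fields_of(rng, values=x1), fields_of(rng, values=x2)
        fy = fields_of(rng, values=x1 + 0.5 * x2)
        m12 = wlm_analysis(fy, [f1, f2], BAND, predictors=["a", "b"])
        m21 = wlm_analysis(fy, [f2, f1], BAND, predictors=["b", "a"])
        assert m12.sync_explained == pytest.approx(m21.sync_explained, abs=1e-10)
        assert m12.contributions["a"] == pytest.approx(m21.contributions["a"], abs=1e-10)
        assert m12.crossterms["a*b"] == pytest.approx(m21.crossterms["b*a"], abs=1e-10)


class TestPhases:
    def test_one_month_lag_at_annual_timescale(self, rng):
        # response lags a 12-mo driver by 1 month: phi = -2/12 = -1/6
        x = seasonal_noise(rng, amp=2.0, noise=0.3)
        fx = fields_of(rng, values=x)
        fy = fields_of(rng, values=np.roll(x, 1, axis=1))
        m = wlm_analysis(fy, [fx], BAND, predictors=["x"])
        assert m.phases["x"] == pytest.approx(-1 / 6, abs=0.02)
        assert m.coefficient_phases["x"] == pytest.approx(-1 / 6, abs=0.02)

    def test_identity_and_antiphase(self, rng):
        fx = fields_of(rng)
        m = wlm_analysis(scaled_copy(fx, 1.0), [fx], BAND, predictors=["x"])
        assert m.phases["x"] == pytest.approx(0.0, abs=1e-10)
        m = wlm_analysis(scaled_copy(fx, -1.0), [fx], BAND, predictors=["x"])
        assert m.phases["x"] == pytest.approx(1.0)

    def test_undefined_phase_for_null_coefficient(self, rng):
        fx = fields_of(rng)
        m = fit_wlm(scaled_copy(fx, 1.0), [fx], BAND, predictors=["x"])
        m.coeffs[:] = 0.0
        with pytest.raises(ValueError, match="undefined"):
            model_band_phase(m, "x", scaled_copy(fx, 1.0), [fx])


class TestDiagnostics:
    def test_exact_fit_perfect_r2_and_silent_residuals(self, rng):
        fx = fields_of(rng)
        fy = scaled_copy(fx, 0.7 * np.exp(-0.3j))
        m = fit_wlm(fy, [fx], BAND)
        d = wlm_diagnostics(m, fy, x_fields=[fx], seed=0)
        assert np.allclose(d["r2_per_timescale"], 1.0, atol=1e-10)
        assert d["residual_wpmf_exceedance"] == 0.0

    def test_noise_response_has_no_explained_structure(self, rng):
        fx = fields_of(rng, amp=2.0, noise=0.3)
        fy = fields_of(rng, values=rng.standard_normal((5, 132)))
        m = wlm_analysis(fy, [fx], BAND, predictors=["x"])
        d = wlm_diagnostics(m, fy, x_fields=[fx], seed=0)
        assert np.mean(d["r2_per_timescale"]) < 0.3
        assert d["residual_wpmf_exceedance"] < 0.3

    def test_omitted_driver_shows_in_residual_coherence(self, rng):
        x1 = seasonal_noise(rng, amp=2.0, noise=0.3)
        x2 = seasonal_noise(rng, period=10.0, amp=2.0, noise=0.3)
        s1 = clean_series(make_series(x1))
        s2 = clean_series(make_series(x2))
        f1, f2 = transform_series(s1), transform_series(s2)
        fy = fields_of(rng, values=x1 + x2 + 0.2 * rng.standard_normal((5, 132)))
        m = wlm_analysis(fy, [f1], BAND, predictors=["x1"])
        d = wlm_diagnostics(m, fy, x_series=[s2], x_fields=[f1], n_surr=199,
                            seed=1)
        # the test harness passes the omitted driver's series: its coherence
        # with the residual field must be detected
        assert d["residual_coherence"]["x1"]["p_value"] < 0.05
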