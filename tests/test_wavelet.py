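"""Transforms, grids, cleaning: oracles are naive direct convolution and
closed-form phase/amplitude properties of sinusoids."""

import numpy as np
import pytest

from synchwave import (
    SpatioTemporalSeries,
    clean_series,
    interpolate_missing,
    make_timescale_grid,
    normalize_transforms,
    transform_series,
    wavelet_transform,
)
from synchwave.types import WaveletFieldSet
from synchwave.wavelet import _edge_mask

from conftest import make_series, seasonal_noise


# ----------------------------------------------------------------------------
# cleaning
# ----------------------------------------------------------------------------

class TestCleanSeries:
    def test_ar1_standardized_moments(self, rng):
        x = np.empty((3, 132))
        x[:, 0] = rng.standard_normal(3)
        for t in range(1, 132):
            x[:, t] = 0.6 * x[:, t - 1] + rng.standard_normal(3) + 5.0
        out = clean_series(make_series(x))
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.values.var(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_perfectly_linear_series_raises_zero_variance(self):
        x = np.tile(np.arange(30.0), (2, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            clean_series(make_series(x))

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            clean_series(make_series(np.full((1, 30), 3.7)), detrend=False)

    def test_missing_value_names_site_and_month(self, rng):
        x = rng.standard_normal((2, 30))
        x[1, 4] = np.nan
        with pytest.raises(ValueError, match="IV.*2009-05"):
            clean_series(make_series(x, t0="2009-01"))

    def test_short_record_rejected(self, rng):
        with pytest.raises(ValueError, match="24"):
            clean_series(make_series(rng.standard_normal((2, 20))))

    def test_interpolation_is_explicit(self, rng):
        x = rng.standard_normal((1, 30))
        truth = 0.5 * (x[0, 3] + x[0, 5])
        x[0, 4] = np.nan
        filled = interpolate_missing(make_series(x))
        assert filled.values[0, 4] == pytest.approx(truth)
        clean_series(filled)  # no longer raises

    def test_boxcox_handles_nonpositive_values(self, rng):
        x = rng.standard_normal((2, 60)) - 5.0
        out = clean_series(make_series(x), boxcox=True)
        assert np.allclose(out.values.var(axis=1, ddof=1), 1.0, atol=1e-12)


# ----------------------------------------------------------------------------
# timescale grid
# ----------------------------------------------------------------------------

class TestTimescaleGrid:
    def test_powers_of_two(self):
        g = make_timescale_grid(132, 1.0, s_min=2, s_max=64, ratio=2.0)
        assert np.allclose(g.timescales, [2, 4, 8, 16, 32, 64])

    def test_count_closed_form(self):
        # floor(log(30)/log(1.05)) + 1 = 70 grid points
        g = make_timescale_grid(132, 1.0, s_min=2, s_max=60, ratio=1.05)
        assert len(g) == 70
        assert g.timescales[-1] <= 60

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(s_min=1), "Nyquist"),
            (dict(s_max=200), "exceeds"),
            (dict(ratio=1.0), "ratio"),
        ],
    )
    def test_invalid_grids(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            make_timescale_grid(132, 1.0, **kwargs)


# ----------------------------------------------------------------------------
# transform
# ----------------------------------------------------------------------------

def naive_transform(x, timescales, dt=1.0):
    """Independent O(T^2) oracle: direct summation of the analytic Morlet
    kernel, truncated at +-4 sigma."""
    T = len(x)
    W = np.zeros((T, len(timescales)), dtype=complex)
    for k, sigma in enumerate(timescales):
        half = int(np.ceil(4.0 * sigma / dt))
        for t in range(T):
            acc = 0.0 + 0.0j
            for u in range(max(0, t - half), min(T, t + half + 1)):
                eta = (u - t) * dt / sigma
                # conj(psi(eta)): the analysis convention, under which the
                # phase at sigma = P advances by +2*pi per P months
                acc += (
                    x[u]
                    * np.pi ** -0.25
                    * np.exp(-2j * np.pi * eta - 0.5 * eta ** 2)
                )
            W[t, k] = acc * dt / sigma
    return W


class TestWaveletTransform:
    def test_matches_direct_convolution_oracle(self, rng):
        T = 64
        x = rng.standard_normal(T)
        x -= x.mean()
        grid = make_timescale_grid(T, s_max=20, ratio=1.3)
        W, _ = wavelet_transform(x, grid)
        assert np.max(np.abs(W - naive_transform(x, grid.timescales))) < 1e-8

    def test_response_peaks_at_period(self):
        T = 132
        x = np.cos(2 * np.pi * np.arange(T) / 12)
        grid = make_timescale_grid(T)
        W, mask = wavelet_transform(x, grid)
        usable = mask.any(axis=0)
        prof = np.where(mask[:, usable], np.abs(W[:, usable]), np.nan)
        with np.errstate(invalid="ignore"):
            profile = np.nanmean(prof, axis=0)
        peak = grid.timescales[usable][np.nanargmax(profile)]
        nearest = grid.timescales[np.argmin(np.abs(grid.timescales - 12))]
        assert peak == pytest.approx(nearest)

    def test_phase_advances_quarter_cycle_in_three_months(self):
        T = 132
        x = np.cos(2 * np.pi * np.arange(T) / 12)
        grid = make_timescale_grid(T)
        k = int(np.argmin(np.abs(grid.timescales - 12)))
        W, _ = wavelet_transform(x, grid)
        for t in (40, 60, 80):
            d = np.angle(W[t + 3, k]) - np.angle(W[t, k])
            assert (d % (2 * np.pi)) == pytest.approx(np.pi / 2, abs=1e-4)

    def test_zero_series_maps_to_zero(self):
        grid = make_timescale_grid(64, s_max=16)
        W, _ = wavelet_transform(np.zeros(64), grid)
        assert np.all(W == 0)

    def test_linearity(self, rng):
        T = 100
        grid = make_timescale_grid(T, s_max=24, ratio=1.2)
        x, y = rng.standard_normal((2, T))
        a, b = 1.7, -0.4
        Wx, _ = wavelet_transform(x, grid)
        Wy, _ = wavelet_transform(y, grid)
        Wab, _ = wavelet_transform(a * x + b * y, grid)
        assert np.max(np.abs(Wab - (a * Wx + b * Wy))) < 1e-10

    def test_time_shift_rotates_phase(self):
        # circular shift of a 12-periodic cosine on T=132 is an exact lag
        T, P, s = 132, 12, 3
        x = np.cos(2 * np.pi * np.arange(T) / P)
        grid = make_timescale_grid(T)
        k = int(np.argmin(np.abs(grid.timescales - P)))
        W, mask = wavelet_transform(x, grid)
        Ws, _ = wavelet_transform(np.roll(x, s), grid)
        interior = slice(40, 90)
        rot = np.angle(Ws[interior, k] / W[interior, k])
        assert np.allclose(rot, -2 * np.pi * s / P, atol=1e-2)

    def test_valid_mask_is_data_independent(self, rng):
        grid = make_timescale_grid(100, s_max=30, ratio=1.2)
        _, m1 = wavelet_transform(rng.standard_normal(100), grid)
        _, m2 = wavelet_transform(np.cos(np.arange(100.0)), grid)
        assert np.array_equal(m1, m2)
        assert np.array_equal(m1, _edge_mask(100, grid, 1.0, 1.0))

    def test_non_finite_input_rejected(self):
        grid = make_timescale_grid(64, s_max=16)
        x = np.zeros(64)
        x[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            wavelet_transform(x, grid)


# ----------------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------------

class TestNormalization:
    def test_across_locations_unit_mean_power(self, seasonal_fields):
        f = seasonal_fields
        mask = f.valid_mask
        power = np.where(mask[None], np.abs(f.coefficients) ** 2, 0.0)
        n_valid = mask.sum(axis=0)
        ok = n_valid > 0
        mean_power = power.sum(axis=(0, 1))[ok] / (f.n_sites * n_valid[ok])
        assert np.allclose(mean_power, 1.0, atol=1e-10)

    def test_scaled_site_per_location_vs_across(self, rng):
        base = seasonal_noise(rng, n_sites=1, T=132)[0]
        s = make_series(np.vstack([base, 3.0 * base]))
        raw = transform_series(clean_series(s, standardize=False),
                               normalization=None)
        per = normalize_transforms(raw, "per_location")
        acc = normalize_transforms(raw, "across_locations")
        # per-location: both sites identical after normalization
        assert np.allclose(per.coefficients[0], per.coefficients[1], atol=1e-10)
        # across-locations: site B keeps 9x site A's power
        pa = np.abs(acc.coefficients[0]) ** 2
        pb = np.abs(acc.coefficients[1]) ** 2
        ratio = pb.sum() / pa.sum()
        assert ratio == pytest.approx(9.0, rel=1e-10)

    def test_idempotent(self, seasonal_fields):
        again = normalize_transforms(seasonal_fields, "across_locations")
        assert np.max(np.abs(again.coefficients - seasonal_fields.coefficients)) < 1e-10

    def test_single_site_methods_coincide(self, rng):
        s = make_series(seasonal_noise(rng, n_sites=1, T=132))
        raw = transform_series(clean_series(s), normalization=None)
        a = normalize_transforms(raw, "per_location")
        b = normalize_transforms(raw, "across_locations")
        assert np.allclose(a.coefficients, b.coefficients)

    def test_zero_power_error_names_pair(self, seasonal_fields):
        coef = seasonal_fields.coefficients.copy()
        coef[1, :, :] = 0.0
        broken = WaveletFieldSet(
            coef, seasonal_fields.grid, seasonal_fields.valid_mask,
            seasonal_fields.site_ids, "none",
        )
        with pytest.raises(ValueError, match="IV"):
            normalize_transforms(broken, "across_locations")

    def test_conflicting_renormalization_rejected(self, seasonal_fields):
        with pytest.raises(ValueError, match="already normalized"):
            normalize_transforms(seasonal_fields, "per_location")
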