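"""Continuous Morlet wavelet transforms of site-level monthly series.

The transform uses a sigma-parameterized complex Morlet kernel whose central
frequency is chosen so that the timescale equals the period of maximal
response: for x(t) = cos(2*pi*t/P) the time-averaged response magnitude
peaks at sigma = P, and the phase at sigma = P advances by 2*pi per P
months. Concretely,

    W(t, sigma) = (dt / sigma) * sum_u x(u) * conj(psi((u - t) / sigma)),
    psi(eta)    = pi**(-1/4) * exp(2j*pi*eta) * exp(-eta**2 / 2),

with the kernel truncated at |u - t| <= 4*sigma (no periodic wrap-around; a
validity mask flags coefficients within ``coi_factor * sigma`` of either
series edge, where edge truncation materially distorts them).

The 1/sigma prefactor makes the frequency response flat across timescales
for a fixed-amplitude sinusoid, so the response peak falls exactly at
sigma = P rather than being biased by an L2-normalization sqrt(sigma)
factor.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import signal, stats

from .types import SpatioTemporalSeries, TimescaleGrid, WaveletFieldSet

logger = logging.getLogger("synchwave")

__all__ = [
    "clean_series",
    "interpolate_missing",
    "make_timescale_grid",
    "wavelet_transform",
    "transform_series",
    "normalize_transforms",
    "morlet_kernel",
]

#: kernel support half-width in units of sigma
KERNEL_TRUNCATION = 4.0
#: default cone-of-influence margin, in units of sigma
DEFAULT_COI_FACTOR = 1.0
#: relative variance below which a series counts as constant
_ZERO_VAR_RTOL = 1e-15


# ----------------------------------------------------------------------------
# cleaning
# ----------------------------------------------------------------------------

def clean_series(
    raw: SpatioTemporalSeries,
    detrend: bool = True,
    standardize: bool = True,
    boxcox: bool = False,
) -> SpatioTemporalSeries:
    """Per-site cleaning: optional Box-Cox, linear detrend, standardization.

    The order is fixed (Box-Cox -> detrend -> standardize). Missing values
    are a hard error naming the offending site and month; interpolation is a
    separate, explicit step (:func:`interpolate_missing`), never silent.

    Raises
    ------
    ValueError
        On any non-finite value, on fewer than 24 time steps, or on a
        zero-variance (constant or perfectly linear, when detrending)
        series.
    """
    x = np.array(raw.values, dtype=float)
    labels = raw.time_labels
    bad = ~np.isfinite(x)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"missing value at site {raw.site_ids[i]!r}, month {labels[j]}; "
            "call interpolate_missing() explicitly if interpolation is intended"
        )
    if x.shape[1] < 24:
        raise ValueError(f"need >= 24 monthly values per site, got {x.shape[1]}")

    out = np.empty_like(x)
    for i in range(x.shape[0]):
        xi = x[i]
        scale = max(1.0, float(np.var(xi)))
        if boxcox:
            shifted = xi
            if shifted.min() <= 0:
                span = float(shifted.max() - shifted.min())
                shift = -shifted.min() + (0.01 * span if span > 0 else 1.0)
                shifted = shifted + shift
            xi, _ = stats.boxcox(shifted)
        if detrend:
            xi = signal.detrend(xi, type="linear")
        else:
            xi = xi - xi.mean() if standardize else xi
        if standardize:
            xi = xi - xi.mean()
            v = float(np.var(xi, ddof=1))
            if v <= _ZERO_VAR_RTOL * scale:
                raise ValueError(
                    f"zero-variance series at site {raw.site_ids[i]!r} "
                    "(constant, or exactly linear under detrending)"
                )
            xi = xi / np.sqrt(v)
        out[i] = xi
    cleaned = raw.copy_with(out)
    return cleaned


def interpolate_missing(raw: SpatioTemporalSeries) -> SpatioTemporalSeries:
    """Linearly interpolate interior NaN runs per site (explicit utility).

    Leading/trailing NaNs cannot be interpolated and remain an error.
    """
    x = np.array(raw.values, dtype=float)
    n_filled = 0
    for i in range(x.shape[0]):
        xi = x[i]
        bad = ~np.isfinite(xi)
        if not bad.any():
            continue
        if bad[0] or bad[-1]:
            raise ValueError(
                f"cannot interpolate leading/trailing missing values at site "
                f"{raw.site_ids[i]!r}"
            )
        good = np.flatnonzero(~bad)
        xi[bad] = np.interp(np.flatnonzero(bad), good, xi[good])
        n_filled += int(bad.sum())
    if n_filled:
        logger.info("interpolate_missing: filled %d missing values", n_filled)
    return raw.copy_with(x)


# ----------------------------------------------------------------------------
# timescale grid
# ----------------------------------------------------------------------------

def make_timescale_grid(
    T: int,
    dt: float = 1.0,
    s_min: float = 2.0,
    s_max: Optional[float] = None,
    ratio: float = 1.05,
) -> TimescaleGrid:
    """Log-spaced timescale grid from s_min up to the largest value <= s_max.

    Defaults (s_min = 2 months, s_max = min(72, T*dt), ratio = 1.05) cover
    the 2-8, 8-16 and 16-60 month analysis bands for an 11-year monthly
    record.
    """
    if s_max is None:
        s_max = min(60.0 * 1.2, T * dt)
    if s_min < 2.0 * dt:
        raise ValueError(f"s_min={s_min} is sub-Nyquist (need >= 2*dt = {2 * dt})")
    if s_max > T * dt + 1e-12:
        raise ValueError(f"s_max={s_max} exceeds record length T*dt = {T * dt}")
    if s_max < s_min:
        raise ValueError("s_max must be >= s_min")
    if ratio <= 1.0:
        raise ValueError("ratio must exceed 1")
    n = int(np.floor(np.log(s_max / s_min) / np.log(ratio) + 1e-9)) + 1
    ts = s_min * ratio ** np.arange(n)
    return TimescaleGrid(timescales=ts, s_min=float(s_min), s_max=float(s_max),
                         ratio=float(ratio))


# ----------------------------------------------------------------------------
# transform
# ----------------------------------------------------------------------------

def morlet_kernel(sigma: float, dt: float = 1.0) -> np.ndarray:
    """Sampled, truncated Morlet kernel psi(t/sigma)*dt/sigma on |t|<=4*sigma."""
    half = int(np.ceil(KERNEL_TRUNCATION * sigma / dt))
    t = np.arange(-half, half + 1) * dt
    eta = t / sigma
    psi = np.pi ** -0.25 * np.exp(2j * np.pi * eta) * np.exp(-0.5 * eta ** 2)
    return psi * (dt / sigma)


def _edge_mask(T: int, grid: TimescaleGrid, dt: float, coi_factor: float) -> np.ndarray:
    """Validity mask: True where the coefficient is at least coi_factor*sigma
    from both series edges. Depends only on (T, grid, coi_factor)."""
    i = np.arange(T)[:, None] * dt
    margin = coi_factor * grid.timescales[None, :]
    return (i >= margin - 1e-12) & (i <= (T - 1) * dt - margin + 1e-12)


def wavelet_transform(
    x: np.ndarray,
    grid: TimescaleGrid,
    dt: float = 1.0,
    coi_factor: float = DEFAULT_COI_FACTOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet transform of one (or a stack of) zero-mean series.

    Parameters
    ----------
    x : array, shape (T,) or (n_series, T)
        Cleaned (zero-mean) series. Complex input is accepted (the transform
        is linear), which the fast surrogate machinery exploits.
    grid : TimescaleGrid
    dt, coi_factor : float
        Sampling step and cone-of-influence margin (in units of sigma).

    Returns
    -------
    W : complex array, shape (..., T, S)
    valid_mask : bool array, shape (T, S)
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    single = x.ndim == 1
    X = np.atleast_2d(x)
    T = X.shape[1]
    S = len(grid)
    W = np.empty((X.shape[0], T, S), dtype=complex)
    for k, sigma in enumerate(grid.timescales):
        kern = morlet_kernel(sigma, dt)
        W[:, :, k] = signal.fftconvolve(X, kern[None, :], mode="same", axes=1)
    mask = _edge_mask(T, grid, dt, coi_factor)
    if single:
        return W[0], mask
    return W, mask


def transform_series(
    series: SpatioTemporalSeries,
    grid: Optional[TimescaleGrid] = None,
    coi_factor: float = DEFAULT_COI_FACTOR,
    normalization: Optional[str] = "across_locations",
) -> WaveletFieldSet:
    """Transform all sites of a cleaned series into a WaveletFieldSet."""
    if not series.is_finite():
        raise ValueError("series contains missing values; clean it first")
    if grid is None:
        grid = make_timescale_grid(series.n_months, series.dt)
    W, mask = wavelet_transform(series.values, grid, series.dt, coi_factor)
    fields = WaveletFieldSet(
        coefficients=W,
        grid=grid,
        valid_mask=mask,
        site_ids=series.site_ids,
        normalization="none",
        dt=series.dt,
        coi_factor=coi_factor,
    )
    if normalization is not None:
        fields = normalize_transforms(fields, normalization)
    return fields


# ----------------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------------

def site_power(fields: WaveletFieldSet) -> np.ndarray:
    """Per-site mean |W|^2 over valid times, shape (n_sites, S).

    Timescales whose validity column is empty (the cone of influence covers
    the whole record there) fall back to the all-times mean power; the mask
    already excludes such columns from every downstream statistic, so the
    fallback only keeps their normalization well defined.
    """
    mask = fields.valid_mask
    n_valid = mask.sum(axis=0)
    empty = n_valid == 0
    if empty.any():
        logger.debug(
            "site_power: %d timescales have no valid points; using all-times "
            "power there", int(empty.sum())
        )
    power = np.abs(fields.coefficients) ** 2
    num = np.where(mask[None, :, :], power, 0.0).sum(axis=1)
    out = num / np.where(empty, 1, n_valid)[None, :]
    if empty.any():
        out[:, empty] = power[:, :, empty].mean(axis=1)
    return out


def normalize_transforms(fields: WaveletFieldSet, method: str) -> WaveletFieldSet:
    """Normalize wavelet magnitudes per site or across sites.

    ``per_location`` divides each site's coefficients at each timescale by
    the square root of that site's mean valid-time power at that timescale;
    ``across_locations`` divides by the square root of the across-site mean
    of those powers (so the across-site mean power is exactly 1 at every
    timescale). Renormalizing with the same method is a no-op.
    """
    if method not in ("per_location", "across_locations"):
        raise ValueError(f"unknown normalization method {method!r}")
    if fields.normalization not in ("none", method):
        raise ValueError(
            f"fields already normalized with {fields.normalization!r}; "
            f"cannot apply {method!r}"
        )
    P = site_power(fields)  # (n_sites, S)
    tiny = np.finfo(float).tiny
    if np.any(P <= tiny):
        i, k = np.argwhere(P <= tiny)[0]
        raise ValueError(
            f"zero wavelet power at site {fields.site_ids[i]!r}, "
            f"timescale {fields.grid.timescales[k]:.4g} months"
        )
    if method == "per_location":
        denom = np.sqrt(P)[:, None, :]
    else:
        denom = np.sqrt(P.mean(axis=0))[None, None, :]
    return WaveletFieldSet(
        coefficients=fields.coefficients / denom,
        grid=fields.grid,
        valid_mask=fields.valid_mask,
        site_ids=fields.site_ids,
        normalization=method,
        dt=fields.dt,
        coi_factor=fields.coi_factor,
    )
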