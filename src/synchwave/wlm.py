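"""Multivariate wavelet linear models and synchrony attribution.

At each grid timescale inside the focal band, the response's normalized
wavelet coefficients are regressed (complex least squares, no intercept —
the fields are zero-mean by construction) on the predictors' coefficients,
pooled over sites and valid times:

    minimize sum_{n,t valid} | w~y_n(t,s) - sum_j beta_j(s) w~x_{j,n}(t,s) |^2.

The model-predicted mean field is the across-site average of the fitted
fields. Writing M_j for the mean field of beta_j * w~x_j, the time-averaged
band synchrony of the model decomposes exactly:

    S_mod = sum_j <|M_j|^2> + sum_{j<k} <2 Re(M_j conj(M_k))>,

giving nonnegative per-driver contributions and signed pairwise interaction
terms (positive = synergistic, negative = antagonistic). The fraction of
observed synchrony explained is S_mod / S_obs with S_obs the band-time mean
of |wmf_y|^2; overfit values above 1 are reported raw with a warning.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np

from .types import TimescaleBand, WaveletFieldSet, WlmResult, frac_pi
from .meanfield import phasor_null_threshold, wavelet_phasor_mean_field
from .coherence import spatial_coherence, coherence_test

logger = logging.getLogger("synchwave")

__all__ = [
    "fit_wlm",
    "coefficient_table",
    "predicted_mean_field",
    "synchrony_explained",
    "model_band_phase",
    "wlm_diagnostics",
    "wlm_analysis",
]

_COND_LIMIT = 1e8
_ZERO_COLUMN_TOL = 1e-14


def _check_fields(y_fields: WaveletFieldSet, x_fields: Sequence[WaveletFieldSet]) -> None:
    if len(x_fields) < 1:
        raise ValueError("need at least one predictor field set")
    for f in (y_fields, *x_fields):
        if f.normalization != "across_locations":
            raise ValueError("all fields must be across_locations-normalized")
    for f in x_fields:
        y_fields.compatible_with(f)


def fit_wlm(
    y_fields: WaveletFieldSet,
    x_fields: Sequence[WaveletFieldSet],
    band: TimescaleBand,
    response: str = "y",
    predictors: Optional[Sequence[str]] = None,
    per_timescale: bool = True,
) -> WlmResult:
    """Complex least-squares coefficients per (predictor, band timescale).

    With ``per_timescale=False`` a single coefficient per predictor is
    fitted by pooling all band timescales into one regression.

    Raises
    ------
    ValueError
        When nonzero predictors are collinear at some timescale (condition
        number of the unit-scaled design above 1e8), naming the timescale.
        Predictors with (numerically) zero power get a zero coefficient.
    """
    _check_fields(y_fields, x_fields)
    names = list(predictors) if predictors is not None else [
        f"x{j + 1}" for j in range(len(x_fields))
    ]
    if len(names) != len(x_fields):
        raise ValueError("predictor name count mismatch")
    grid = y_fields.grid
    idx = grid.band_indices(band, y_fields.valid_mask)
    mask = y_fields.valid_mask
    J = len(x_fields)
    coeffs = np.zeros((J, len(idx)), dtype=complex)

    def solve(A: np.ndarray, b: np.ndarray, label: str) -> np.ndarray:
        norms = np.linalg.norm(A, axis=0)
        scale = np.max(norms) if np.max(norms) > 0 else 1.0
        nonzero = norms > _ZERO_COLUMN_TOL * scale
        beta = np.zeros(A.shape[1], dtype=complex)
        if not nonzero.any():
            return beta
        An = A[:, nonzero] / norms[nonzero]
        if An.shape[1] > 1 and np.linalg.cond(An) > _COND_LIMIT:
            raise ValueError(f"collinear predictors at timescale {label}")
        sol, *_ = np.linalg.lstsq(An, b, rcond=None)
        beta[nonzero] = sol / norms[nonzero]
        return beta

    if per_timescale:
        for c, k in enumerate(idx):
            rows = mask[:, k]
            b = y_fields.coefficients[:, rows, k].ravel()
            A = np.stack(
                [f.coefficients[:, rows, k].ravel() for f in x_fields], axis=1
            )
            coeffs[:, c] = solve(A, b, f"{grid.timescales[k]:.4g} months")
    else:
        cols = []
        bs = []
        for k in idx:
            rows = mask[:, k]
            bs.append(y_fields.coefficients[:, rows, k].ravel())
            cols.append(
                np.stack([f.coefficients[:, rows, k].ravel() for f in x_fields], axis=1)
            )
        beta = solve(np.concatenate(cols, axis=0), np.concatenate(bs), band.label)
        coeffs[:] = beta[:, None]

    return WlmResult(
        response=response,
        predictors=names,
        band=band,
        band_idx=idx,
        timescales=grid.timescales[idx],
        coeffs=coeffs,
    )


def _component_fields(
    model: WlmResult, x_fields: Sequence[WaveletFieldSet]
) -> list[np.ndarray]:
    """Per-predictor fitted site fields beta_j(s) * w~x_j, band columns only."""
    return [
        model.coeffs[j][None, None, :] * f.coefficients[:, :, model.band_idx]
        for j, f in enumerate(x_fields)
    ]


def predicted_mean_field(
    model: WlmResult, x_fields: Sequence[WaveletFieldSet]
) -> np.ndarray:
    """Wavelet mean field of the fitted values, shape (T, n_band_timescales)."""
    comps = _component_fields(model, x_fields)
    fitted = np.sum(comps, axis=0)  # (N, T, Sb)
    return fitted.mean(axis=0)


def synchrony_explained(
    model: WlmResult,
    y_fields: WaveletFieldSet,
    x_fields: Sequence[WaveletFieldSet],
) -> WlmResult:
    """Wavelet Moran decomposition: fraction explained + attribution terms.

    Fills ``sync_explained``, ``contributions`` (per predictor, >= 0),
    ``crossterms`` (signed, per unordered predictor pair) and
    ``predicted_wmf`` on the model and returns it. The identity
    S_mod = sum(contributions) + sum(crossterms) is exact.
    """
    mask = y_fields.valid_mask[:, model.band_idx]
    n_valid = mask.sum()

    def band_time_mean(field2d: np.ndarray) -> float:
        return float(np.where(mask, field2d, 0.0).sum() / n_valid)

    wmf_y = y_fields.coefficients[:, :, model.band_idx].mean(axis=0)
    S_obs = band_time_mean(np.abs(wmf_y) ** 2)
    if S_obs < 1e-12:
        raise ValueError("observed band synchrony is ~0; nothing to explain")

    comps = _component_fields(model, x_fields)
    M = [c.mean(axis=0) for c in comps]  # per-predictor mean fields (T, Sb)
    model.predicted_wmf = np.sum(M, axis=0)
    S_mod = band_time_mean(np.abs(model.predicted_wmf) ** 2)

    names = model.predictors
    contributions = {names[j]: band_time_mean(np.abs(M[j]) ** 2) for j in range(len(M))}
    crossterms = {}
    for j in range(len(M)):
        for k in range(j + 1, len(M)):
            crossterms[f"{names[j]}*{names[k]}"] = band_time_mean(
                2.0 * np.real(M[j] * np.conj(M[k]))
            )
    model.sync_explained = S_mod / S_obs
    if model.sync_explained > 1.0 + 1e-9:
        logger.warning(
            "sync_explained = %.3f exceeds 1 (overfit); reported raw",
            model.sync_explained,
        )
    model.contributions = contributions
    model.crossterms = crossterms
    return model


def model_band_phase(
    model: WlmResult,
    predictor: str,
    y_fields: WaveletFieldSet,
    x_fields: Sequence[WaveletFieldSet],
    method: str = "crossprod",
) -> float:
    """Band phase of the response-predictor relationship, in fractions of pi.

    ``crossprod`` (default): the argument of the band-time mean of
    conj(w~x_j) * w~y — the cross-spectral phase between the predictor and
    the response, with the same sign convention as spatial coherence
    (negative, non-in/anti-phase => response lags the driver).

    ``coefficient``: the argument of the predictor-power-weighted band
    average of beta_j(s); in a multi-predictor model this is the phase of
    the predictor's fitted component relative to the predictor itself.
    """
    j = model.predictors.index(predictor)
    if np.max(np.abs(model.coeffs[j])) < 1e-12:
        raise ValueError(f"phase undefined: coefficient of {predictor!r} is ~0 "
                         "at all band timescales")
    mask = y_fields.valid_mask[:, model.band_idx]
    xj = x_fields[j].coefficients[:, :, model.band_idx]
    if method == "crossprod":
        cross = np.conj(xj) * y_fields.coefficients[:, :, model.band_idx]
        z = complex(np.where(mask[None], cross, 0.0).sum())
    elif method == "coefficient":
        P = np.where(mask[None], np.abs(xj) ** 2, 0.0).sum(axis=(0, 1))  # (Sb,)
        z = complex((model.coeffs[j] * P).sum())
    else:
        raise ValueError(f"unknown phase method {method!r}")
    return frac_pi(z)


def wlm_diagnostics(
    model: WlmResult,
    y_fields: WaveletFieldSet,
    x_series: Optional[Sequence] = None,
    x_fields: Optional[Sequence[WaveletFieldSet]] = None,
    alpha: float = 0.05,
    n_surr: int = 1000,
    n_rand: int = 1000,
    seed: Union[int, np.random.Generator, None] = None,
) -> dict:
    """Model-assumption diagnostics on the residual fields.

    Reports (a) a per-timescale R^2 analog 1 - sum|resid|^2 / sum|w~y|^2,
    (b) the fraction of valid band cells where the residual phasor mean
    field exceeds the random-phasor threshold (should be near alpha under a
    well-specified model), and (c), when the predictor *series* are
    supplied, a surrogate coherence test of each predictor against the
    residual field (should be non-significant).
    """
    if x_fields is None:
        raise ValueError("x_fields is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = y_fields.valid_mask[:, model.band_idx]
    yb = y_fields.coefficients[:, :, model.band_idx]
    fitted = np.sum(_component_fields(model, x_fields), axis=0)
    resid = yb - fitted  # (N, T, Sb)

    tot = np.where(mask[None], np.abs(yb) ** 2, 0.0).sum(axis=(0, 1))
    rss = np.where(mask[None], np.abs(resid) ** 2, 0.0).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - rss / tot

    diagnostics: dict = {
        "timescales": [float(s) for s in model.timescales],
        "r2_per_timescale": [float(v) for v in r2],
    }

    # residual phase synchrony
    resid_power = float(rss.sum())
    if resid_power < 1e-20:
        diagnostics["residual_wpmf_exceedance"] = 0.0
        diagnostics["residual_coherence"] = None
        return diagnostics

    band_grid = _band_grid(y_fields, model)
    resid_fields = WaveletFieldSet(
        resid, band_grid, mask, y_fields.site_ids, "none",
        y_fields.dt, y_fields.coi_factor,
    )
    wpmf = wavelet_phasor_mean_field(resid_fields)
    thr = phasor_null_threshold(y_fields.n_sites, alpha, n_rand, rng)
    with np.errstate(invalid="ignore"):
        diagnostics["residual_wpmf_exceedance"] = float(
            np.where(mask, wpmf > thr, False).sum() / mask.sum()
        )

    if x_series is not None:
        from .wavelet import normalize_transforms

        resid_norm = normalize_transforms(resid_fields, "across_locations")
        rescoh = {}
        for name, series in zip(model.predictors, x_series):
            res = coherence_test(
                series, resid_norm, model.band, grid=band_grid,
                n_surr=n_surr, method="fast", seed=rng,
                coi_factor=y_fields.coi_factor,
                x_name=name, y_name="residuals",
            )
            rescoh[name] = {"magnitude": res.magnitude, "p_value": res.p_value}
        diagnostics["residual_coherence"] = rescoh
    else:
        diagnostics["residual_coherence"] = None
    return diagnostics


def _band_grid(y_fields: WaveletFieldSet, model: WlmResult):
    from .types import TimescaleGrid

    ts = model.timescales
    return TimescaleGrid(ts, float(ts[0]), float(ts[-1]), y_fields.grid.ratio)


def coefficient_table(model: WlmResult):
    """Per-timescale coefficient table (modulus, phase in fractions of pi,
    real/imaginary parts) as a pandas DataFrame, one row per band timescale."""
    import pandas as pd

    data = {"timescale_months": model.timescales}
    for j, name in enumerate(model.predictors):
        bj = model.coeffs[j]
        data[f"{name}_modulus"] = np.abs(bj)
        data[f"{name}_phase_frac_pi"] = np.array([frac_pi(z) for z in bj])
        data[f"{name}_re"] = bj.real
        data[f"{name}_im"] = bj.imag
    return pd.DataFrame(data)


def wlm_analysis(
    y_fields: WaveletFieldSet,
    x_fields: Sequence[WaveletFieldSet],
    band: TimescaleBand,
    response: str = "y",
    predictors: Optional[Sequence[str]] = None,
    per_timescale: bool = True,
) -> WlmResult:
    """Fit, decompose, and attach both phase variants in one call."""
    model = fit_wlm(y_fields, x_fields, band, response, predictors, per_timescale)
    model = synchrony_explained(model, y_fields, x_fields)
    model.phases = {}
    model.coefficient_phases = {}
    for name in model.predictors:
        try:
            model.phases[name] = model_band_phase(
                model, name, y_fields, x_fields, method="crossprod"
            )
            model.coefficient_phases[name] = model_band_phase(
                model, name, y_fields, x_fields, method="coefficient"
            )
        except ValueError:
            logger.warning("phase undefined for predictor %r", name)
    return model
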