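"""Core containers for site-by-month data and wavelet fields.

All analyses operate on a small number of shared containers: a
:class:`SpatioTemporalSeries` (N sites observed on a common, gapless monthly
time index), a log-spaced :class:`TimescaleGrid`, and a
:class:`WaveletFieldSet` holding the per-site complex Morlet transforms with
an edge-validity mask. Result objects for the mean-field, coherence and
wavelet-linear-model stages live here too so that every module exchanges the
same types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatioTemporalSeries",
    "TimescaleGrid",
    "TimescaleBand",
    "WaveletFieldSet",
    "MeanFieldResult",
    "CoherenceResult",
    "WlmResult",
    "ScreeningTable",
]


def frac_pi(z: complex) -> float:
    """Argument of z in fractions of pi, mapped to (-1, 1].

    Values within 1e-9 of -1 (an argument numerically at -pi) map to +1,
    the anti-phase representative of the convention.
    """
    phi = float(np.angle(z) / np.pi)
    if phi <= -1.0 + 1e-9:
        phi = 1.0
    return phi


def month_labels(t0: str, n: int) -> list[str]:
    """ISO year-month labels for ``n`` consecutive months starting at ``t0``."""
    return [str(p) for p in pd.period_range(t0, periods=n, freq="M")]


@dataclass
class SpatioTemporalSeries:
    """An N-site x T-month real matrix on one common monthly time index.

    Raw inputs may contain NaN missing markers; analysis stages require the
    matrix to be cleaned first (see :func:`synchwave.wavelet.clean_series`).
    """

    values: np.ndarray
    site_ids: Sequence[str]
    t0: str = "2009-01"
    dt: float = 1.0
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (site x month) matrix")
        self.site_ids = list(self.site_ids)
        if len(self.site_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.site_ids)} site ids for {self.values.shape[0]} rows"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids")
        if self.values.shape[1] < 1:
            raise ValueError("need at least 1 monthly time step")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_months(self) -> int:
        return self.values.shape[1]

    @property
    def time_labels(self) -> list[str]:
        return month_labels(self.t0, self.n_months)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def copy_with(self, values: np.ndarray, t0: Optional[str] = None) -> "SpatioTemporalSeries":
        return SpatioTemporalSeries(
            values=np.array(values, dtype=float),
            site_ids=list(self.site_ids),
            t0=self.t0 if t0 is None else t0,
            dt=self.dt,
            units=self.units,
        )


@dataclass
class TimescaleGrid:
    """Log-uniformly spaced timescales (months): s[k+1]/s[k] = ratio."""

    timescales: np.ndarray
    s_min: float
    s_max: float
    ratio: float

    def __post_init__(self) -> None:
        self.timescales = np.asarray(self.timescales, dtype=float)
        if self.timescales.ndim != 1 or len(self.timescales) == 0:
            raise ValueError("timescales must be a non-empty 1-D array")
        if np.any(self.timescales <= 0) or np.any(np.diff(self.timescales) <= 0):
            raise ValueError("timescales must be strictly increasing and positive")

    def __len__(self) -> int:
        return len(self.timescales)

    def band_indices(
        self, band: "TimescaleBand", valid_mask: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Indices of grid timescales with lo <= sigma <= hi (inclusive).

        When a validity mask (T, S) is given, timescales whose validity
        column is empty — the cone of influence covers the whole record
        there — are excluded, since no band statistic can use them.
        """
        idx = np.flatnonzero(
            (self.timescales >= band.lo - 1e-12) & (self.timescales <= band.hi + 1e-12)
        )
        if len(idx) == 0:
            raise ValueError(f"band [{band.lo}, {band.hi}] contains no grid timescales")
        if valid_mask is not None:
            idx = idx[valid_mask[:, idx].any(axis=0)]
            if len(idx) == 0:
                raise ValueError(
                    f"band [{band.lo}, {band.hi}] lies entirely inside the "
                    "cone of influence for this record length"
                )
        return idx


@dataclass(frozen=True)
class TimescaleBand:
    """A contiguous range of timescales in months; membership lo <= sigma <= hi."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("require 0 < lo < hi")

    @property
    def label(self) -> str:
        return f"{self.lo:g}-{self.hi:g}"


@dataclass
class WaveletFieldSet:
    """Per-site complex Morlet transforms over (month x timescale).

    ``coefficients`` has shape (n_sites, T, S); ``valid_mask`` (T, S) marks
    coefficients unaffected by the series edges and is identical across sites
    (it depends only on T, the grid, and the cone-of-influence factor).
    ``normalization`` is one of ``none``, ``per_location``,
    ``across_locations``.
    """

    coefficients: np.ndarray
    grid: TimescaleGrid
    valid_mask: np.ndarray
    site_ids: Sequence[str]
    normalization: str = "none"
    dt: float = 1.0
    coi_factor: float = 1.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must be (n_sites, T, S)")
        n, T, S = self.coefficients.shape
        if self.valid_mask.shape != (T, S):
            raise ValueError("valid_mask shape must be (T, S)")
        if S != len(self.grid):
            raise ValueError("coefficient timescale axis does not match grid")
        self.site_ids = list(self.site_ids)
        if len(self.site_ids) != n:
            raise ValueError("site_ids length mismatch")
        if self.normalization not in ("none", "per_location", "across_locations"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def n_sites(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_months(self) -> int:
        return self.coefficients.shape[1]

    def compatible_with(self, other: "WaveletFieldSet") -> None:
        """Raise if the two field sets cannot enter a cross-variable statistic."""
        if list(self.site_ids) != list(other.site_ids):
            raise ValueError("site sets differ between field sets")
        if self.coefficients.shape != other.coefficients.shape:
            raise ValueError("field shapes differ")
        if not np.allclose(self.grid.timescales, other.grid.timescales):
            raise ValueError("timescale grids differ")
        if not np.array_equal(self.valid_mask, other.valid_mask):
            raise ValueError("valid masks differ")


@dataclass
class MeanFieldResult:
    """Wavelet mean field + phasor mean field with a random-phasor threshold."""

    wmf: np.ndarray
    wpmf_magnitude: np.ndarray
    threshold: float
    sig_mask: np.ndarray
    valid_mask: np.ndarray
    n_sites: int
    n_rand: int
    alpha: float
    timescales: np.ndarray
    time_labels: list[str] = field(default_factory=list)


@dataclass
class CoherenceResult:
    """Band-aggregated spatial wavelet coherence between two variables.

    ``phi`` is the phase of the band coherence in fractions of pi, in
    (-1, 1]; negative (and not in/anti-phase) means the response variable
    (y) lags the driver (x).
    """

    per_timescale: np.ndarray
    timescales: np.ndarray
    band: TimescaleBand
    band_coherence: complex
    magnitude: float
    phi: float
    p_value: Optional[float] = None
    n_surr: int = 0
    surr_type: str = "fourier"
    x_name: str = "x"
    y_name: str = "y"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "variables": [self.x_name, self.y_name],
            "band": [self.band.lo, self.band.hi],
            "magnitude": float(self.magnitude),
            "phi_fractions_of_pi": float(self.phi),
            "p_value": None if self.p_value is None else float(self.p_value),
            "n_surr": int(self.n_surr),
            "surr_type": self.surr_type,
            "seed": self.seed,
        }


@dataclass
class WlmResult:
    """A fitted multivariate wavelet linear model on one timescale band."""

    response: str
    predictors: list[str]
    band: TimescaleBand
    band_idx: np.ndarray
    timescales: np.ndarray            # band timescales (months)
    coeffs: np.ndarray                # (n_predictors, n_band_timescales) complex
    predicted_wmf: Optional[np.ndarray] = None   # (T, n_band_timescales)
    sync_explained: Optional[float] = None
    contributions: Optional[dict] = None
    crossterms: Optional[dict] = None
    phases: Optional[dict] = None
    coefficient_phases: Optional[dict] = None
    diagnostics: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "response": self.response,
            "predictors": list(self.predictors),
            "band": [self.band.lo, self.band.hi],
            "sync_explained": _opt_float(self.sync_explained),
            "contributions": _opt_map(self.contributions),
            "crossterms": _opt_map(self.crossterms),
            "phases": _opt_map(self.phases),
            "coefficient_phases": _opt_map(self.coefficient_phases),
            "diagnostics": self.diagnostics,
        }
        return out


def _opt_float(x):
    return None if x is None else float(x)


def _opt_map(d):
    if d is None:
        return None
    return {str(k): float(v) for k, v in d.items()}


@dataclass
class ScreeningTable:
    """Per-(driver, band) coherence screening for model construction.

    A driver is selected when its surrogate p-value is below ``alpha_screen``
    (0.1 by default); when both the local and regional kelp candidates pass
    in one band, only the one with the smaller p-value is kept.
    """

    rows: list[dict]
    alpha_screen: float
    n_tests: int
    n_significant_005: int

    def selected(self, band: TimescaleBand) -> list[str]:
        lab = band.label
        return [r["driver"] for r in self.rows if r["band"] == lab and r["selected"]]

    def to_dict(self) -> dict:
        return {
            "alpha_screen": float(self.alpha_screen),
            "n_tests": int(self.n_tests),
            "n_significant_005": int(self.n_significant_005),
            "rows": self.rows,
        }
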