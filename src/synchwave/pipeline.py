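"""End-to-end analysis of the kelp -> wrack -> shorebird synchrony cascade.

Stages: aggregate raw survey tables to site-by-month matrices (transect
means for wrack, species totals for shorebirds, monthly means of daily
maximum wave heights), first-difference the wave series, align and clean
all variables, then (1) wrack mean fields with significance contours,
(2) per-band coherence screening of candidate drivers, (3) per-band
multivariate wavelet linear models of wrack with synchrony attribution,
(4) shorebird mean fields, (5) shorebird-wrack coherence, and (6) shorebird
models with wrack and air temperature as predictors, caution-flagged in
bands where wrack-bird coherence is not significant. Every random stage is
seeded from one master seed, so a report is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    MeanFieldResult,
    ScreeningTable,
    SpatioTemporalSeries,
    TimescaleBand,
    WaveletFieldSet,
)
from .wavelet import clean_series, make_timescale_grid, transform_series
from .meanfield import mean_field_analysis
from .coherence import coherence_test
from .wlm import wlm_analysis, wlm_diagnostics

logger = logging.getLogger("synchwave")

__all__ = [
    "DEFAULT_SHOREBIRD_SPECIES",
    "CascadeConfig",
    "CascadeReport",
    "mean_over_transects",
    "total_over_species",
    "monthly_mean_of_daily_max",
    "first_difference",
    "preprocess_variables",
    "screen_drivers",
    "classify_phase",
    "run_cascade",
]

#: aggregate shorebird taxa counted in the monthly beach surveys
DEFAULT_SHOREBIRD_SPECIES = (
    "American Avocet", "Baird's Sandpiper", "Black-bellied Plover",
    "Black-necked Stilt", "Black Turnstone", "Dowitcher spp.", "Dunlin",
    "Greater Yellowlegs", "Killdeer", "Least Sandpiper", "Lesser Yellowlegs",
    "Long-billed Curlew", "Long-billed Dowitcher", "Marbled Godwit",
    "Pectoral Sandpiper", "Red-necked Phalarope", "Red Knot",
    "Ruddy Turnstone", "Sanderling", "Semipalmated Plover",
    "Short-billed Dowitcher", "Snowy Plover", "Spotted Sandpiper", "Surfbird",
    "Wandering Tattler", "Western Sandpiper", "Whimbrel", "Willet",
    "Wilson's Plover",
)

DEFAULT_BANDS = (TimescaleBand(2, 8), TimescaleBand(8, 16), TimescaleBand(16, 60))

WRACK_DRIVERS = ("kelp_local", "kelp_regional", "waves", "width")
_KELP_PAIR = ("kelp_local", "kelp_regional")


# ----------------------------------------------------------------------------
# aggregation of raw survey tables
# ----------------------------------------------------------------------------

def _pivot(
    df: pd.DataFrame, aggfunc: str, value_col: str = "value"
) -> SpatioTemporalSeries:
    """Long (site, month, value) table -> wide site-by-month series."""
    piv = df.pivot_table(index="site", columns="month", values=value_col,
                         aggfunc=aggfunc)
    months = pd.PeriodIndex(piv.columns, freq="M").sort_values()
    expected = pd.period_range(months[0], months[-1], freq="M")
    missing = expected.difference(months)
    if len(missing):
        raise ValueError(f"month gap in table: missing {missing[0]}")
    piv = piv.reindex(columns=[str(m) for m in expected])
    return SpatioTemporalSeries(
        values=piv.to_numpy(dtype=float),
        site_ids=[str(s) for s in piv.index],
        t0=str(expected[0]),
    )


def mean_over_transects(df: pd.DataFrame) -> SpatioTemporalSeries:
    """Across-transect mean of wrack cover per site and monthly survey."""
    return _pivot(df, "mean")


def total_over_species(
    df: pd.DataFrame,
    species: Sequence[str] = DEFAULT_SHOREBIRD_SPECIES,
) -> SpatioTemporalSeries:
    """Total abundance over all configured shorebird species.

    Counts for species not in the configured list are excluded with a
    warning (never silently).
    """
    known = set(species)
    unknown = sorted(set(df["species"]) - known)
    if unknown:
        logger.warning(
            "total_over_species: excluding %d species not in the configured "
            "shorebird list: %s", len(unknown), ", ".join(unknown)
        )
        df = df[df["species"].isin(known)]
    return _pivot(df, "sum")


def monthly_mean_of_daily_max(df: pd.DataFrame) -> SpatioTemporalSeries:
    """Monthly mean of daily maximum significant wave heights per site."""
    return _pivot(df, "mean")


def first_difference(x: SpatioTemporalSeries) -> SpatioTemporalSeries:
    """Per-site first difference, indexed at the later month.

    The output has T-1 columns starting one month after the input's t0;
    positive values correspond to periods of increasing wave action into
    the current month.
    """
    if x.n_months < 2:
        raise ValueError("first difference needs at least 2 months")
    d = np.diff(x.values, axis=1)
    t0 = str(pd.Period(x.t0, freq="M") + 1)
    return x.copy_with(d, t0=t0)


# ----------------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------------

@dataclass
class CascadeConfig:
    """Knobs of the full cascade analysis (all stages seeded)."""

    bands: Sequence[TimescaleBand] = DEFAULT_BANDS
    alpha_screen: float = 0.1     # driver-selection threshold (P < 0.1)
    alpha_sig: float = 0.05      # contour / coherence significance
    n_surr: int = 10000
    n_rand: int = 1000
    coi_factor: float = 1.0
    s_min: float = 2.0
    s_max: Optional[float] = None
    ratio: float = 1.05
    surr_type: str = "fourier"
    method: str = "fast"
    boxcox: bool = False
    run_diagnostics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.bands = tuple(
            b if isinstance(b, TimescaleBand) else TimescaleBand(*b)
            for b in self.bands
        )


# ----------------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------------

def preprocess_variables(
    raw: dict,
    config: Optional[CascadeConfig] = None,
    shorebird_species: Sequence[str] = DEFAULT_SHOREBIRD_SPECIES,
) -> dict[str, SpatioTemporalSeries]:
    """Aggregate, first-difference waves, align and clean all variables.

    ``raw`` maps variable names to either site-by-month
    :class:`SpatioTemporalSeries` or long-format DataFrames (columns
    ``site, month, value`` — plus ``species`` for birds). The wave series is
    first-differenced, and because that shortens it by one month, all other
    variables are trimmed to months 2..T so every cleaned variable shares
    the same T-1 index. Cleaning = (optional Box-Cox), linear detrend,
    standardization, per site.
    """
    config = config or CascadeConfig()
    agg: dict[str, SpatioTemporalSeries] = {}
    for name, v in raw.items():
        if isinstance(v, pd.DataFrame):
            if name == "birds":
                v = total_over_species(v, shorebird_species)
            elif name == "waves":
                v = monthly_mean_of_daily_max(v)
            else:
                v = mean_over_transects(v)
        agg[name] = v

    if "waves" in agg:
        agg["waves"] = first_difference(agg["waves"])
        for name in agg:
            if name != "waves":
                s = agg[name]
                agg[name] = s.copy_with(
                    s.values[:, 1:], t0=str(pd.Period(s.t0, freq="M") + 1)
                )
    T = {name: s.n_months for name, s in agg.items()}
    if len(set(T.values())) > 1:
        raise ValueError(f"variables disagree on record length: {T}")
    return {
        name: clean_series(s, detrend=True, standardize=True, boxcox=config.boxcox)
        for name, s in agg.items()
    }


# ----------------------------------------------------------------------------
# screening and phase classification
# ----------------------------------------------------------------------------

def screen_drivers(
    response: SpatioTemporalSeries,
    candidates: dict[str, SpatioTemporalSeries],
    bands: Sequence[TimescaleBand] = DEFAULT_BANDS,
    alpha_screen: float = 0.1,
    n_surr: int = 10000,
    seed: Union[int, np.random.SeedSequence, None] = 0,
    config: Optional[CascadeConfig] = None,
) -> ScreeningTable:
    """Coherence-screen candidate drivers of a response, per band.

    A driver is selected when its surrogate p-value is below
    ``alpha_screen``; when both kelp-scale candidates pass in one band only
    the one with the smaller p-value is kept. Rejections at 0.05 are
    tallied for the multiple-testing summary.
    """
    config = config or CascadeConfig(n_surr=n_surr, alpha_screen=alpha_screen)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    grid = make_timescale_grid(response.n_months, response.dt,
                               config.s_min, config.s_max, config.ratio)
    y_fields = transform_series(response, grid, config.coi_factor, "across_locations")

    rows = []
    n_sig = 0
    children = ss.spawn(len(candidates) * len(bands))
    i = 0
    for name, series in candidates.items():
        for band in bands:
            res = coherence_test(
                series, y_fields, band, grid=grid, n_surr=n_surr,
                surr_type=config.surr_type, method=config.method,
                seed=np.random.default_rng(children[i]),
                coi_factor=config.coi_factor,
                x_name=name, y_name="response",
            )
            i += 1
            passed = res.p_value < alpha_screen
            n_sig += res.p_value < 0.05
            rows.append({
                "driver": name,
                "band": band.label,
                "p_value": res.p_value,
                "phi": res.phi,
                "magnitude": res.magnitude,
                "selected": bool(passed),
                "reason": "P<%.2g" % alpha_screen if passed else "not coherent",
            })

    # kelp-scale tiebreak: keep only the lower-P scale per band
    for band in bands:
        kelp_rows = [
            r for r in rows
            if r["band"] == band.label and r["driver"] in _KELP_PAIR and r["selected"]
        ]
        if len(kelp_rows) == 2:
            drop = max(kelp_rows, key=lambda r: (r["p_value"], r["driver"] == "kelp_local"))
            drop["selected"] = False
            drop["reason"] = "kelp scale with larger P dropped"
    return ScreeningTable(
        rows=rows,
        alpha_screen=alpha_screen,
        n_tests=len(candidates) * len(bands),
        n_significant_005=int(n_sig),
    )


def classify_phase(
    phi: float, response_role: str = "response", driver_role: str = "driver"
) -> str:
    """Interpret a band phase (fractions of pi) as a lag/lead/phase label.

    In-phase is the open interval -0.25 < phi < 0.25; anti-phase is
    phi < -0.75 or phi > 0.75. Otherwise a negative phi means the response
    lags the driver and a positive phi means the response leads (its peaks
    precede the driver's). Boundary values (|phi| exactly 0.25 or 0.75)
    fall in the lag/lead categories, reading the in-/anti-phase thresholds
    as strict inequalities.
    """
    if not -1.0 < phi <= 1.0 + 1e-12:
        raise ValueError("phi must lie in (-1, 1]")
    if -0.25 < phi < 0.25:
        return "in-phase"
    if phi < -0.75 or phi > 0.75:
        return "anti-phase"
    if phi < 0:
        return f"{response_role}-lags-{driver_role}"
    return f"{response_role}-leads-{driver_role}"


# ----------------------------------------------------------------------------
# the full cascade
# ----------------------------------------------------------------------------

@dataclass
class CascadeReport:
    """Structured output of :func:`run_cascade` (arrays live on the result
    objects; :func:`to_dict` yields the scalar JSON-serializable view)."""

    wrack_meanfields: MeanFieldResult
    wrack_screening: ScreeningTable
    wrack_models: dict
    bird_meanfields: MeanFieldResult
    bird_coherence: dict
    bird_models: dict
    significance_summary: dict
    config: CascadeConfig
    fields: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        def mf_summary(mf: MeanFieldResult) -> dict:
            valid = mf.valid_mask
            return {
                "n_sites": int(mf.n_sites),
                "alpha": float(mf.alpha),
                "n_rand": int(mf.n_rand),
                "threshold": float(mf.threshold),
                "frac_significant": float(mf.sig_mask.sum() / valid.sum()),
                "mean_wmf_sq_valid": float(
                    np.where(valid, np.abs(mf.wmf) ** 2, 0.0).sum() / valid.sum()
                ),
            }

        return {
            "schema_version": 1,
            "config": {
                "bands": [[b.lo, b.hi] for b in self.config.bands],
                "alpha_screen": self.config.alpha_screen,
                "alpha_sig": self.config.alpha_sig,
                "n_surr": self.config.n_surr,
                "n_rand": self.config.n_rand,
                "coi_factor": self.config.coi_factor,
                "seed": self.config.seed,
                "surr_type": self.config.surr_type,
                "method": self.config.method,
            },
            "wrack_meanfields": mf_summary(self.wrack_meanfields),
            "wrack_screening": self.wrack_screening.to_dict(),
            "wrack_models": {
                k: (None if v is None else v.to_dict())
                for k, v in self.wrack_models.items()
            },
            "bird_meanfields": mf_summary(self.bird_meanfields),
            "bird_coherence": {k: v.to_dict() for k, v in self.bird_coherence.items()},
            "bird_models": {
                k: (None if v is None else dict(v["model"].to_dict(),
                                                caution=v["caution"]))
                for k, v in self.bird_models.items()
            },
            "significance_summary": self.significance_summary,
        }


def run_cascade(
    variables: dict,
    config: Optional[CascadeConfig] = None,
) -> CascadeReport:
    """Run the whole analysis on raw variables (see module docstring).

    ``variables`` must contain wrack, kelp_local, kelp_regional, waves
    (undifferenced), width, temp and birds, each a site-by-month series or
    long DataFrame. Deterministic given ``config.seed``.
    """
    config = config or CascadeConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(6)

    required = {"wrack", "kelp_local", "kelp_regional", "waves", "width",
                "temp", "birds"}
    missing = required - set(variables)
    if missing:
        raise ValueError(f"missing variables: {sorted(missing)}")

    cleaned = preprocess_variables(variables, config)
    wrack = cleaned["wrack"]
    grid = make_timescale_grid(wrack.n_months, wrack.dt,
                               config.s_min, config.s_max, config.ratio)
    fields = {
        name: transform_series(s, grid, config.coi_factor, "across_locations")
        for name, s in cleaned.items()
    }

    # (1) wrack mean fields + significance contours
    wrack_mf = mean_field_analysis(
        fields["wrack"], config.alpha_sig, config.n_rand,
        np.random.default_rng(seeds[0]),
    )

    # (2) driver screening
    screening = screen_drivers(
        wrack,
        {d: cleaned[d] for d in WRACK_DRIVERS},
        config.bands, config.alpha_screen, config.n_surr,
        seed=seeds[1], config=config,
    )

    # (3) per-band wrack models
    diag_rng = np.random.default_rng(seeds[2])
    wrack_models: dict = {}
    for band in config.bands:
        chosen = screening.selected(band)
        if not chosen:
            logger.warning("band %s: no coherent driver; band left model-free",
                           band.label)
            wrack_models[band.label] = None
            continue
        model = wlm_analysis(
            fields["wrack"], [fields[d] for d in chosen], band,
            response="wrack", predictors=chosen,
        )
        if config.run_diagnostics:
            model.diagnostics = wlm_diagnostics(
                model, fields["wrack"],
                x_series=[cleaned[d] for d in chosen],
                x_fields=[fields[d] for d in chosen],
                alpha=config.alpha_sig, n_surr=max(199, config.n_surr // 10),
                n_rand=config.n_rand, seed=diag_rng,
            )
        wrack_models[band.label] = model

    # (4) bird mean fields
    bird_mf = mean_field_analysis(
        fields["birds"], config.alpha_sig, config.n_rand,
        np.random.default_rng(seeds[3]),
    )

    # (5) bird-wrack coherence per band
    coh_seeds = seeds[4].spawn(len(config.bands))
    bird_coh: dict = {}
    for band, s in zip(config.bands, coh_seeds):
        bird_coh[band.label] = coherence_test(
            wrack, fields["birds"], band, grid=grid, n_surr=config.n_surr,
            surr_type=config.surr_type, method=config.method,
            seed=np.random.default_rng(s), coi_factor=config.coi_factor,
            x_name="wrack", y_name="birds",
        )

    # (6) bird models (wrack + air temperature), caution-flagged
    bird_models: dict = {}
    bdiag_rng = np.random.default_rng(seeds[5])
    for band in config.bands:
        model = wlm_analysis(
            fields["birds"], [fields["wrack"], fields["temp"]], band,
            response="birds", predictors=["wrack", "temp"],
        )
        caution = bird_coh[band.label].p_value >= config.alpha_sig
        if config.run_diagnostics:
            model.diagnostics = wlm_diagnostics(
                model, fields["birds"],
                x_series=[cleaned["wrack"], cleaned["temp"]],
                x_fields=[fields["wrack"], fields["temp"]],
                alpha=config.alpha_sig, n_surr=max(199, config.n_surr // 10),
                n_rand=config.n_rand, seed=bdiag_rng,
            )
        bird_models[band.label] = {"model": model, "caution": bool(caution)}

    summary = {
        "wrack_screening_tests": screening.n_tests,
        "wrack_screening_significant_005": screening.n_significant_005,
        "bird_coherence_tests": len(config.bands),
        "bird_coherence_significant_005": int(
            sum(c.p_value < 0.05 for c in bird_coh.values())
        ),
    }
    return CascadeReport(
        wrack_meanfields=wrack_mf,
        wrack_screening=screening,
        wrack_models=wrack_models,
        bird_meanfields=bird_mf,
        bird_coherence=bird_coh,
        bird_models=bird_models,
        significance_summary=summary,
        config=config,
        fields=fields,
    )
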