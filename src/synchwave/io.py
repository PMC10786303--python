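"""Strict CSV readers/writers, YAML run configuration, report serialization.

The primary on-disk layout is a wide CSV per variable: a ``site`` column
followed by ISO year-month columns (one file per variable, sites as rows),
matching the N << T shape of these data. A long-format converter is
provided. Reports are written as a versioned JSON file of scalar results
plus CSV matrices for the wavelet fields, with a manifest of content
hashes for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import MeanFieldResult, SpatioTemporalSeries

logger = logging.getLogger("synchwave")

__all__ = [
    "read_site_matrix",
    "write_site_matrix",
    "long_to_wide",
    "RunConfig",
    "write_report",
    "read_report",
]


def read_site_matrix(
    path: Union[str, Path],
    expected_sites: Optional[Sequence[str]] = None,
) -> SpatioTemporalSeries:
    """Read a wide site-by-month CSV, validating the monthly time index.

    The first column must be ``site``; remaining column headers must be
    consecutive ISO year-months. Errors name the offending row/column.
    Sites are reordered to ``expected_sites`` when given (logged).
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "site":
        raise ValueError(f"{path}: first column must be 'site', got {df.columns[0]!r}")
    sites = df["site"].tolist()
    dupes = {s for s in sites if sites.count(s) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate site rows: {sorted(dupes)}")
    try:
        months = pd.PeriodIndex(df.columns[1:], freq="M")
    except Exception as exc:
        raise ValueError(f"{path}: month columns must be ISO year-months: {exc}")
    expected = pd.period_range(months[0], months[-1], freq="M")
    if len(months) != len(expected) or (months != expected).any():
        missing = expected.difference(months)
        if len(missing):
            raise ValueError(f"{path}: missing month column {missing[0]}")
        raise ValueError(f"{path}: month columns out of order or duplicated")
    vals = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    raw = df.iloc[:, 1:]
    bad = vals.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at site {sites[i]!r}, month {df.columns[1 + j]}"
        )
    series = SpatioTemporalSeries(
        values=vals.to_numpy(dtype=float),
        site_ids=sites,
        t0=str(months[0]),
    )
    if expected_sites is not None:
        expected_sites = list(expected_sites)
        if set(expected_sites) != set(sites):
            raise ValueError(
                f"{path}: site set {sorted(sites)} does not match configured "
                f"{sorted(expected_sites)}"
            )
        if expected_sites != sites:
            logger.info("%s: reordering sites to configured order", path)
            order = [sites.index(s) for s in expected_sites]
            series = SpatioTemporalSeries(
                series.values[order], expected_sites, series.t0,
                series.dt, series.units,
            )
    return series


def write_site_matrix(series: SpatioTemporalSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame(series.values, index=pd.Index(series.site_ids, name="site"),
                      columns=series.time_labels)
    df.to_csv(path, float_format="%.10g")


def long_to_wide(df: pd.DataFrame, aggfunc: str = "mean") -> SpatioTemporalSeries:
    """Convert a long (site, month, value) table to the wide layout."""
    from .pipeline import _pivot

    return _pivot(df, aggfunc)


@dataclass
class RunConfig:
    """Plain-text run configuration mapping variables to CSV files."""

    files: dict = field(default_factory=dict)       # variable -> csv path
    sites: Optional[list] = None
    bands: list = field(default_factory=lambda: [[2, 8], [8, 16], [16, 60]])
    alpha_screen: float = 0.1
    alpha_sig: float = 0.05
    n_surr: int = 10000
    n_rand: int = 1000
    coi_factor: float = 1.0
    seed: int = 0
    boxcox: bool = False
    outdir: str = "synchwave_out"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for var, p in cfg.files.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config file for {var!r} not found: {p}")
        lohi = [tuple(b) for b in cfg.bands]
        if sorted(lohi) != lohi or any(
            a[1] > b[0] + 1e-9 for a, b in zip(lohi, lohi[1:])
        ):
            raise ValueError("bands must be ordered and non-overlapping")
        return cfg

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def load_variables(self) -> dict[str, SpatioTemporalSeries]:
        return {
            var: read_site_matrix(p, self.sites) for var, p in self.files.items()
        }


# ----------------------------------------------------------------------------
# report serialization
# ----------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def report_json(report) -> str:
    """Canonical JSON text of a cascade report (sorted keys, stable floats)."""
    return json.dumps(report.to_dict(), sort_keys=True, indent=1,
                      default=_json_default)


def _field_frame(matrix: np.ndarray, timescales: np.ndarray,
                 time_labels: Sequence[str]) -> pd.DataFrame:
    cols = [f"{s:.6g}" for s in timescales]
    idx = list(time_labels) if time_labels else list(range(matrix.shape[0]))
    return pd.DataFrame(matrix, index=pd.Index(idx, name="month"), columns=cols)


def write_meanfield_csvs(mf: MeanFieldResult, outdir: Path, prefix: str) -> list[Path]:
    paths = []
    for name, mat in (
        ("wmf_sq", np.abs(mf.wmf) ** 2),
        ("wmf_mag", np.abs(mf.wmf)),
        ("wpmf", mf.wpmf_magnitude),
        ("sig_mask", mf.sig_mask.astype(int)),
    ):
        p = outdir / f"{prefix}_{name}.csv"
        _field_frame(np.asarray(mat, dtype=float), mf.timescales,
                     mf.time_labels).to_csv(p, float_format="%.10g")
        paths.append(p)
    return paths


def write_report(report, outdir: Union[str, Path]) -> dict:
    """Write report.json + CSV field exports + a manifest of content hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "report.json"]
    paths[0].write_text(report_json(report))
    paths += write_meanfield_csvs(report.wrack_meanfields, outdir, "wrack")
    paths += write_meanfield_csvs(report.bird_meanfields, outdir, "birds")
    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    logger.info("wrote report to %s (%d files)", outdir, len(paths) + 1)
    return manifest


def read_report(outdir: Union[str, Path]) -> dict:
    """Reload the scalar JSON report written by :func:`write_report`."""
    with open(Path(outdir) / "report.json") as fh:
        return json.load(fh)


def plot_meanfield(
    mf: MeanFieldResult,
    path: Union[str, Path],
    squared: bool = True,
    title: str = "",
) -> None:
    """Render a mean-field heatmap with the significance contour overlay.

    Plots |wmf|^2 (or |wmf|) over (month, timescale) inside the cone of
    influence, with a black contour where the phasor mean field exceeds the
    random-phasor threshold. Requires matplotlib (an optional dependency);
    output format follows the file extension (png, svg, pdf).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = np.abs(mf.wmf) ** 2 if squared else np.abs(mf.wmf)
    z = np.where(mf.valid_mask, z, np.nan)
    t = np.arange(z.shape[0])
    fig, ax = plt.subplots(figsize=(8, 4))
    pc = ax.pcolormesh(t, mf.timescales, z.T, shading="auto", cmap="viridis")
    if mf.sig_mask.any():
        ax.contour(
            t, mf.timescales, mf.sig_mask.T.astype(float), levels=[0.5],
            colors="black", linewidths=1.0,
        )
    ax.set_yscale("log")
    ax.set_ylabel("timescale (months)")
    ax.set_xlabel("month index")
    label = "|WMF|^2" if squared else "|WMF|"
    ax.set_title(title or f"{label}, contour: WPMF > {mf.threshold:.3f}")
    fig.colorbar(pc, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
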