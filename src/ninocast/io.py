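"""Readers and writers for the package's plain-text input/output formats.

Three input families are supported:

* Scripps-style monthly CO2 CSV — columns ``year, month, value`` with a
  configurable missing-value sentinel (default -99.99) and comment lines
  beginning with ``"`` or ``%`` (the dialect of the published Mauna Loa
  monthly tables);
* long-format SST anomaly ensemble CSV — columns
  ``member, year, month, anomaly_degC, source`` where source is
  ``observed`` or ``forecast``;
* annual emissions CSV — columns ``year, gtc``.

All parsing goes through pandas; sentinel-coded values are dropped at read
time and never stored.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .timeseries import (
    DEGC,
    PPM,
    EmissionsSeries,
    MonthlySeries,
    annual_increment,
    annual_mean,
    in_year_growth,
)
from .enso import FORECAST, OBSERVED, EnsembleMonthlySeries

COMMENT_PREFIXES = ('"', "%", "#")


def _read_csv_skipping_comments(path, **kwargs) -> pd.DataFrame:
    text = Path(path).read_text()
    kept = [
        line
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith(COMMENT_PREFIXES)
    ]
    if not kept:
        raise InputFormatError(f"{path}: no data lines")
    try:
        return pd.read_csv(_io.StringIO("\n".join(kept)), skipinitialspace=True, **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


def read_co2_csv(path, sentinel: float = -99.99, units: str = PPM) -> MonthlySeries:
    """Read a Scripps-style monthly CSV, dropping sentinel-coded months."""
    df = _read_csv_skipping_comments(path)
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in ("year", "month", "value") if c not in cols]
    if missing:
        raise InputFormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    df = df.rename(columns={cols[k]: k for k in ("year", "month", "value")})
    df = df[~np.isclose(df["value"].astype(float), sentinel)]
    if df.empty:
        raise InputFormatError(f"{path}: all rows sentinel-coded")
    records = list(zip(df["year"].astype(int), df["month"].astype(int), df["value"].astype(float)))
    return MonthlySeries.from_records(records, units=units)


def write_co2_csv(series: MonthlySeries, path) -> None:
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.6f")


def read_emissions_csv(path) -> EmissionsSeries:
    """Read an annual emissions table with columns ``year, gtc``."""
    df = _read_csv_skipping_comments(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "year" not in cols or "gtc" not in cols:
        raise InputFormatError(f"{path}: need columns year, gtc; found {list(df.columns)}")
    mapping = dict(zip(df[cols["year"]].astype(int), df[cols["gtc"]].astype(float)))
    return EmissionsSeries.from_mapping(mapping)


def write_emissions_csv(emissions: EmissionsSeries, path) -> None:
    df = pd.DataFrame({"year": emissions.data.index, "gtc": emissions.data.to_numpy()})
    df.to_csv(path, index=False, float_format="%.6f")


def read_ensemble_csv(path) -> dict[str, EnsembleMonthlySeries]:
    """Read a long-format ensemble CSV into per-source ensembles.

    Returns a dict keyed by source (``"observed"`` / ``"forecast"``) holding
    only the sources present in the file.
    """
    df = _read_csv_skipping_comments(path)
    cols = {c.strip().lower(): c for c in df.columns}
    needed = ("member", "year", "month", "anomaly_degc", "source")
    missing = [c for c in needed if c not in cols]
    if missing:
        raise InputFormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    df = df.rename(columns={cols[k]: k for k in needed})
    out: dict[str, EnsembleMonthlySeries] = {}
    for source, group in df.groupby("source"):
        source = str(source).strip().lower()
        if source not in (OBSERVED, FORECAST):
            raise InputFormatError(f"{path}: unknown source tag {source!r}")
        members = {}
        for member, rows in group.groupby("member"):
            records = list(
                zip(rows["year"].astype(int), rows["month"].astype(int), rows["anomaly_degc"].astype(float))
            )
            members[str(member)] = MonthlySeries.from_records(records, units=DEGC)
        out[source] = EnsembleMonthlySeries(members=members, source=source)
    return out


def write_ensemble_csv(ensembles: dict[str, EnsembleMonthlySeries], path) -> None:
    frames = []
    for source, ens in sorted(ensembles.items()):
        for member, series in sorted(ens.members.items()):
            df = series.to_frame().rename(columns={"value": "anomaly_degC"})
            df.insert(0, "member", member)
            df["source"] = source
            frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def write_annual_stats_csv(series: MonthlySeries, path) -> pd.DataFrame:
    """Tidy per-year table of annual means, increments and in-year growth.

    Years for which a statistic is undefined (incomplete coverage, missing
    boundary month) get an empty cell.  Returns the frame it wrote.
    """
    rows = []
    for y in series.years():
        row: dict[str, object] = {"year": y}
        for name, fn in (
            ("annual_mean_ppm", lambda: annual_mean(series, y)),
            ("annual_increment_ppm", lambda: annual_increment(series, y)),
            ("in_year_growth_ppm", lambda: in_year_growth(series, y)),
        ):
            try:
                row[name] = fn()
            except Exception:
                row[name] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6f")
    return df
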