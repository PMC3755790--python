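"""Delimited-text table readers/writers and the shipped reference fixtures.

Dialect: comma-separated, '.' decimal, '#' comment lines, UTF-8, scientific
notation accepted on input. Column matching is case-insensitive. Every file
this package writes embeds its full effective configuration as '#'-prefixed
header comments.
"""

from __future__ import annotations

import os
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import TableFormatError
from .prep import ObservationRecord, PreparedDataset

__all__ = [
    "SCHEMAS",
    "read_observations",
    "observations_from_tables",
    "write_table",
    "read_table",
    "prepared_from_frame",
    "prepared_to_frame",
    "load_table4",
    "load_table5",
    "load_table6",
    "load_table1",
    "load_insitu_toc",
    "load_table6_increase",
    "load_insitu_prepared",
]

# required columns per schema; all numeric except sample_id/labels
SCHEMAS: dict[str, tuple[str, ...]] = {
    "table4": ("sample_id", "time_d", "no3_mmol", "no2_mmol", "nh3_mmol"),
    "table5": (
        "sample_id",
        "time_d",
        "tnc_solution",
        "tnc_sigma",
        "qpcr_solution",
        "qpcr_solution_sigma",
        "qpcr_biofilm",
        "qpcr_biofilm_sigma",
    ),
    "table6": (
        "sample_id",
        "time_d",
        "toc_gC",
        "tnc_solution_dm3",
        "cells_total",
        "biomass_toc",
        "no3_gN",
    ),
    "toc": ("sample_id", "toc_gC"),
}

_TEXT_COLUMNS = {"sample_id"}


def read_observations(path, schema: str) -> pd.DataFrame:
    """Read a delimited observation table and validate it against a schema.

    Returns a DataFrame with canonical (schema-cased) column names and
    numeric dtypes. Malformed numeric cells are reported with their file
    line numbers.
    """
    if schema not in SCHEMAS:
        raise TableFormatError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file") from None
    if df.empty and len(df.columns) == 0:
        raise TableFormatError(f"{path}: no data rows")

    lower_map = {c.lower(): c for c in df.columns}
    canonical = SCHEMAS[schema]
    missing = [c for c in canonical if c.lower() not in lower_map]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    df = df.rename(columns={lower_map[c.lower()]: c for c in canonical})[list(canonical)]

    # line numbers: header is the first non-comment line; count comments
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = [
        i + 1
        for i, line in enumerate(lines)
        if line.strip() and not line.lstrip().startswith("#")
    ][1:]  # skip header

    bad: list[str] = []
    for col in canonical:
        if col in _TEXT_COLUMNS:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        mask = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        for pos in np.flatnonzero(mask.to_numpy()):
            lineno = data_lines[pos] if pos < len(data_lines) else "?"
            bad.append(f"line {lineno}: column {col!r} value {df[col].iloc[pos]!r}")
        df[col] = converted
    if bad:
        raise TableFormatError(f"{path}: unparseable numeric value(s): " + "; ".join(bad))
    return df


def observations_from_tables(
    chem: pd.DataFrame, micro: pd.DataFrame, toc: Mapping[str, float] | None = None
) -> list[ObservationRecord]:
    """Join chemistry and microbiology tables on sample_id into typed records."""
    merged = chem.merge(micro, on="sample_id", suffixes=("", "_micro"))
    if len(merged) != len(chem) or len(merged) != len(micro):
        raise TableFormatError("chemistry and microbiology tables do not share sample ids")
    records = []
    for _, row in merged.iterrows():
        sid = str(row["sample_id"])
        records.append(
            ObservationRecord(
                sample_id=sid,
                t=float(row["time_d"]),
                no3=float(row["no3_mmol"]),
                no2=float(row["no2_mmol"]),
                nh3=float(row["nh3_mmol"]),
                tnc_solution=float(row["tnc_solution"]),
                tnc_sigma=float(row["tnc_sigma"]),
                qpcr_solution=float(row["qpcr_solution"]),
                qpcr_solution_sigma=float(row["qpcr_solution_sigma"]),
                qpcr_biofilm=float(row["qpcr_biofilm"]),
                qpcr_biofilm_sigma=float(row["qpcr_biofilm_sigma"]),
                toc_solution=float(toc[sid]) if toc and sid in toc else None,
            )
        )
    return sorted(records, key=lambda r: r.t)


# ---------------------------------------------------------------------------
# writing


def write_table(frame: pd.DataFrame, path, config: Mapping | None = None) -> None:
    """Write a DataFrame as CSV with the effective config in '#' header lines.

    The write is atomic (temp file + rename) and numbers keep full precision
    so write-read round trips are value-identical.
    """
    tmp = f"{os.fspath(path)}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        if config:
            fh.write("# config:\n")
            for line in yaml.safe_dump(dict(config), sort_keys=True).splitlines():
                fh.write(f"#   {line}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")
    os.replace(tmp, path)


def read_table(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, comment="#")


def prepared_to_frame(ds: PreparedDataset) -> pd.DataFrame:
    frame = ds.frame.reset_index()
    return frame.rename(
        columns={"t": "time_d", "toc": "toc_gC", "no3": "no3_gN"}
    )


def prepared_from_frame(
    frame: pd.DataFrame,
    toc_per_cell_factor: float = float("nan"),
    nc_ratio: float = float("nan"),
    growth_fraction_x: float = 0.5,
    baseline_from: str = "",
    baseline_to: str = "",
) -> PreparedDataset:
    """Build a PreparedDataset from a table6-shaped DataFrame (rows lacking
    biomass or nitrate entries — e.g. a pre-injection sample — are dropped)."""
    df = frame.rename(
        columns={"time_d": "t", "toc_gC": "toc", "no3_gN": "no3"}
    ).dropna(subset=["biomass_toc", "no3"])
    df = df.set_index("sample_id")[["t", "toc", "cells_total", "biomass_toc", "no3"]]
    return PreparedDataset(
        frame=df.astype(float),
        toc_per_cell_factor=toc_per_cell_factor,
        nc_ratio=nc_ratio,
        growth_fraction_x=growth_fraction_x,
        baseline_from=baseline_from or str(df.index[0]),
        baseline_to=baseline_to or str(df.index[-1]),
    )


# ---------------------------------------------------------------------------
# shipped fixtures (the printed reference tables)


def _data_path(name: str):
    return resources.files("denitkin").joinpath("data", name)


def _read_fixture(name: str, schema: str | None = None) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        if schema is None:
            return pd.read_csv(path, comment="#")
        return read_observations(path, schema)


def load_table4() -> pd.DataFrame:
    """In-situ chemistry reference table (nitrogen species, mmol/dm3)."""
    return _read_fixture("table4.csv", "table4")


def load_table5() -> pd.DataFrame:
    """In-situ microbiology reference table (TNC and NarG qPCR with sigmas)."""
    return _read_fixture("table5.csv", "table5")


def load_table6() -> pd.DataFrame:
    """Prepared in-situ dataset reference table (model-ready trajectory)."""
    return _read_fixture("table6.csv")


def load_table1() -> pd.DataFrame:
    """In-vitro run matrix (series A-E experimental conditions)."""
    return _read_fixture("table1.csv")


def load_insitu_toc() -> dict[str, float]:
    """Solution TOC series keyed by sample id [g-C/dm3]."""
    df = _read_fixture("insitu_toc.csv", "toc")
    return dict(zip(df["sample_id"], df["toc_gC"].astype(float)))


def load_table6_increase() -> dict[str, float]:
    """The experiment-wide 'increase of amount' row as printed."""
    df = _read_fixture("table6_increase.csv")
    return {k: float(df[k].iloc[0]) for k in df.columns}


def load_insitu_prepared() -> PreparedDataset:
    """The prepared in-situ dataset with its printed derived constants.

    The pre-injection sample (no biomass/nitrate entries) is excluded; the
    derived constants are recomputed from the printed increase row with the
    published growth-fraction assumption x = 0.5.
    """
    from .prep import nc_ratio as _nc, toc_correlation_factor as _factor

    inc = load_table6_increase()
    return prepared_from_frame(
        load_table6(),
        toc_per_cell_factor=_factor(inc["delta_toc"], inc["delta_cells"], x=0.5),
        nc_ratio=_nc(inc["delta_no3"], inc["delta_toc"]),
        growth_fraction_x=0.5,
        baseline_from="S-2",
        baseline_to="S-6",
    )
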