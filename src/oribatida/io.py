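"""Delimited-text readers and writers for plots, specimens, traits and matrices.

Dialect is deliberately fixed: comma- or tab-delimited with a header row,
UTF-8, '.' decimal separator, no thousands separators. Matrices are written
long-form (species, plot, abundance) so they stay line-diffable.
"""

from __future__ import annotations

import csv
from os import PathLike
from pathlib import Path

import pandas as pd

from .records import (
    FormatError,
    PlotRecord,
    SpecimenRecord,
    SpeciesTrait,
    ValidationError,
)

_PLOT_FIXED_COLS = ["plot_id", "region", "habitat", "sample_side_cm", "n_subsamples"]
_SPECIMEN_COLS = ["plot_id", "subsample_id", "species", "sex", "gravid", "egg_count"]
_TRAIT_COLS = ["species", "mode", "mode_source", "body_size_um"]


def _sniff_sep(path: str | PathLike) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def _read_table(path: str | PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing required column(s) {missing}")
    return df


def read_plots(path: str | PathLike) -> list[PlotRecord]:
    """Read a plot table; extra numeric columns become land-use parameters.

    Rows violating an invariant (e.g. a proportion outside [0, 1], or a
    grassland parameter on a forest plot) are rejected with their row number.
    """
    df = _read_table(path, ["plot_id", "region", "habitat"])
    landuse_cols = [c for c in df.columns if c not in _PLOT_FIXED_COLS]
    records = []
    for i, row in df.iterrows():
        landuse = {
            c: float(row[c]) for c in landuse_cols if pd.notna(row[c])
        }
        try:
            records.append(
                PlotRecord(
                    plot_id=str(row["plot_id"]),
                    region=str(row["region"]),
                    habitat=str(row["habitat"]),
                    landuse=landuse,
                    sample_side_cm=float(row.get("sample_side_cm", 0.0) or 0.0),
                    n_subsamples=int(row.get("n_subsamples", 5)),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i + 2} of {Path(path).name}: {err}") from err
    return records


def write_plots(plots: list[PlotRecord], path: str | PathLike) -> None:
    landuse_cols = sorted({k for p in plots for k in p.landuse})
    rows = []
    for p in plots:
        row = {
            "plot_id": p.plot_id,
            "region": p.region,
            "habitat": p.habitat,
            "sample_side_cm": p.sample_side_cm,
            "n_subsamples": p.n_subsamples,
        }
        row.update({c: p.landuse.get(c) for c in landuse_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=_PLOT_FIXED_COLS + landuse_cols).to_csv(path, index=False)


def read_specimens(path: str | PathLike) -> list[SpecimenRecord]:
    df = _read_table(path, _SPECIMEN_COLS[:4])
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SpecimenRecord(
                    plot_id=str(row["plot_id"]),
                    subsample_id=int(row["subsample_id"]),
                    species=str(row["species"]),
                    sex=str(row["sex"]),
                    gravid=bool(row.get("gravid", False)),
                    egg_count=int(row.get("egg_count", 0)),
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"row {i + 2} of {Path(path).name}: {err}") from err
    return records


def write_specimens(specimens: list[SpecimenRecord], path: str | PathLike) -> None:
    pd.DataFrame(
        [
            (s.plot_id, s.subsample_id, s.species, s.sex, s.gravid, s.egg_count)
            for s in specimens
        ],
        columns=_SPECIMEN_COLS,
    ).to_csv(path, index=False)


def read_traits(path: str | PathLike) -> list[SpeciesTrait]:
    df = _read_table(path, ["species"])
    records = []
    for i, row in df.iterrows():
        size = row.get("body_size_um")
        try:
            records.append(
                SpeciesTrait(
                    species=str(row["species"]),
                    mode=str(row.get("mode", "unknown")),
                    mode_source=str(row.get("mode_source", "sex_ratio_rule")),
                    body_size_um=float(size) if pd.notna(size) else None,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i + 2} of {Path(path).name}: {err}") from err
    return records


def write_traits(traits: list[SpeciesTrait], path: str | PathLike) -> None:
    pd.DataFrame(
        [(t.species, t.mode, t.mode_source, t.body_size_um) for t in traits],
        columns=_TRAIT_COLS,
    ).to_csv(path, index=False)


def read_mode_overrides(path: str | PathLike) -> dict[str, str]:
    """Two-column (species, mode) file of literature reproductive-mode calls."""
    df = _read_table(path, ["species", "mode"])
    return {str(r["species"]): str(r["mode"]) for _, r in df.iterrows()}
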