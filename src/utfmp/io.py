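"""Read and write spectral cohorts, sample metadata, and feature tables.

The canonical spectral format is a wide CSV: a ``wavelength_nm`` column
followed by one column per sample. Dilution series are encoded as
``sampleid@factor`` column names (absent suffix means undiluted, factor 1).
A long format (``sample_id, wavelength_nm, intensity``) is accepted on read.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import GROUPS, STRIP_PARAMETERS, SampleMetadata, SynchronousSpectrum, WavelengthGrid

logger = logging.getLogger(__name__)

WAVELENGTH_COLUMN = "wavelength_nm"


class SpectraFormatError(ValueError):
    """Malformed spectra file (missing columns, bad cells, bad coverage)."""


def _parse_column_id(name: str) -> tuple[str, float]:
    """Split a ``sampleid@factor`` column name; bare names mean factor 1."""
    if "@" in name:
        sample_id, _, factor = name.rpartition("@")
        try:
            return sample_id, float(factor)
        except ValueError as exc:
            raise SpectraFormatError(
                f"column {name!r}: dilution suffix is not numeric"
            ) from exc
    return name, 1.0


def read_spectra(path: str | Path, grid: WavelengthGrid | None = None) -> list[SynchronousSpectrum]:
    """Read a cohort of synchronous spectra from CSV.

    Wavelengths are linearly interpolated onto ``grid`` if the file's grid
    differs but covers it; interpolation is exact when the grids coincide.
    Negative intensities are clipped to 0 with a warning (baseline artifacts:
    fluorescence is nonnegative).
    """
    grid = grid or WavelengthGrid()
    df = pd.read_csv(path)
    if {"sample_id", WAVELENGTH_COLUMN, "intensity"} <= set(df.columns):
        df = df.pivot(index=WAVELENGTH_COLUMN, columns="sample_id", values="intensity").reset_index()
        df.columns.name = None
    if WAVELENGTH_COLUMN not in df.columns:
        raise SpectraFormatError(f"{path}: missing {WAVELENGTH_COLUMN!r} column")
    sample_cols = [c for c in df.columns if c != WAVELENGTH_COLUMN]
    for col in [WAVELENGTH_COLUMN, *sample_cols]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraFormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at row {row}, column {col!r}"
            )
    wl_file = df[WAVELENGTH_COLUMN].to_numpy(dtype=float)
    order = np.argsort(wl_file)
    wl_file = wl_file[order]
    target = grid.wavelengths
    if wl_file[0] > target[0] + 1e-9 or wl_file[-1] < target[-1] - 1e-9:
        raise SpectraFormatError(
            f"{path}: wavelength coverage {wl_file[0]}-{wl_file[-1]} nm narrower "
            f"than grid {target[0]}-{target[-1]} nm"
        )

    seen: set[tuple[str, float]] = set()
    spectra: list[SynchronousSpectrum] = []
    for col in sample_cols:
        sample_id, factor = _parse_column_id(str(col))
        key = (sample_id, factor)
        if key in seen:
            raise SpectraFormatError(f"{path}: duplicate sample column {col!r}")
        seen.add(key)
        y = df[col].to_numpy(dtype=float)[order]
        intens = np.interp(target, wl_file, y)
        n_neg = int((intens < 0).sum())
        if n_neg:
            logger.warning(
                "spectrum %s: clipped %d negative intensities to 0", sample_id, n_neg
            )
            intens = np.clip(intens, 0.0, None)
        spectra.append(
            SynchronousSpectrum(
                sample_id=sample_id, grid=grid, intensities=intens, dilution_factor=factor
            )
        )
    logger.info("read %d spectra from %s", len(spectra), path)
    return spectra


def write_spectra(spectra: Sequence[SynchronousSpectrum], path: str | Path) -> None:
    """Write spectra to the wide CSV format (inverse of :func:`read_spectra`)."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    data = {WAVELENGTH_COLUMN: grid.wavelengths}
    for s in spectra:
        name = s.sample_id if s.dilution_factor == 1.0 else f"{s.sample_id}@{s.dilution_factor:g}"
        data[name] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read and validate the sample-metadata CSV (sample_id, group, age, strip)."""
    df = pd.read_csv(path)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise SpectraFormatError(f"{path}: metadata must contain columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    strip_cols = [c for c in STRIP_PARAMETERS if c in df.columns]
    records = []
    for _, row in df.iterrows():
        strip = None
        if strip_cols:
            vals = {c: row[c] for c in strip_cols if not _is_missing(row[c])}
            strip = vals or None
        age = None if "age_years" not in df.columns or _is_missing(row.get("age_years")) else float(row["age_years"])
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                age_years=age,
                strip=strip,
            )
        )
    counts = {g: sum(1 for r in records if r.group == g) for g in GROUPS}
    logger.info("read %d metadata records from %s: %s", len(records), path, counts)
    return records


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {"sample_id": r.sample_id, "group": r.group}
        if r.age_years is not None:
            row["age_years"] = r.age_years
        if r.strip:
            row.update(r.strip)
        rows.append(row)
    if not rows:
        raise ValueError("no metadata records to write")
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table, round-trip safe to full float precision."""
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, index_label="sample_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
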