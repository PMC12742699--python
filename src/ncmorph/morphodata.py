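"""Specimen-level morphometry: I/O, bilateral averaging, ratio indices, nest centroids.

The unit of measurement is one minor worker. Fourteen linear characters are
recorded in micrometres; bilateral characters may be supplied as a single
(pre-averaged) column or as ``<CHAR>_left`` / ``<CHAR>_right`` pairs. Cephalic
size CS = (CL + CW) / 2 is the body-size proxy, and thirteen dimensionless
ratio indices (twelve divided by CS, PreOc divided by CL, plus the shape ratio
CL/CW) feed the multivariate stages. Nest centroids -- per-colony arithmetic
means -- are the unit of unsupervised clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 14 raw linear characters, in canonical column order.
CHARACTERS = [
    "CL", "CW", "dAN", "EL", "HTL", "MGr", "ML",
    "MW", "NOL", "PeSH", "PeW", "PreOc", "PrGr", "SL",
]

#: Characters that may legitimately be zero (groove depths).
ZERO_ALLOWED = {"MGr", "PrGr"}

#: The 13 ratio indices derived from the raw characters.
INDICES = [
    "CL/CW", "dAN/CS", "EL/CS", "HTL/CS", "MGr/CS", "ML/CS", "MW/CS",
    "NOL/CS", "PeSH/CS", "PeW/CS", "PreOc/CL", "PrGr/CS", "SL/CS",
]

#: Metadata columns recognised in specimen tables.
ID_COLUMNS = [
    "specimen_id", "nest_id", "species", "color_morph",
    "region", "latitude", "longitude",
]

#: Valid color-morph labels ("none" marks the non-polymorphic species).
COLOR_MORPHS = ("truncata_like", "red_headed", "blackish", "none")


def average_bilateral(left, right):
    """Arithmetic mean of a bilateral character pair.

    Either side may be missing (NaN), in which case the present side is
    returned. Works element-wise on arrays. Returns NaN where both sides
    are absent.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    both = (left + right) / 2.0
    out = np.where(np.isnan(left), right, np.where(np.isnan(right), left, both))
    if out.ndim == 0:
        return float(out)
    return out


def read_specimen_table(path, column_map=None) -> pd.DataFrame:
    """Read a specimen-level CSV into a canonical measurement table.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row, one row per specimen. Bilateral characters may
        appear as a single column ``X`` or as ``X_left`` / ``X_right``.
    column_map : dict, optional
        Mapping from the file's column names to canonical names
        (e.g. ``{"colony": "nest_id"}``).

    Returns
    -------
    pandas.DataFrame
        One row per specimen, row order preserved. Bilateral pairs are
        averaged. A boolean ``complete`` column flags rows with all 14
        characters present; incomplete rows are retained but must be
        excluded from multivariate stages.

    Raises
    ------
    ValueError
        On an unparseable number (naming row and column), a duplicate
        ``specimen_id``, or missing mandatory columns.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.strip() for c in df.columns]

    for required in ("specimen_id", "nest_id"):
        if required not in df.columns:
            raise ValueError(f"missing required column {required!r}")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise ValueError(f"duplicate specimen_id {dup!r}")

    out = pd.DataFrame(index=df.index)
    for col in ID_COLUMNS:
        if col in df.columns:
            out[col] = df[col]
    for col in ("latitude", "longitude"):
        if col in out.columns:
            out[col] = _numeric(df[col], col)

    for char in CHARACTERS:
        lcol, rcol = f"{char}_left", f"{char}_right"
        if lcol in df.columns or rcol in df.columns:
            left = _numeric(df[lcol], lcol) if lcol in df.columns else np.nan
            right = _numeric(df[rcol], rcol) if rcol in df.columns else np.nan
            out[char] = average_bilateral(left, right)
        elif char in df.columns:
            out[char] = _numeric(df[char], char)
        else:
            out[char] = np.nan

    _validate_ranges(out)
    out["complete"] = out[CHARACTERS].notna().all(axis=1)
    return out


def write_specimen_table(records: pd.DataFrame, path) -> None:
    """Write a measurement table back to CSV (full float precision round-trip)."""
    cols = [c for c in ID_COLUMNS if c in records.columns] + CHARACTERS
    records.to_csv(path, index=False, columns=cols)


def _numeric(series, colname):
    # parses via float() for exact (shortest-repr) round trips
    series = pd.Series(series)

    def parse(value, row):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        text = str(value).strip()
        if text == "":
            return np.nan
        try:
            return float(text)
        except ValueError:
            raise ValueError(
                f"unparseable number {value!r} in column {colname!r}, row {row}"
            ) from None

    return pd.Series([parse(v, i) for i, v in series.items()],
                     index=series.index, dtype=float)


def _validate_ranges(records: pd.DataFrame) -> None:
    for char in CHARACTERS:
        vals = records[char]
        floor_ok = vals >= 0 if char in ZERO_ALLOWED else vals > 0
        bad = ~floor_ok & vals.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-positive value {vals[row]} for character {char!r}, row {row}"
            )


def compute_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Derive CS and the 13 ratio indices from the raw characters.

    CS = (CL + CW)/2 in the input unit (micrometres). PreOc is divided by CL;
    every other size-relative character by CS; CL/CW is the head-shape ratio.
    Metadata columns are carried through. Rows with missing characters yield
    NaN indices.
    """
    out = records[[c for c in ID_COLUMNS if c in records.columns]].copy()
    cs = (records["CL"] + records["CW"]) / 2.0
    out["CS"] = cs
    for index_name in INDICES:
        num, den = index_name.split("/")
        denom = {"CS": cs, "CL": records["CL"], "CW": records["CW"]}[den]
        if (denom == 0).any():
            raise ZeroDivisionError(f"zero denominator {den} computing {index_name}")
        out[index_name] = records[num] / denom
    return out


def nest_centroids(records: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Per-nest arithmetic mean of the given variables.

    Singleton nests are retained (their centroid equals the single worker).
    Categorical metadata (species, color_morph, region) is summarised by the
    nest majority; latitude/longitude by the mean.

    Returns a DataFrame indexed by ``nest_id`` with an ``n_workers`` column.
    """
    if variables is None:
        variables = [c for c in CHARACTERS if c in records.columns]
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise ValueError(f"variables not present: {missing}")
    if len(records) == 0:
        return pd.DataFrame(columns=["n_workers", *variables])

    grouped = records.groupby("nest_id", sort=True)
    cent = grouped[variables].mean()
    cent.insert(0, "n_workers", grouped.size())
    for col in ("species", "color_morph", "region"):
        if col in records.columns:
            cent[col] = grouped[col].agg(_majority)
    for col in ("latitude", "longitude"):
        if col in records.columns:
            cent[col] = grouped[col].mean()
    return cent


def _majority(values):
    values = values.dropna()
    if values.empty:
        return np.nan
    return values.mode().iloc[0]
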