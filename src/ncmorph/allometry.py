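"""Removal of allometric variance (RAV).

Shape ratios in polymorphic ants drift systematically with body size
(allometry): e.g. relative mesosoma width grows, relative scape length
shrinks, as cephalic size CS increases. Size-driven variance would dominate a
PCA, so every index y is rescaled to the value expected at a reference size,

    y_0.9 = y / (k * CS + d) * (k * 0.9 + d),

where (k, d) are slope and intercept of the ordinary-least-squares line of
the index against CS in millimetres, fitted per species and then averaged
between the two species. The reference CS is 0.9 mm, close to the grand mean
worker size. At CS = 0.9 the correction is the identity; elsewhere it divides
out the fitted size trend, leaving the residual (taxonomically informative)
shape variation.

Raw characters live in micrometres throughout the package; this module is the
single point where CS is converted to millimetres.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .morphodata import INDICES

CS_REF_MM = 0.9


@dataclass(frozen=True)
class AllometricLine:
    """OLS line of one ratio index against CS (mm): value = k * CS + d."""

    index_name: str
    k: float
    d: float
    cs_ref: float = CS_REF_MM
    k_se: float | None = None
    d_se: float | None = None

    @property
    def multiplier(self) -> float:
        """Value of the fitted line at the reference size, k * cs_ref + d."""
        return self.k * self.cs_ref + self.d

    def value_at(self, cs_mm):
        return self.k * np.asarray(cs_mm, dtype=float) + self.d


@dataclass
class RavParameterSet:
    """One allometric line per ratio index, plus where the lines came from."""

    lines: dict[str, AllometricLine] = field(default_factory=dict)
    provenance: str = "fitted_per_species"  # or "pooled", "paper_printed"

    def __getitem__(self, index_name: str) -> AllometricLine:
        return self.lines[index_name]

    def __iter__(self):
        return iter(self.lines.values())

    def validate(self) -> None:
        missing = set(INDICES) - set(self.lines)
        if missing:
            raise ValueError(f"parameter set lacks indices: {sorted(missing)}")

    def to_csv(self, path) -> None:
        rows = [
            {"index_name": ln.index_name, "k": ln.k, "d": ln.d,
             "cs_ref": ln.cs_ref, "provenance": self.provenance}
            for ln in self
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RavParameterSet":
        df = pd.read_csv(path)
        lines = {
            r.index_name: AllometricLine(r.index_name, float(r.k), float(r.d),
                                         float(getattr(r, "cs_ref", CS_REF_MM)))
            for r in df.itertuples()
        }
        prov = df["provenance"].iloc[0] if "provenance" in df.columns else "pooled"
        return cls(lines=lines, provenance=str(prov))


def printed_parameters() -> RavParameterSet:
    """The 13 published correction lines (pooled across the two species)."""
    src = importlib.resources.files("ncmorph.data").joinpath("rav_printed.csv")
    with importlib.resources.as_file(src) as path:
        df = pd.read_csv(path)
    lines = {
        r.index_name: AllometricLine(r.index_name, float(r.k), float(r.d))
        for r in df.itertuples()
    }
    return RavParameterSet(lines=lines, provenance="paper_printed")


def printed_multipliers() -> dict[str, float]:
    """The published reference-size constants k*0.9 + d, as printed."""
    src = importlib.resources.files("ncmorph.data").joinpath("rav_printed.csv")
    with importlib.resources.as_file(src) as path:
        df = pd.read_csv(path)
    return dict(zip(df["index_name"], df["multiplier"].astype(float)))


def fit_allometric_line(cs_mm, values, index_name: str) -> AllometricLine:
    """OLS fit of an index on CS (mm); returns slope/intercept with SEs."""
    cs_mm = np.asarray(cs_mm, dtype=float)
    values = np.asarray(values, dtype=float)
    if cs_mm.size < 2:
        raise ValueError(f"{index_name}: need at least 2 points, got {cs_mm.size}")
    if np.ptp(cs_mm) == 0:
        raise ValueError(f"{index_name}: CS values are all equal; slope undefined")
    res = stats.linregress(cs_mm, values)
    return AllometricLine(
        index_name, float(res.slope), float(res.intercept),
        k_se=float(res.stderr), d_se=float(res.intercept_stderr),
    )


def pool_species_lines(line_a: AllometricLine, line_b: AllometricLine) -> AllometricLine:
    """Unweighted arithmetic mean of two species' (k, d) parameters."""
    if line_a.index_name != line_b.index_name:
        raise ValueError(
            f"index mismatch: {line_a.index_name!r} vs {line_b.index_name!r}"
        )
    if line_a.cs_ref != line_b.cs_ref:
        raise ValueError("reference sizes differ")
    return AllometricLine(
        line_a.index_name, (line_a.k + line_b.k) / 2.0, (line_a.d + line_b.d) / 2.0,
        cs_ref=line_a.cs_ref,
    )


def fit_species_pooled(index_table: pd.DataFrame, species_col: str = "species",
                       cs_col: str = "CS") -> RavParameterSet:
    """Fit per-species lines for every index and pool them.

    ``index_table`` holds CS in micrometres plus the 13 indices (as from
    :func:`ncmorph.morphodata.compute_indices`). Exactly two species labels
    are required.
    """
    species = index_table[species_col].dropna().unique()
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species labels, got {list(species)}")
    cs_mm = index_table[cs_col] / 1000.0
    lines = {}
    for index_name in INDICES:
        per_species = []
        for sp in species:
            mask = index_table[species_col] == sp
            per_species.append(
                fit_allometric_line(cs_mm[mask], index_table.loc[mask, index_name],
                                    index_name)
            )
        lines[index_name] = pool_species_lines(*per_species)
    return RavParameterSet(lines=lines, provenance="pooled")


def rav_correct(y, cs_mm, line: AllometricLine):
    """Rescale index values to the reference cephalic size.

    Returns ``y / (k*cs + d) * (k*cs_ref + d)``; the identity when
    ``cs == cs_ref``. Raises if the fitted line is non-positive anywhere in
    the data (the correction would flip signs).
    """
    cs_mm = np.asarray(cs_mm, dtype=float)
    denom = line.value_at(cs_mm)
    if np.any(denom <= 0):
        bad_cs = np.atleast_1d(cs_mm)[np.argmin(np.atleast_1d(denom))]
        raise ValueError(
            f"{line.index_name}: fitted line non-positive at CS={bad_cs:.4f} mm"
        )
    return np.asarray(y, dtype=float) / denom * line.multiplier


def rav_correct_table(index_table: pd.DataFrame, params: RavParameterSet,
                      indices=None, cs_col: str = "CS") -> pd.DataFrame:
    """Apply RAV to every (or the given) indices of a table; CS is in um."""
    params.validate()
    if indices is None:
        indices = [c for c in INDICES if c in index_table.columns]
    cs_mm = index_table[cs_col] / 1000.0
    out = index_table.copy()
    for index_name in indices:
        out[index_name] = rav_correct(index_table[index_name], cs_mm,
                                      params[index_name])
    return out


def verify_printed_functions(params: RavParameterSet, tol: float = 2e-4) -> pd.DataFrame:
    """Check each line's reference-size constant against the published value.

    Returns a report with one row per index: recomputed k*0.9 + d, the printed
    constant, their absolute difference, and an ``ok`` flag at tolerance
    ``tol`` (the printing precision of the published constants).
    """
    printed = printed_multipliers()
    rows = []
    for index_name, target in printed.items():
        line = params[index_name]
        computed = line.multiplier
        rows.append({
            "index_name": index_name, "k": line.k, "d": line.d,
            "computed_multiplier": computed, "printed_multiplier": target,
            "abs_diff": abs(computed - target),
            "ok": abs(computed - target) <= tol,
        })
    return pd.DataFrame(rows)
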