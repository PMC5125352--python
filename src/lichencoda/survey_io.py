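"""Reading, validation and pre-processing of concentration survey tables.

A survey is a wide table: one row per lichen sample, one column per element,
with a categorical group label and optional WGS84 coordinates.  Replicate
measurements of the same thallus share a base identifier plus a ``bis``
marker (``"11"`` and ``"11bis"``).  All concentrations must be strictly
positive before any log-ratio work.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOD_TOKEN = "<LOD"
REPLICATE_MARKER = "bis"

#: unit tags understood by :func:`harmonize_units`
UG_PER_G = "ug/g"
PERCENT_WW = "%w/w"
_UNIT_FACTORS = {UG_PER_G: 1.0, PERCENT_WW: 1.0e4}


class SchemaError(ValueError):
    """A declared element column is missing or the header is malformed."""


class ValidationError(ValueError):
    """Row-level content violates the survey invariants."""


@dataclass(frozen=True)
class ElementPanel:
    """The measured element set and its roles.

    Parameters
    ----------
    names:
        Ordered element identifiers, e.g. ``("Co", "Cu", "Cr", "Fe", "Ni",
        "Zn", "Ti")``.
    units:
        Per-element unit tag, ``"ug/g"`` or ``"%w/w"``.
    reference_element:
        The crustal reference used for single-element normalization and for
        orienting the contamination index (default titanium).
    source_elements:
        Elements attributed to the contamination source under study
        (default the mining-emitted triad Ni, Cr, Co).
    """

    names: tuple[str, ...]
    units: tuple[str, ...] = ()
    reference_element: str = "Ti"
    source_elements: tuple[str, ...] = ("Ni", "Cr", "Co")

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValidationError("element names must be unique")
        if len(self.names) < 3:
            raise ValidationError(
                "log-ratio methods need at least 3 parts, got %d" % len(self.names)
            )
        units = self.units or tuple(UG_PER_G for _ in self.names)
        if len(units) != len(self.names):
            raise ValidationError("one unit tag per element required")
        for u in units:
            if u not in _UNIT_FACTORS:
                raise ValidationError(f"unknown unit tag {u!r}")
        object.__setattr__(self, "units", units)
        missing = [e for e in (self.reference_element, *self.source_elements)
                   if e not in self.names]
        if missing:
            raise ValidationError(f"elements not in panel: {missing}")

    @property
    def D(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class BlankSeries:
    """Repeated measurements of an analytical blank for one element."""

    element: str
    readings: tuple[float, ...]

    def __post_init__(self):
        r = tuple(float(x) for x in self.readings)
        if len(r) < 2:
            raise ValidationError("at least 2 blank readings needed for an SD")
        if not all(math.isfinite(x) for x in r):
            raise ValidationError("blank readings must be finite")
        object.__setattr__(self, "readings", r)

    @property
    def n(self) -> int:
        return len(self.readings)


@dataclass
class ConcentrationTable:
    """Samples x elements concentration matrix with group labels.

    ``values`` is a DataFrame indexed by sample id with one column per panel
    element; ``groups`` a Series aligned to the same index.  ``below_lod`` is
    a boolean mask (same shape as ``values``) marking cells read as the
    ``<LOD`` token; such cells hold NaN until :func:`replace_below_lod`.
    """

    values: pd.DataFrame
    groups: pd.Series
    panel: ElementPanel
    coords: pd.DataFrame | None = None
    below_lod: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = self.values.loc[:, list(self.panel.names)].astype(float)
        if not self.values.index.is_unique:
            raise ValidationError("duplicate sample ids")
        if not self.groups.index.equals(self.values.index):
            raise ValidationError("group labels do not align with samples")
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        bad = (self.values <= 0) & ~self.below_lod
        if bad.any().any():
            r, c = np.argwhere(bad.values)[0]
            raise ValidationError(
                "non-positive concentration at sample "
                f"{self.values.index[r]!r}, element {self.values.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def copy(self) -> "ConcentrationTable":
        return ConcentrationTable(
            self.values.copy(), self.groups.copy(), self.panel,
            None if self.coords is None else self.coords.copy(),
            self.below_lod.copy(),
        )


def base_id(sample_id: str) -> str:
    """Strip the replicate marker: ``"11bis" -> "11"``."""
    s = str(sample_id)
    return s[: -len(REPLICATE_MARKER)] if s.endswith(REPLICATE_MARKER) else s


def read_concentrations(path, panel: ElementPanel) -> ConcentrationTable:
    """Read a wide CSV survey into a :class:`ConcentrationTable`.

    The header must name ``sample_id``, ``group``, optionally ``lat``/``lon``,
    and every panel element.  Element cells are numbers or the literal token
    ``<LOD``.  No unit harmonization is performed here.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise SchemaError("CSV must have 'sample_id' and 'group' columns")
    missing = [e for e in panel.names if e not in df.columns]
    if missing:
        raise SchemaError(f"declared element columns absent from CSV: {missing}")
    ids = df["sample_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate sample id {dup!r} without a replicate marker"
        )
    raw = df[list(panel.names)].astype(str).apply(lambda s: s.str.strip())
    mask = raw.eq(LOD_TOKEN)
    vals = raw.mask(mask).apply(pd.to_numeric)
    vals.index = ids
    mask.index = ids
    groups = pd.Series(df["group"].astype(str).values, index=ids, name="group")
    coords = None
    if {"lat", "lon"}.issubset(df.columns):
        coords = pd.DataFrame(
            {"lat": df["lat"].values, "lon": df["lon"].values}, index=ids
        )
    bad = vals.le(0) & ~mask
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValidationError(
            f"non-positive value at sample {ids.iloc[r]!r}, "
            f"element {vals.columns[c]!r}"
        )
    return ConcentrationTable(vals, groups, panel, coords, mask)


def write_concentrations(table: ConcentrationTable, path) -> None:
    """Write the survey back to the CSV dialect read by ``read_concentrations``."""
    out = pd.DataFrame({"sample_id": table.sample_ids,
                        "group": table.groups.values})
    if table.coords is not None:
        out["lat"] = table.coords["lat"].values
        out["lon"] = table.coords["lon"].values
    for e in table.panel.names:
        col = table.values[e].astype(object).copy()
        col[table.below_lod[e].values] = LOD_TOKEN
        out[e] = col.values
    out.to_csv(path, index=False, float_format="%.12g")


def harmonize_units(table: ConcentrationTable) -> ConcentrationTable:
    """Express every element in ug/g (``%w/w`` cells multiplied by 1e4).

    Idempotent: unit tags are updated so a second call is a no-op.  For the
    centered log-ratio PCA the per-column factor is provably irrelevant, but
    raw outputs (ratios, geometric means) need consistent units.
    """
    factors = np.array([_UNIT_FACTORS[u] for u in table.panel.units])
    new = table.copy()
    new.values = new.values * factors
    new.panel = replace(table.panel,
                        units=tuple(UG_PER_G for _ in table.panel.names))
    return new


def compute_lod(blanks: BlankSeries) -> float:
    """Limit of detection: three times the SD of repeated analytical blanks.

    The sample SD (n-1 denominator) is used.
    """
    return 3.0 * float(np.std(blanks.readings, ddof=1))


def replace_below_lod(table: ConcentrationTable,
                      lods: Mapping[str, float],
                      fraction: float = 0.65) -> ConcentrationTable:
    """Substitute flagged ``<LOD`` cells by ``fraction * LOD`` of their element.

    ``fraction`` must be in (0, 1]; 0.65 is the common simple multiplicative
    replacement for compositional data.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    new = table.copy()
    n_replaced = 0
    for e in table.panel.names:
        mask = new.below_lod[e]
        if not mask.any():
            continue
        if e not in lods:
            raise ValidationError(f"flagged <LOD cells for {e!r} but no LOD given")
        new.values.loc[mask, e] = fraction * float(lods[e])
        n_replaced += int(mask.sum())
    new.below_lod = pd.DataFrame(False, index=new.values.index,
                                 columns=new.values.columns)
    new._n_lod_replacements = n_replaced  # QC breadcrumb
    return ConcentrationTable(new.values, new.groups, new.panel,
                              new.coords, new.below_lod)


def aggregate_replicates(table: ConcentrationTable,
                         mode: str = "keep_all") -> ConcentrationTable:
    """Resolve replicate ("bis") rows.

    mode="keep_all"
        return the table unchanged (every measurement is a row).
    mode="geometric_mean"
        collapse each replicate set to its element-wise geometric mean.
    mode="first"
        keep only the first (unmarked) measurement of each sample.
    """
    if mode not in ("keep_all", "geometric_mean", "first"):
        raise ValidationError(f"unknown replicate mode {mode!r}")
    if mode == "keep_all":
        return table.copy()
    bases = [base_id(s) for s in table.sample_ids]
    gb = pd.Series(table.groups.values, index=bases)
    for b, grs in gb.groupby(level=0):
        if grs.nunique() > 1:
            raise ValidationError(
                f"replicates of sample {b!r} carry different group labels"
            )
    if mode == "first":
        keep = [s for s in table.sample_ids
                if not str(s).endswith(REPLICATE_MARKER)]
        return ConcentrationTable(
            table.values.loc[keep], table.groups.loc[keep], table.panel,
            None if table.coords is None else table.coords.loc[keep],
            table.below_lod.loc[keep],
        )
    logs = np.log(table.values)
    logs.index = bases
    merged = np.exp(logs.groupby(level=0, sort=False).mean())
    groups = gb.groupby(level=0, sort=False).first()
    groups = groups.loc[merged.index]
    groups.name = "group"
    coords = None
    if table.coords is not None:
        c = table.coords.copy()
        c.index = bases
        coords = c.groupby(level=0, sort=False).first().loc[merged.index]
    return ConcentrationTable(merged, groups, table.panel, coords)


def group_geometric_means(table: ConcentrationTable) -> pd.DataFrame:
    """Per-group, per-element geometric mean (nth root of the product of n)."""
    if (table.values <= 0).any().any():
        raise ValidationError("geometric means need strictly positive values")
    logs = np.log(table.values)
    out = np.exp(logs.groupby(table.groups.values, sort=False).mean())
    out.index.name = "group"
    return out


def normalize_to_reference(table: ConcentrationTable) -> pd.DataFrame:
    """Classical single-reference normalization: metal / reference element.

    Returns a samples x (D-1) frame of ratios; the reference column is
    omitted.  This is the traditional baseline the compositional analysis
    replaces, kept for comparison.
    """
    ref = table.panel.reference_element
    others = [e for e in table.panel.names if e != ref]
    ratios = table.values[others].div(table.values[ref], axis=0)
    ratios.columns = [f"{e}/{ref}" for e in others]
    return ratios
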