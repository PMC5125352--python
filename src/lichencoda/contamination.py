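"""The synthetic contamination index: sign-oriented PC1 sample scores.

The first principal component of the clr-PCA concentrates the joint
enrichment of the source elements (Ni, Cr, Co) relative to the crustal
reference (Ti), so the PC1 sample score summarizes, per sample, the local
contamination level.  Because an SVD fixes signs only up to a flip, the
component is oriented deterministically: the geometric mean of the
multiplicative ratio loadings source/reference on PC1 must exceed 1, so
larger index = more contaminated.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import CompositionalPCA, ratio_loading
from .survey_io import ConcentrationTable


def orient_pc(p: CompositionalPCA,
              source_elements=None,
              reference_element=None,
              panel=None) -> CompositionalPCA:
    """Fix the sign of PC1 so the source/reference ratio loadings exceed 1.

    Idempotent.  Raises when the mean loading is exactly 1 (orientation
    undefined on such degenerate data).
    """
    if panel is not None:
        source_elements = source_elements or panel.source_elements
        reference_element = reference_element or panel.reference_element
    if not source_elements or reference_element is None:
        raise ValueError("source and reference elements required")
    for e in (*source_elements, reference_element):
        if e not in p.elements:
            raise ValueError(f"element {e!r} not in PCA")
    logh = np.mean([np.log(ratio_loading(p, e, reference_element, pc=1))
                    for e in source_elements])
    if logh == 0.0:
        raise ValueError("orientation undefined: mean source/reference "
                         "loading on PC1 is exactly 1")
    if logh < 0:
        p.flip(0)
    return p


def index_table(p: CompositionalPCA, table: ConcentrationTable) -> pd.DataFrame:
    """Join the oriented PC1 score with sample metadata.

    The PCA must have been computed from this table's clr matrix (sample ids
    are checked).  The index mean is ~0 by construction (centered scores).
    """
    if tuple(map(str, table.sample_ids)) != p.sample_ids:
        raise ValueError("sample mismatch between PCA and table")
    out = pd.DataFrame({
        "sample_id": list(p.sample_ids),
        "group": table.groups.values,
        "index": p.scores["PC1"].values,
    })
    if table.coords is not None:
        out["lat"] = table.coords["lat"].values
        out["lon"] = table.coords["lon"].values
    return out


def export_map_layer(idx: pd.DataFrame, path, format: str = "geojson") -> None:
    """Write the index as a mappable layer.

    geojson: RFC 7946 FeatureCollection, WGS84 [lon, lat] point per sample,
    properties sample_id/group/index.  csv: the same columns, flat.
    """
    if format == "csv":
        idx.to_csv(path, index=False, float_format="%.17g")
        return
    if format != "geojson":
        raise ValueError(f"unknown format {format!r}")
    if "lat" not in idx.columns or "lon" not in idx.columns:
        raise ValueError("coordinates required for GeoJSON export")
    missing = idx.loc[idx["lat"].isna() | idx["lon"].isna(), "sample_id"]
    if len(missing):
        raise ValueError(f"samples without coordinates: {list(missing)}")
    features = []
    for _, row in idx.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["lon"]), float(row["lat"])]},
            "properties": {"sample_id": str(row["sample_id"]),
                           "group": str(row["group"]),
                           "index": float(row["index"])},
        })
    fc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)
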