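"""Bundled example survey: trace metals in New Caledonian epiphytic lichens.

39 measurement rows (34 thalli, 5 measured twice; replicates carry a "bis"
suffix) over 7 elements in three groups: COUN (countryside background), NOU
(Noumea, near a pyrometallurgical plant) and PORO (around an open-cast Ni
mine).  Concentrations in ug/g except Fe in % w/w.

Coordinates are SYNTHETIC plausible points near the three survey areas,
generated deterministically for mapping demos; they are not survey data.
"""
from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .survey_io import (ConcentrationTable, ElementPanel, UG_PER_G,
                        PERCENT_WW, read_concentrations)

ELEMENTS = ("Co", "Cu", "Cr", "Fe", "Ni", "Zn", "Ti")
UNITS = (UG_PER_G, UG_PER_G, UG_PER_G, PERCENT_WW, UG_PER_G, UG_PER_G, UG_PER_G)

PANEL = ElementPanel(names=ELEMENTS, units=UNITS,
                     reference_element="Ti", source_elements=("Ni", "Cr", "Co"))

# sample_id, group, Co, Cu, Cr, Fe(%w/w), Ni, Zn, Ti
_ROWS = [
    ("1",     "COUN", 2.1,  8.2,  26,   0.19, 43,   75,  128),
    ("8",     "COUN", 2.0,  2.2,  18,   0.24, 26,   59,  181),
    ("9",     "COUN", 2.0,  3.5,  19,   0.17, 83,   30,  100),
    ("10",    "COUN", 21,   19,   120,  2.12, 443,  92,  2045),
    ("11",    "COUN", 11,   21,   61,   3.29, 75,   52,  3974),
    ("11bis", "COUN", 10,   16,   58,   3.2,  365,  45,  3669),
    ("22",    "COUN", 3.4,  0.82, 20,   0.53, 32,   76,  471),
    ("23",    "COUN", 2.1,  2.9,  23,   0.19, 28,   77,  163),
    ("23bis", "COUN", 1.4,  8.5,  21,   0.15, 23,   68,  137),
    ("24",    "COUN", 6.6,  21.4, 30,   0.75, 60,   20,  478),
    ("25",    "COUN", 3.2,  0.63, 29,   0.23, 54,   89,  172),
    ("26",    "COUN", 5.0,  6.4,  58,   0.37, 51,   23,  347),
    ("27",    "COUN", 0.85, 0.63, 13,   0.10, 20,   20,  73),
    ("2",     "NOU",  26,   38,   133,  0.75, 822,  87,  299),
    ("3",     "NOU",  2.8,  5.6,  14,   0.22, 64,   28,  195),
    ("4",     "NOU",  0.84, 0.63, 4.8,  0.04, 24,   33,  32),
    ("5",     "NOU",  3.9,  3.8,  24,   0.17, 130,  103, 123),
    ("6",     "NOU",  1.8,  4.8,  13,   0.08, 64,   29,  33),
    ("7",     "NOU",  2.4,  0.63, 18,   0.11, 66,   67,  60),
    ("12",    "NOU",  15,   21,   51,   0.80, 238,  77,  761),
    ("13",    "NOU",  53,   9.2,  346,  2.02, 1981, 934, 939),
    ("14",    "NOU",  12,   2.4,  60,   0.45, 429,  69,  188),
    ("15",    "NOU",  100,  15,   319,  2.15, 4140, 153, 506),
    ("16",    "NOU",  130,  37,   1046, 4.67, 4536, 259, 1138),
    ("16bis", "NOU",  124,  23,   966,  4.35, 4246, 243, 1033),
    ("17",    "NOU",  15,   13,   86,   0.92, 427,  110, 711),
    ("18",    "NOU",  12,   8.4,  76,   0.49, 432,  63,  226),
    ("19",    "NOU",  50,   111,  400,  2.16, 1645, 238, 908),
    ("19bis", "NOU",  42,   91,   318,  1.85, 1462, 230, 696),
    ("20",    "NOU",  33,   9.2,  157,  0.94, 1344, 99,  201),
    ("28",    "PORO", 176,  2.4,  1612, 6.68, 3536, 147, 64),
    ("29",    "PORO", 14,   0.47, 111,  0.53, 204,  33,  10),
    ("30",    "PORO", 24,   52,   54,   1.37, 391,  36,  164),
    ("32",    "PORO", 323,  15,   1503, 6.15, 5216, 76,  69),
    ("32bis", "PORO", 294,  14,   1262, 6.48, 4725, 67,  61),
    ("33",    "PORO", 11,   66,   66,   1.84, 325,  30,  43),
    ("34",    "PORO", 0.31, 0.70, 12,   0.04, 12,   3,   3),
    ("35",    "PORO", 11,   0.76, 118,  0.48, 191,  49,  28),
    ("36",    "PORO", 64,   13,   565,  2.02, 949,  44,  28),
]

# synthetic area centroids (lat, lon): countryside, Noumea, Poro
_CENTROIDS = {"COUN": (-21.60, 165.80), "NOU": (-22.27, 166.44),
              "PORO": (-21.32, 165.70)}


def _synthetic_coords(ids, groups) -> pd.DataFrame:
    rng = np.random.default_rng(20160128)
    lat, lon = [], []
    for g in groups:
        c = _CENTROIDS[g]
        lat.append(c[0] + rng.normal(0, 0.05))
        lon.append(c[1] + rng.normal(0, 0.05))
    return pd.DataFrame({"lat": lat, "lon": lon}, index=list(ids))


def lichen_survey(coords: bool = True) -> ConcentrationTable:
    """The bundled 39-row survey, units as printed (Fe in %w/w)."""
    ids = [r[0] for r in _ROWS]
    groups = pd.Series([r[1] for r in _ROWS], index=ids, name="group")
    vals = pd.DataFrame([r[2:] for r in _ROWS], index=ids,
                        columns=list(ELEMENTS), dtype=float)
    c = _synthetic_coords(ids, groups.values) if coords else None
    return ConcentrationTable(vals, groups, PANEL, c)


def lichen_survey_csv() -> str:
    """The same survey as the wide-CSV text dialect read by survey_io."""
    t = lichen_survey()
    buf = io.StringIO()
    from .survey_io import write_concentrations
    write_concentrations(t, buf)
    return buf.getvalue()
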