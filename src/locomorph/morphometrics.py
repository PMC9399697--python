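"""Geometric-mean size correction of linear measurements.

Raw astragalar measurements confound size and shape.  Dividing each of a
specimen's measurements by their geometric mean (GM) and taking logs yields
log-shape ratios that are invariant to isometric size, while the GM itself
serves as a size proxy (reported as log10, "LogGM").  Analyses run at the
species level by default: specimen log-shape vectors are averaged per
species before any discriminant analysis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of locomotor categories (hind-limb-and-tail paddlers
#: only count as semi-aquatic; bipedal saltators are "ricochetal").
LOCOMOTOR_CLASSES = (
    "arboreal",
    "cursorial",
    "fossorial",
    "gliding",
    "ricochetal",
    "semi-aquatic",
    "semi-fossorial",
    "terrestrial",
)
UNKNOWN = "unknown"

#: Default abbreviations for the 15 retained astragalar measurements
#: (total/body/trochlear lengths, widths and heights, ectal, sustentacular
#: and head facet dimensions; the neck length is deliberately excluded as
#: hard to replicate).  The exact scheme is configurable via a column map.
MEASUREMENT_NAMES = (
    "ATL",   # astragalus total length
    "ATW",   # astragalus total width
    "ABW",   # astragalus body width
    "ATrW",  # trochlear width
    "LTL",   # lateral trochlear length
    "MTL",   # medial trochlear length
    "MBH",   # medial body height
    "LBH",   # lateral body height
    "EL",    # ectal facet length
    "EW",    # ectal facet width
    "SL",    # sustentacular facet length
    "SW",    # sustentacular facet width
    "HL",    # head length
    "HW",    # head width
    "CFW",   # calcaneofibular groove width
)

ID_COLUMNS = ("specimen_id", "species", "locomotion")


def _check_locomotion(label: str) -> str:
    if label not in LOCOMOTOR_CLASSES and label != UNKNOWN:
        raise ValueError(
            f"locomotion {label!r} not in {LOCOMOTOR_CLASSES + (UNKNOWN,)}"
        )
    return label


def load_measurements(
    path, column_map: dict | str | None = None
) -> pd.DataFrame:
    """Read a specimen-level measurement CSV.

    Expects one row per specimen with ``specimen_id``, ``species``,
    ``locomotion`` and 15 measurement columns.  ``column_map`` (dict or path
    to a JSON file mapping canonical name -> CSV header) lets alternative
    abbreviation schemes load cleanly.
    """
    df = pd.read_csv(path)
    if column_map is not None:
        if isinstance(column_map, (str, bytes)) or hasattr(column_map, "read_text"):
            with open(column_map) as fh:
                column_map = json.load(fh)
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return validate_measurements(df)


def validate_measurements(
    df: pd.DataFrame, columns: tuple[str, ...] = MEASUREMENT_NAMES
) -> pd.DataFrame:
    """Validate a measurement table; drop specimens with missing values.

    Non-positive measurements are a hard error (they cannot be a length);
    missing values exclude the specimen with a logged warning rather than
    imputing.
    """
    missing_cols = [c for c in ID_COLUMNS + tuple(columns) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"measurement table lacks columns {missing_cols}")
    for lab in df["locomotion"].unique():
        _check_locomotion(lab)
    m = df.loc[:, list(columns)]
    bad_na = m.isna().any(axis=1)
    if bad_na.any():
        dropped = df.loc[bad_na, "specimen_id"].tolist()
        warnings.warn(
            f"excluding {len(dropped)} specimen(s) with missing measurements: "
            f"{dropped}", stacklevel=2,
        )
        df = df.loc[~bad_na].reset_index(drop=True)
        m = df.loc[:, list(columns)]
    nonpos = (m <= 0) | ~np.isfinite(m)
    if nonpos.any().any():
        col = nonpos.any(axis=0).idxmax()
        row = df.loc[nonpos[col], "specimen_id"].iloc[0]
        raise ValueError(
            f"non-positive or non-finite measurement {col!r} for specimen {row!r}"
        )
    return df


def gm_normalize(
    df: pd.DataFrame, columns: tuple[str, ...] = MEASUREMENT_NAMES
) -> pd.DataFrame:
    """Log-shape ratios: ln(m_i / GM) per specimen.

    The GM is taken over the same set of measurements, so each row of the
    result sums to zero — equivalently the values are the mean-centred
    natural logs of the measurements.
    """
    df = validate_measurements(df, columns)
    logm = np.log(df.loc[:, list(columns)].to_numpy(float))
    shape = logm - logm.mean(axis=1, keepdims=True)
    out = df.loc[:, list(ID_COLUMNS)].copy()
    out[list(columns)] = shape
    return out


def size_gm(
    df: pd.DataFrame, columns: tuple[str, ...] = MEASUREMENT_NAMES
) -> pd.Series:
    """Specimen size proxy: log10 of the measurement geometric mean (mm).

    Reported as "LogGM"; base 10 so values are directly comparable to the
    printed size comparisons (e.g. a 10 mm-average astragalus has LogGM 1).
    """
    df = validate_measurements(df, columns)
    logm = np.log10(df.loc[:, list(columns)].to_numpy(float))
    return pd.Series(logm.mean(axis=1), index=df.index, name="LogGM")


@dataclass
class SpeciesMeans:
    """Per-species mean log-shape table used by all discriminant analyses."""

    values: pd.DataFrame            # species x 15, mean log-shape
    n: pd.Series                    # specimens per species
    locomotion: pd.Series           # one label per species
    columns: tuple[str, ...] = field(default=MEASUREMENT_NAMES)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path, sidecar: str | None = None) -> None:
        self.values.to_csv(path, index_label="species")
        if sidecar is not None:
            meta = {
                sp: {"n": int(self.n[sp]), "locomotion": self.locomotion[sp]}
                for sp in self.species
            }
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=1)


def species_means(
    shape_df: pd.DataFrame, columns: tuple[str, ...] = MEASUREMENT_NAMES
) -> SpeciesMeans:
    """Average specimen log-shape vectors within species.

    Raises if a species carries conflicting locomotion labels.
    """
    conflicts = shape_df.groupby("species")["locomotion"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise ValueError(
            f"conflicting locomotion labels within species: {list(bad.index)}"
        )
    grouped = shape_df.groupby("species", sort=True)
    values = grouped[list(columns)].mean()
    n = grouped.size().rename("n")
    locomotion = grouped["locomotion"].first()
    return SpeciesMeans(values=values, n=n, locomotion=locomotion, columns=tuple(columns))
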