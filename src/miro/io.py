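"""Reading and writing localization tables.

A localization table is a :class:`pandas.DataFrame` with columns

==============  =======================================================
``x``, ``y``    coordinates in nm (float)
``frame``       optional acquisition frame index (int)
``label``       optional cluster id; ``-1`` marks background/noise
``sublabel``    optional second clustering level (e.g. spots in rings)
``shape_class`` optional per-row structural class id
==============  =======================================================

Two CSV dialects are supported: ``plain`` (headers ``x,y``) and
``thunderstorm`` (headers ``"x [nm]","y [nm]"`` as produced by the
ThunderSTORM localizer).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd

__all__ = ["read_localizations", "write_localizations", "write_sidecar", "FormatError"]

OPTIONAL_COLUMNS = ("frame", "label", "sublabel", "shape_class")

_THUNDERSTORM_MAP = {"x [nm]": "x", "y [nm]": "y", "frame": "frame"}


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def read_localizations(path, dialect: str = "plain") -> pd.DataFrame:
    """Read a localization table from CSV.

    Parameters
    ----------
    path : str or Path
        CSV file to read.
    dialect : {'plain', 'thunderstorm'}
        Column-naming convention of the file.

    Returns
    -------
    pandas.DataFrame
        Table with at least ``x`` and ``y`` columns in nm.
    """
    if dialect not in ("plain", "thunderstorm"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if dialect == "thunderstorm":
        df = df.rename(columns=_THUNDERSTORM_MAP)
    missing = [c for c in ("x", "y") if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing coordinate column(s) {missing}; found {list(df.columns)}"
        )
    keep = ["x", "y"] + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    for c in ("label", "sublabel", "shape_class", "frame"):
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df


def write_localizations(table: pd.DataFrame, path, dialect: str = "plain") -> None:
    """Write a localization table to CSV in the given dialect."""
    if dialect not in ("plain", "thunderstorm"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = table.copy()
    if dialect == "thunderstorm":
        df = df.rename(columns={v: k for k, v in _THUNDERSTORM_MAP.items()})
    df.to_csv(path, index=False)


def write_sidecar(meta, path) -> None:
    """Write a JSON sidecar describing how a table was produced."""
    if is_dataclass(meta) and not isinstance(meta, type):
        meta = asdict(meta)
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
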