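"""Bundled reference tables of the example stroke cohort (n = 19).

Two fixture tables ship with the package: per-patient demographic and
lesion characteristics, and per-patient language test scores.  "NT" (not
tested) entries are kept as missing values, never coerced to zero, and
summary statistics use pairwise deletion over the tested patients only.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_demographics",
    "load_language_scores",
    "parse_time_post_onset",
    "table_summary",
]

_NA_VALUES = ["NT", ""]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("restdyn.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=_NA_VALUES)


def parse_time_post_onset(text: str) -> float:
    """Decimal years from strings like ``4y 1m``, ``7m`` or ``10y``
    (years + months / 12)."""
    if not isinstance(text, str):
        return float("nan")
    m = re.fullmatch(r"\s*(?:(\d+)\s*y)?\s*(?:(\d+)\s*m)?\s*", text)
    if m is None or (m.group(1) is None and m.group(2) is None):
        raise ValueError(f"cannot parse time post onset {text!r}")
    years = int(m.group(1) or 0)
    months = int(m.group(2) or 0)
    return years + months / 12.0


def load_demographics() -> pd.DataFrame:
    """Patient demographics/lesion table; adds a numeric
    ``time_post_onset_years`` column parsed from the y/m notation."""
    df = _read("patients_demographics.tsv")
    df["time_post_onset_years"] = df["time_post_onset"].map(parse_time_post_onset)
    return df

def load_language_scores() -> pd.DataFrame:
    """Per-patient language test scores (BNT, PPVT, NAVS, PALPA9, WAB);
    NaN marks tests that were not administered."""
    return _read("patients_language_scores.tsv")


def table_summary(table: pd.DataFrame, column: str, statistic: str = "mean") -> float:
    """Mean or SD (N-1) of a column over its non-missing entries.

    Raises KeyError for a missing column; returns NaN (with the count
    zero) only when every entry is missing.
    """
    if column not in table.columns:
        raise KeyError(f"no column {column!r}")
    values = pd.to_numeric(table[column], errors="coerce").dropna()
    if values.empty:
        return float("nan")
    if statistic == "mean":
        return float(values.mean())
    if statistic == "sd":
        return float(values.std(ddof=1)) if len(values) > 1 else float("nan")
    raise ValueError(f"unknown statistic {statistic!r}")
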