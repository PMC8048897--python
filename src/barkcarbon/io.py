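"""File formats and run configuration for the command-line tool.

Measurement CSV (header row, UTF-8, '.' decimal separator; comma, semicolon or tab
delimited — auto-detected):

    tree_id, species, dob_cm, reading_cm, reading_kind [, angle_deg, quadrant]

``reading_kind`` is 'gauge' (random/systematic points, estimates BT_f) or 'ridge'
(ridge points, estimates BT_max). ``dob_cm`` must be constant within a tree.

Inventory CSV for bark-carbon conversion (joined on tree_id):

    tree_id [, volume_m3 | basal_area_m2 + height_m + form_factor
            | biomass_kg | tree_carbon_kgc]
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator, Optional, Tuple

import pandas as pd
import yaml

from .errors import ConfigurationError, MeasurementParseError

__all__ = ["MeasurementTable", "RunConfig", "read_measurements", "write_measurements"]

REQUIRED_COLUMNS = ("tree_id", "species", "dob_cm", "reading_cm", "reading_kind")
OPTIONAL_COLUMNS = ("angle_deg", "quadrant")
READING_KINDS = ("gauge", "ridge")
_DELIMITERS = (",", ";", "\t")


@dataclass
class MeasurementTable:
    """Validated per-reading field measurements."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def iter_trees(self) -> Iterator[Tuple[str, str, float, pd.DataFrame]]:
        """Yield (tree_id, species, dob_cm, readings sub-frame) per tree, input order."""
        for tree_id in self.df["tree_id"].unique():
            sub = self.df[self.df["tree_id"] == tree_id]
            yield str(tree_id), str(sub["species"].iloc[0]), float(sub["dob_cm"].iloc[0]), sub


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for line in fh:
            if line.strip():
                counts = {d: line.count(d) for d in _DELIMITERS}
                best = max(counts, key=counts.get)
                return best if counts[best] > 0 else ","
    return ","


def read_measurements(path) -> MeasurementTable:
    """Read and validate a measurement CSV; all malformed rows are reported at once.

    Line numbers in error messages refer to the file (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise MeasurementParseError([f"file not found: {path}"])
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementParseError([f"missing required column(s): {', '.join(missing)}"])

    problems = []
    lines = df.index + 2  # header occupies line 1
    for col in ("dob_cm", "reading_cm", "angle_deg"):
        if col in df.columns:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & numeric.isna()
            for ln, raw in zip(lines[bad], df.loc[bad, col]):
                problems.append(f"line {ln}: non-numeric {col} {raw!r}")
            df[col] = numeric
    for ln in lines[df["dob_cm"].isna() | (df["dob_cm"] <= 0)]:
        problems.append(f"line {ln}: dob_cm must be a positive number")
    for ln in lines[df["reading_cm"].isna() | (df["reading_cm"] < 0)]:
        problems.append(f"line {ln}: reading_cm must be a non-negative number")
    kinds = df["reading_kind"].astype(str).str.strip().str.lower()
    for ln, raw in zip(lines[~kinds.isin(READING_KINDS)], df.loc[~kinds.isin(READING_KINDS), "reading_kind"]):
        problems.append(f"line {ln}: reading_kind must be one of {READING_KINDS}, got {raw!r}")
    df["reading_kind"] = kinds
    for tree_id, sub in df.groupby("tree_id", sort=False):
        if sub["dob_cm"].nunique(dropna=True) > 1:
            first = lines[sub.index[0]]
            problems.append(
                f"line {first}: tree {tree_id!r} has inconsistent dob_cm values "
                f"{sorted(sub['dob_cm'].dropna().unique())}"
            )
    if "quadrant" in df.columns:
        q = pd.to_numeric(df["quadrant"], errors="coerce")
        bad = df["quadrant"].notna() & (q.isna() | ~q.isin([1, 2, 3, 4]))
        for ln in lines[bad]:
            problems.append(f"line {ln}: quadrant must be 1-4 when given")
        df["quadrant"] = q
    if problems:
        raise MeasurementParseError(problems)
    return MeasurementTable(df=df.reset_index(drop=True))


def write_measurements(table: MeasurementTable, path) -> None:
    """Write a measurement table back to CSV (round-trips through read_measurements)."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.df.columns]
    table.df.to_csv(path, index=False, columns=cols, quoting=csv.QUOTE_MINIMAL)


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every CLI flag overrides the config file."""

    confidence: float = 0.95
    bt_max_rule: str = "ridge"  # 'ridge' | 'smooth_top3'
    bias_cm: float = 0.0
    clamp_bfi: bool = True
    decimals: int = 1
    seed: int = 20210114

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ConfigurationError(f"confidence must be in (0, 1), got {self.confidence}")
        if self.bt_max_rule not in ("ridge", "smooth_top3"):
            raise ConfigurationError(
                f"bt_max_rule must be 'ridge' or 'smooth_top3', got {self.bt_max_rule!r}"
            )
        if self.decimals < 0:
            raise ConfigurationError("decimals must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {path} must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        """New config with the non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self
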