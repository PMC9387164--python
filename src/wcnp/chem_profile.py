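"""GC-MS component profiles and Kováts retention indices.

A volatile-oil profile is a table of components, each with a relative
content (GC peak area percent, ``I``), an oral bioavailability fraction
(``OB``) and a retention time or retention index. Retention indices are
computed by linear interpolation of the retention time between the two
bracketing members of an n-alkane calibration ladder:

    RI = 100 * (Z + (Z' - Z) * (t_x - tR(Z)) / (tR(Z') - tR(Z)))

where ``Z`` and ``Z'`` are the carbon numbers of the alkanes eluting
immediately before and after the analyte. For consecutive alkanes
(Z' = Z + 1) this is the classical Kováts formula
``100*Z + 100*(t_x - tR(Z)) / (tR(Z+1) - tR(Z))``. The formula is an
interpolation: retention times outside the ladder range are an error,
never extrapolated.
"""

from __future__ import annotations

import bisect
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import OutOfRangeError, ParseError, ValidationError

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Trim, collapse internal whitespace and case-fold for uniqueness checks."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration series: (carbon_number, retention_time in minutes)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self):
        if len(self.entries) < 2:
            raise ValidationError("alkane ladder needs at least 2 entries")
        zs = [z for z, _ in self.entries]
        ts = [t for _, t in self.entries]
        if any(not isinstance(z, int) or z <= 0 for z in zs):
            raise ValidationError("carbon numbers must be positive integers")
        if any(not math.isfinite(t) or t <= 0 for t in ts):
            raise ValidationError("retention times must be finite and > 0")
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValidationError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("retention times must be strictly increasing")

    @property
    def retention_times(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.entries)

    @property
    def carbon_numbers(self) -> tuple[int, ...]:
        return tuple(z for z, _ in self.entries)

    @property
    def t_min(self) -> float:
        return self.entries[0][1]

    @property
    def t_max(self) -> float:
        return self.entries[-1][1]


@dataclass(frozen=True)
class Component:
    """One essential-oil constituent.

    ``area_pct`` is the relative content I on the 0-100 percent scale as
    printed in GC reports; ``oral_bioavailability`` is a fraction in [0, 1]
    and may be None (it must be supplied before weighting, never imputed).
    """

    name: str
    cas: str = ""
    retention_time: Optional[float] = None
    retention_index: Optional[float] = None
    area_pct: float = 0.0
    oral_bioavailability: Optional[float] = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise ValidationError("component name must be non-empty")
        if self.retention_time is None and self.retention_index is None:
            raise ValidationError(
                f"component {self.name!r}: need retention_time or retention_index"
            )
        if self.retention_time is not None and self.retention_time <= 0:
            raise ValidationError(f"component {self.name!r}: retention_time must be > 0")
        if self.retention_index is not None and self.retention_index < 0:
            raise ValidationError(f"component {self.name!r}: retention_index must be >= 0")
        if not (0.0 <= self.area_pct <= 100.0):
            raise ValidationError(
                f"component {self.name!r}: area_pct {self.area_pct} not in [0, 100]"
            )
        ob = self.oral_bioavailability
        if ob is not None and not (0.0 <= ob <= 1.0):
            raise ValidationError(f"component {self.name!r}: OB {ob} not in [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        """Identity used for uniqueness: normalized (name, CAS)."""
        return (normalize_name(self.name), self.cas.strip())


@dataclass(frozen=True)
class ComponentTable:
    components: tuple[Component, ...] = field(default_factory=tuple)

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for c in self.components:
            if c.key in seen:
                raise ValidationError(
                    f"duplicate component (name, CAS) pair: {c.key!r}"
                )
            seen.add(c.key)

    @property
    def total_area_pct(self) -> float:
        return float(sum(c.area_pct for c in self.components))

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def by_name(self, name: str) -> tuple[Component, ...]:
        """All rows sharing a normalized name (duplicates under different CAS)."""
        norm = normalize_name(name)
        return tuple(c for c in self.components if normalize_name(c.name) == norm)

    @property
    def names(self) -> frozenset[str]:
        return frozenset(normalize_name(c.name) for c in self.components)


def compute_retention_index(t_x: float, ladder: AlkaneLadder) -> float:
    """Kováts retention index of an analyte with retention time ``t_x``.

    Raises OutOfRangeError if ``t_x`` lies outside [min tR, max tR]
    (interpolation only). At a ladder member's retention time the result
    is exactly 100 * carbon_number.
    """
    if not math.isfinite(t_x):
        raise ValidationError(f"retention time must be finite, got {t_x!r}")
    ts = ladder.retention_times
    zs = ladder.carbon_numbers
    if t_x < ts[0] or t_x > ts[-1]:
        raise OutOfRangeError(
            f"t_x={t_x} outside ladder range [{ts[0]}, {ts[-1]}]; no extrapolation"
        )
    # largest index with tR <= t_x
    i = bisect.bisect_right(ts, t_x) - 1
    if ts[i] == t_x:
        return 100.0 * zs[i]
    frac = (t_x - ts[i]) / (ts[i + 1] - ts[i])
    return 100.0 * (zs[i] + (zs[i + 1] - zs[i]) * frac)


def annotate_table(table: ComponentTable, ladder: AlkaneLadder) -> ComponentTable:
    """Populate retention_index for every component lacking one.

    Supplied indices are preserved; the input table is not modified.
    Components whose retention time violates compute_retention_index
    preconditions are collected into a single aggregated error.
    """
    out: list[Component] = []
    failures: list[str] = []
    for c in table:
        if c.retention_index is not None:
            out.append(c)
            continue
        try:
            ri = compute_retention_index(c.retention_time, ladder)
        except (OutOfRangeError, ValidationError) as exc:
            failures.append(f"{c.name!r}: {exc}")
            continue
        out.append(replace(c, retention_index=ri))
    if failures:
        raise OutOfRangeError(
            "retention index failed for components: " + "; ".join(failures)
        )
    return ComponentTable(tuple(out))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

COMPONENT_COLUMNS = ["name", "cas", "retention_time", "retention_index", "area_pct", "ob"]
LADDER_COLUMNS = ["carbon_number", "retention_time"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_component_table(path, content_scale: str = "percent") -> ComponentTable:
    """Read a component table from CSV/TSV.

    Header: ``name,cas,retention_time,retention_index,area_pct,ob``; missing
    cells empty. ``content_scale='fraction'`` converts 0-1 contents to the
    canonical 0-100 percent scale.
    """
    path = Path(path)
    if content_scale not in {"percent", "fraction"}:
        raise ValidationError(f"unknown content_scale {content_scale!r}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype={"name": str, "cas": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read component table {path}: {exc}") from exc
    missing = {"name", "area_pct"} - set(df.columns)
    if missing:
        raise ParseError(f"component table {path} missing columns: {sorted(missing)}")
    comps = []
    for _, row in df.iterrows():
        area = float(row["area_pct"])
        if content_scale == "fraction":
            area *= 100.0
        comps.append(
            Component(
                name=str(row["name"]),
                cas="" if pd.isna(row.get("cas")) else str(row["cas"]),
                retention_time=_opt_float(row.get("retention_time")),
                retention_index=_opt_float(row.get("retention_index")),
                area_pct=area,
                oral_bioavailability=_opt_float(row.get("ob")),
            )
        )
    return ComponentTable(tuple(comps))


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def write_component_table(table: ComponentTable, path) -> None:
    path = Path(path)
    df = component_table_to_frame(table)
    df.to_csv(path, sep=_sep_for(path), index=False)


def component_table_to_frame(table: ComponentTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": c.name,
                "cas": c.cas,
                "retention_time": c.retention_time,
                "retention_index": c.retention_index,
                "area_pct": c.area_pct,
                "ob": c.oral_bioavailability,
            }
            for c in table
        ],
        columns=COMPONENT_COLUMNS,
    )


def read_alkane_ladder(path) -> AlkaneLadder:
    """Read a ladder from CSV/TSV with header ``carbon_number,retention_time``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot read alkane ladder {path}: {exc}") from exc
    missing = set(LADDER_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"ladder {path} missing columns: {sorted(missing)}")
    entries = tuple(
        (int(z), float(t))
        for z, t in zip(df["carbon_number"], df["retention_time"])
    )
    return AlkaneLadder(entries)


def write_alkane_ladder(ladder: AlkaneLadder, path) -> None:
    path = Path(path)
    pd.DataFrame(ladder.entries, columns=LADDER_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )
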