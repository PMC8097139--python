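"""Species-level stomatal trait tables: data model, validation, CSV I/O.

Units are fixed package-wide: stomatal density (sd) per mm^2, lengths (sl,
sw) in um, areas (ss, es) in um^2, stomatal index (si) in percent.  Any
conversion from other conventions happens before ingest.

Canonical CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory
header, columns in the order
``species,group,subgroup,sd_per_mm2,sl_um,sw_um,ss_um2,es_um2,si_pct``.
Blank cells encode absent values (never zeros).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SUBGROUPS",
    "CANONICAL_COLUMNS",
    "TraitFormatError",
    "TraitValidationError",
    "StomatalRecord",
    "TraitTable",
    "normalize_label",
    "read_trait_csv",
    "write_trait_csv",
    "complete_record",
    "complete_table",
]

logger = logging.getLogger(__name__)

GROUPS = ("pteridophyte", "gymnosperm", "angiosperm")
SUBGROUPS = ("magnoliid", "dicot", "monocot", "other")

CANONICAL_COLUMNS = (
    "species",
    "group",
    "subgroup",
    "sd_per_mm2",
    "sl_um",
    "sw_um",
    "ss_um2",
    "es_um2",
    "si_pct",
)

MANDATORY_COLUMNS = ("species", "group", "sd_per_mm2", "sl_um")

# CSV column name -> record attribute for the numeric fields
_NUMERIC_FIELDS = {
    "sd_per_mm2": "sd",
    "sl_um": "sl",
    "sw_um": "sw",
    "ss_um2": "ss",
    "es_um2": "es",
    "si_pct": "si",
}


class TraitFormatError(ValueError):
    """Malformed trait file (missing mandatory column, empty table...)."""


class TraitValidationError(ValueError):
    """A record violates the trait invariants."""


def normalize_label(label: str) -> str:
    """Normalize a taxon label: trim, collapse internal whitespace to '_'.

    This is the package-wide convention for matching species names to
    phylogeny tip labels.
    """
    return "_".join(label.split())


@dataclass(frozen=True)
class StomatalRecord:
    """One species' stomatal morphology.

    Numeric fields are ``None`` when absent.  ``derived_flags`` marks each
    numeric field as 'observed' or 'derived' (fields not in the mapping
    were never set).  Stomatal counts m and n are represented only through
    si = 100*m/(m+n); they are never stored individually.
    """

    species: str
    group: str
    sd: Optional[float] = None
    sl: Optional[float] = None
    sw: Optional[float] = None
    ss: Optional[float] = None
    es: Optional[float] = None
    si: Optional[float] = None
    subgroup: Optional[str] = None
    derived_flags: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`TraitValidationError` on any invariant violation."""
        if not self.species or not self.species.strip():
            raise TraitValidationError("species label must be non-empty")
        if self.group not in GROUPS:
            raise TraitValidationError(
                f"{self.species}: group {self.group!r} not one of {GROUPS}"
            )
        if self.subgroup is not None:
            if self.subgroup not in SUBGROUPS:
                raise TraitValidationError(
                    f"{self.species}: subgroup {self.subgroup!r} "
                    f"not one of {SUBGROUPS}"
                )
            if self.group != "angiosperm":
                raise TraitValidationError(
                    f"{self.species}: subgroup {self.subgroup!r} only "
                    "allowed under group 'angiosperm'"
                )
        for name in ("sd", "sl", "sw", "ss", "es", "si"):
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value) or value <= 0:
                raise TraitValidationError(
                    f"{self.species}: {name} must be finite and positive, "
                    f"got {value}"
                )
        if self.si is not None and self.si >= 100:
            raise TraitValidationError(
                f"{self.species}: si must be < 100, got {self.si}"
            )


@dataclass
class TraitTable:
    """An ordered collection of :class:`StomatalRecord` with provenance."""

    records: list
    source_label: str = ""
    n_dropped: int = 0  # rows discarded during lenient ingest

    def __post_init__(self) -> None:
        if not self.records:
            raise TraitFormatError("a trait table needs at least one record")
        seen = set()
        for rec in self.records:
            if rec.species in seen:
                raise TraitValidationError(
                    f"duplicate species label {rec.species!r}"
                )
            seen.add(rec.species)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (absent values as NaN)."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "species": rec.species,
                    "group": rec.group,
                    "subgroup": rec.subgroup,
                    "sd_per_mm2": rec.sd,
                    "sl_um": rec.sl,
                    "sw_um": rec.sw,
                    "ss_um2": rec.ss,
                    "es_um2": rec.es,
                    "si_pct": rec.si,
                }
            )
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        for col in _NUMERIC_FIELDS:
            df[col] = pd.to_numeric(df[col])
        return df


def _row_to_record(row: pd.Series, present_cols: Iterable[str]) -> StomatalRecord:
    def cell(col):
        if col not in present_cols:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        if isinstance(v, str) and not v.strip():
            return None
        return v

    species = cell("species")
    if species is None:
        raise TraitValidationError("species label must be non-empty")
    numeric = {}
    flags = {}
    for col, attr in _NUMERIC_FIELDS.items():
        v = cell(col)
        if v is None:
            continue
        try:
            numeric[attr] = float(v)
        except (TypeError, ValueError):
            raise TraitValidationError(
                f"{species}: non-numeric value {v!r} in column {col}"
            ) from None
        flags[attr] = "observed"
    rec = StomatalRecord(
        species=normalize_label(str(species)),
        group=str(cell("group") or "").strip(),
        subgroup=(str(cell("subgroup")).strip() if cell("subgroup") else None),
        derived_flags=flags,
        **numeric,
    )
    rec.validate()
    return rec


def read_trait_csv(path, strict: bool = True, source_label: str = "") -> TraitTable:
    """Read a trait table from the canonical CSV dialect.

    Parameters
    ----------
    path
        CSV file with at least the columns species, group, sd_per_mm2,
        sl_um.  Unknown columns are ignored with a warning.
    strict
        If True (default) any invalid row raises; if False invalid rows
        are dropped with a warning and counted in ``table.n_dropped``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TraitFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    unknown = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", path, unknown)
    present = [c for c in df.columns if c in CANONICAL_COLUMNS]

    records, n_dropped = [], 0
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_row_to_record(row, present))
        except TraitValidationError as exc:
            if strict:
                raise TraitValidationError(f"row {i + 2}: {exc}") from exc
            n_dropped += 1
            logger.warning("%s: dropping row %d: %s", path, i + 2, exc)
    if not records:
        raise TraitFormatError(f"{path}: no valid records")
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    return TraitTable(
        records=records,
        source_label=source_label or str(path),
        n_dropped=n_dropped,
    )


def write_trait_csv(table: TraitTable, path) -> None:
    """Write a table in the canonical dialect; absent fields become blanks.

    ``read_trait_csv(write_trait_csv(t))`` preserves every value.
    """
    df = table.to_dataframe()
    # repr-based float formatting keeps the round-trip bit-exact
    df.to_csv(path, index=False, float_format=None, na_rep="")


def complete_record(rec: StomatalRecord, params=None) -> StomatalRecord:
    """Fill in derivable morphology: sw from sl, then ss from sl and sw.

    Uses sw = width_ratio * sl when width is absent and the plan-area
    approximation ss = (pi/2) * sl * sw.  Observed values are never
    overwritten; derived fields are flagged.  Idempotent.
    """
    from .geometry import GeometricParams  # deferred: geometry imports traitio

    if params is None:
        params = GeometricParams()
    if rec.sl is None:
        raise TraitValidationError(
            f"{rec.species}: cannot derive sw/ss without sl"
        )
    changes = {}
    flags = dict(rec.derived_flags)
    sw = rec.sw
    if sw is None:
        sw = params.width_ratio * rec.sl
        changes["sw"] = sw
        flags["sw"] = "derived"
    if rec.ss is None:
        changes["ss"] = (np.pi / 2.0) * rec.sl * sw
        flags["ss"] = "derived"
    if not changes:
        return rec
    return replace(rec, derived_flags=flags, **changes)


def complete_table(table: TraitTable, params=None) -> TraitTable:
    """Apply :func:`complete_record` to every record that has sl."""
    out = []
    for rec in table.records:
        out.append(complete_record(rec, params) if rec.sl is not None else rec)
    return TraitTable(
        records=out, source_label=table.source_label, n_dropped=table.n_dropped
    )
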