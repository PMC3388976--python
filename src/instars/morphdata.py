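"""Data model and CSV I/O for morphometric measurement tables.

A specimen table holds one row per (specimen, character) pair: a stage
label (egg / embryo / larva / prepupa / pupa), a measured character and
its value in millimetres.  Synthetic tables may additionally carry a
``true_instar`` column; it is plumbing for validation only and is never
read by any inference operation.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

REQUIRED_COLUMNS = ("specimen_id", "stage", "character", "value_mm")

#: Sanity bound in mm; every measured dimension of these ants is well below this.
MAX_VALUE_MM = 10.0


class Stage(str, enum.Enum):
    """Developmental stage of a specimen."""

    EGG = "egg"
    EMBRYO = "embryo"  # mature embryo measured through the egg chorion
    LARVA = "larva"
    PREPUPA = "prepupa"  # last-instar larva with the pupa showing within
    PUPA = "pupa"


class Character(str, enum.Enum):
    """Measured morphometric character."""

    HEAD_WIDTH = "head_width"
    BODY_LENGTH = "body_length"
    BODY_WIDTH = "body_width"
    MANDIBLE_LENGTH = "mandible_length"
    SPIRACLE_DIAMETER = "spiracle_diameter"
    LENGTH_THROUGH_SPIRACLES = "length_through_spiracles"
    EGG_LENGTH = "egg_length"
    EGG_WIDTH = "egg_width"
    PUPA_LENGTH = "pupa_length"


#: Stages on which each character may legitimately be measured.
CHARACTER_STAGES: dict[Character, frozenset[Stage]] = {
    Character.EGG_LENGTH: frozenset({Stage.EGG}),
    Character.EGG_WIDTH: frozenset({Stage.EGG}),
    Character.HEAD_WIDTH: frozenset({Stage.LARVA, Stage.EMBRYO, Stage.PREPUPA}),
    Character.PUPA_LENGTH: frozenset({Stage.PUPA}),
    Character.BODY_LENGTH: frozenset({Stage.LARVA, Stage.PREPUPA}),
    Character.BODY_WIDTH: frozenset({Stage.LARVA, Stage.PREPUPA}),
    Character.MANDIBLE_LENGTH: frozenset({Stage.LARVA, Stage.PREPUPA}),
    Character.SPIRACLE_DIAMETER: frozenset({Stage.LARVA, Stage.PREPUPA}),
    Character.LENGTH_THROUGH_SPIRACLES: frozenset({Stage.LARVA, Stage.PREPUPA}),
}


@dataclass(frozen=True)
class MeasurementRecord:
    """One morphometric value for one specimen.

    Parameters
    ----------
    specimen_id : str
        Opaque specimen identifier.
    stage : Stage
        Developmental stage.
    character : Character
        Which dimension was measured.
    value_mm : float
        Measured value in millimetres; must be positive and < 10 mm.
    true_instar : int, optional
        Hidden ground-truth instar (synthetic populations only).
    """

    specimen_id: str
    stage: Stage
    character: Character
    value_mm: float
    true_instar: Optional[int] = None


@dataclass(frozen=True)
class Violation:
    """One validation failure: which record broke which rule."""

    index: int
    specimen_id: str
    rule: str
    message: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class SpecimenTable:
    """Ordered collection of measurement records backed by a DataFrame.

    Columns: ``specimen_id, stage, character, value_mm`` and optionally
    ``true_instar`` (nullable integer).  Row order is preserved through
    I/O round trips.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        df = df.reset_index(drop=True).copy()
        if "true_instar" not in df.columns:
            df["true_instar"] = pd.array([pd.NA] * len(df), dtype="Int64")
        else:
            df["true_instar"] = df["true_instar"].astype("Int64")
        df["value_mm"] = df["value_mm"].astype(float)
        self._df = df[list(REQUIRED_COLUMNS) + ["true_instar"]]
        self.provenance = provenance

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[MeasurementRecord], provenance: str = ""
    ) -> "SpecimenTable":
        rows = [
            {
                "specimen_id": r.specimen_id,
                "stage": Stage(r.stage).value,
                "character": Character(r.character).value,
                "value_mm": float(r.value_mm),
                "true_instar": r.true_instar if r.true_instar is not None else pd.NA,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["true_instar"])
        return cls(df, provenance=provenance)

    def to_records(self) -> list[MeasurementRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            out.append(
                MeasurementRecord(
                    specimen_id=row.specimen_id,
                    stage=Stage(row.stage),
                    character=Character(row.character),
                    value_mm=float(row.value_mm),
                    true_instar=None if pd.isna(row.true_instar) else int(row.true_instar),
                )
            )
        return out

    # -- accessors -------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (a defensive copy)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpecimenTable):
            return NotImplemented
        return self._df.equals(other._df)

    def values_for(
        self, character: Character | str, stages: Iterable[Stage | str] | None = None
    ) -> np.ndarray:
        """Values (mm) of one character, optionally restricted to stages."""
        character = Character(character).value
        mask = self._df["character"] == character
        if stages is not None:
            stage_vals = {Stage(s).value for s in stages}
            mask &= self._df["stage"].isin(stage_vals)
        return self._df.loc[mask, "value_mm"].to_numpy(dtype=float)

    def head_widths(self, stages: Iterable[Stage | str] = (Stage.LARVA,)) -> np.ndarray:
        """Head-capsule widths for the given stages (default: larvae)."""
        return self.values_for(Character.HEAD_WIDTH, stages)

    def true_instars(self, character: Character | str = Character.HEAD_WIDTH) -> np.ndarray:
        """Hidden ground-truth instars aligned with larval rows of ``character``.

        For synthetic-data validation only; inference never calls this.
        """
        character = Character(character).value
        mask = (self._df["character"] == character) & (self._df["stage"] == Stage.LARVA.value)
        vals = self._df.loc[mask, "true_instar"]
        return vals.to_numpy(dtype=float)


def validate_table(table: SpecimenTable) -> list[Violation]:
    """Check every type invariant; return one Violation per breach.

    Side-effect free and idempotent.  An empty report means the table is
    valid.
    """
    violations: list[Violation] = []
    df = table._df
    if len(df) == 0:
        violations.append(Violation(-1, "", "non_empty", "table contains no records"))
        return violations

    stage_values = {s.value for s in Stage}
    char_values = {c.value for c in Character}
    for idx, row in enumerate(df.itertuples(index=False)):
        sid = str(row.specimen_id)
        if row.stage not in stage_values:
            violations.append(
                Violation(idx, sid, "stage_vocabulary", f"unknown stage {row.stage!r}")
            )
            continue
        if row.character not in char_values:
            violations.append(
                Violation(idx, sid, "character_vocabulary", f"unknown character {row.character!r}")
            )
            continue
        value = row.value_mm
        if not np.isfinite(value) or value <= 0:
            violations.append(
                Violation(idx, sid, "positive_value", f"value_mm={value!r} is not positive")
            )
        elif value >= MAX_VALUE_MM:
            violations.append(
                Violation(
                    idx, sid, "sanity_bound", f"value_mm={value!r} exceeds {MAX_VALUE_MM} mm"
                )
            )
        allowed = CHARACTER_STAGES[Character(row.character)]
        if Stage(row.stage) not in allowed:
            violations.append(
                Violation(
                    idx,
                    sid,
                    "stage_character_consistency",
                    f"character {row.character!r} not measurable on stage {row.stage!r}",
                )
            )
        if not pd.isna(row.true_instar) and int(row.true_instar) < 1:
            violations.append(
                Violation(idx, sid, "true_instar_positive", f"true_instar={row.true_instar}")
            )

    dup = df.duplicated(subset=["specimen_id", "character"], keep="first")
    for idx in np.flatnonzero(dup.to_numpy()):
        violations.append(
            Violation(
                int(idx),
                str(df.iloc[int(idx)]["specimen_id"]),
                "unique_specimen_character",
                "duplicate (specimen_id, character) pair",
            )
        )
    return violations


def report_to_json(violations: list[Violation]) -> str:
    """Serialize a validation report to JSON."""
    return json.dumps([v.to_dict() for v in violations], indent=2)


def read_measurements(path, *, sep: str = ",", validate: bool = True) -> SpecimenTable:
    """Read a measurement CSV into a validated SpecimenTable.

    The file must have a header with columns ``specimen_id, stage,
    character, value_mm`` (``true_instar`` optional).  Raises
    :class:`FormatError` on missing columns, :class:`ValidationError`
    with the 1-based line number on unparseable numerics, and
    :class:`EmptyInputError` on an empty file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows after header")

    values = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df["value_mm"].tolist()):
        try:
            values[i] = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path}, line {i + 2}: value_mm={raw!r} is not a number"
            ) from None
    out = df[["specimen_id", "stage", "character"]].copy()
    out["value_mm"] = values
    if "true_instar" in df.columns:
        ti = [pd.NA if v.strip() == "" else int(float(v)) for v in df["true_instar"].tolist()]
        out["true_instar"] = pd.array(ti, dtype="Int64")
    table = SpecimenTable(out, provenance=str(path))
    if validate:
        violations = validate_table(table)
        if violations:
            head = "; ".join(f"[row {v.index}] {v.rule}: {v.message}" for v in violations[:5])
            raise ValidationError(f"{path}: {len(violations)} invalid record(s): {head}")
    return table


def write_measurements(table: SpecimenTable, path) -> None:
    """Write a SpecimenTable to CSV (values at 9 significant digits)."""
    path = Path(path)
    df = table.df
    df["value_mm"] = [f"{v:.9g}" for v in df["value_mm"]]
    df["true_instar"] = df["true_instar"].astype(object).where(df["true_instar"].notna(), "")
    df.to_csv(path, index=False)
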