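"""Per-instar morphometric summaries, classification and the character key.

Stage 3 of the analysis: once larvae carry instar labels, every
measured character is summarized per instar (mean ± SD, min–max, n) in
the style of the published description; new specimens can then be
classified from their measurements by a naive-Bayes Gaussian score, or
diagnosed from qualitative characters (hair types, hair counts,
mandible sclerotization) via the built-in character key.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DiagnosabilityError, ValidationError, VocabularyError
from .morphdata import Character, SpecimenTable, Stage

#: Floor (mm) for a reference SD when scoring, matching the measurement
#: quantization; a zero-SD group would otherwise give degenerate scores.
SCORE_SD_FLOOR = 1e-3


@dataclass(frozen=True)
class InstarSummary:
    """Descriptive statistics of one character within one instar (mm)."""

    instar: int
    character: Character
    n: int
    mean: float
    sd: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {
            "instar": self.instar,
            "character": Character(self.character).value,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
        }

    def paper_style(self) -> str:
        """'mean ± SD mm, varying min – max mm' presentation string."""
        return (
            f"{self.mean:.3f} ± {self.sd:.3f} mm, "
            f"varying {self.min:.3f} – {self.max:.3f} mm (n = {self.n})"
        )


def summarize_instars(
    table: SpecimenTable,
    labels: Union[Mapping[str, int], pd.Series],
) -> list[InstarSummary]:
    """Per-(instar, character) descriptive statistics of labeled larvae.

    ``labels`` maps specimen_id to an instar label (dict or Series).
    SD uses the n−1 divisor (0.0 for singleton groups).  Unlabeled
    larvae or empty groups are dropped with a warning rather than
    raising.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    df = table.df
    larvae = df[df["stage"] == Stage.LARVA.value].copy()
    if larvae.empty:
        warnings.warn("table contains no larval records; summary is empty")
        return []
    larvae["instar"] = larvae["specimen_id"].map(labels)
    unlabeled = larvae["instar"].isna()
    if unlabeled.any():
        warnings.warn(
            f"{int(unlabeled.sum())} larval record(s) without an instar label were dropped"
        )
        larvae = larvae[~unlabeled]
    out: list[InstarSummary] = []
    for (instar, character), grp in larvae.groupby(["instar", "character"], sort=True):
        vals = grp["value_mm"].to_numpy(dtype=float)
        out.append(
            InstarSummary(
                instar=int(instar),
                character=Character(character),
                n=int(vals.size),
                mean=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                min=float(np.min(vals)),
                max=float(np.max(vals)),
            )
        )
    out.sort(key=lambda s: (s.instar, s.character.value))
    return out


def summaries_to_frame(summaries: Iterable[InstarSummary]) -> pd.DataFrame:
    """Summaries as a tidy DataFrame (instar, character, n, mean, sd, min, max)."""
    return pd.DataFrame([s.to_dict() for s in summaries])


def dimension_ratio(numerator_mean: float, denominator_mean: float) -> float:
    """Ratio of two mean dimensions (e.g. egg length : width)."""
    if denominator_mean <= 0:
        raise ValidationError(
            f"denominator mean must be positive, got {denominator_mean}"
        )
    return numerator_mean / denominator_mean


def classify_specimen(
    measurements: Mapping[Union[Character, str], float],
    summaries: Sequence[InstarSummary],
) -> tuple[int, dict[int, float]]:
    """Classify one specimen from its measurements against reference summaries.

    The score of instar i is the product over shared characters of the
    normal density at that instar's (mean, sd); characters are treated
    as conditionally independent given the instar.  Returns
    (argmax label, score per instar); ties break toward the lower
    instar.
    """
    measurements = {Character(c): float(v) for c, v in measurements.items()}
    ref: dict[int, dict[Character, InstarSummary]] = {}
    for s in summaries:
        ref.setdefault(s.instar, {})[Character(s.character)] = s
    log_scores: dict[int, float] = {}
    for instar in sorted(ref):
        shared = [c for c in measurements if c in ref[instar]]
        if not shared:
            continue
        total = 0.0
        for c in shared:
            s = ref[instar][c]
            sd = max(s.sd, SCORE_SD_FLOOR)
            z = (measurements[c] - s.mean) / sd
            total += -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)
        log_scores[instar] = total
    if not log_scores:
        raise DiagnosabilityError(
            "specimen shares no measured character with the reference summaries"
        )
    scores = {i: math.exp(ls) for i, ls in log_scores.items()}
    best = max(sorted(log_scores), key=lambda i: (log_scores[i], -i))
    return best, scores


# ---------------------------------------------------------------------------
# Qualitative character key
# ---------------------------------------------------------------------------

HAIR_TYPES = frozenset({"A", "B", "C", "D", "E"})
SCLEROTIZATION_LEVELS = frozenset({"none", "weak", "moderate"})

#: Qualitative observation vocabulary accepted by diagnose_by_characters.
OBSERVATION_VOCABULARY = frozenset(
    {"hair_type_present", "body_hair_count", "head_hair_count", "mandible_sclerotization"}
)


@dataclass(frozen=True)
class KeyRow:
    """Qualitative character states of one instar."""

    hair_types: frozenset
    body_hair_count: tuple[int, int]
    head_hair_count: int
    mandible_sclerotization: frozenset
    notes: str = ""

    def __post_init__(self):
        if self.body_hair_count[0] > self.body_hair_count[1]:
            raise ValidationError("body_hair_count interval is empty")


@dataclass(frozen=True)
class CharacterKey:
    """Instar × qualitative-character matrix."""

    rows: Mapping[int, KeyRow]
    hair_type_glossary: Mapping[str, str] = field(default_factory=dict)

    @property
    def instars(self) -> list[int]:
        return sorted(self.rows)


def default_character_key() -> CharacterKey:
    """The built-in three-instar key.

    First-instar mandibles are described both as weakly sclerotized and
    as completely unsclerotised in different parts of the source
    description; the key accepts either phrasing for instar 1.  Hair
    types C/D/E occur in both later instars and therefore do not
    discriminate between them; body-hair counts do.
    """
    return CharacterKey(
        rows={
            1: KeyRow(
                hair_types=frozenset({"A", "B"}),
                body_hair_count=(300, 400),
                head_hair_count=26,
                mandible_sclerotization=frozenset({"none", "weak"}),
                notes="mostly simple type-A hairs; mandibles effectively unsclerotised",
            ),
            2: KeyRow(
                hair_types=frozenset({"B", "C", "D", "E"}),
                body_hair_count=(400, 500),
                head_hair_count=26,
                mandible_sclerotization=frozenset({"moderate"}),
            ),
            3: KeyRow(
                hair_types=frozenset({"B", "C", "D", "E"}),
                body_hair_count=(500, 600),
                head_hair_count=26,
                mandible_sclerotization=frozenset({"moderate"}),
            ),
        },
        hair_type_glossary={
            "A": "simple, unbranched",
            "B": "denticulate bifid",
            "C": "curved bifid",
            "D": "multifid",
            "E": "unbranched denticulate",
        },
    )


def _row_consistent(row: KeyRow, name: str, value) -> bool:
    if name == "hair_type_present":
        values = {value} if isinstance(value, str) else set(value)
        bad = values - HAIR_TYPES
        if bad:
            raise VocabularyError(f"unknown hair type(s): {sorted(bad)}")
        return values <= row.hair_types
    if name == "body_hair_count":
        lo, hi = row.body_hair_count
        return lo <= float(value) <= hi
    if name == "head_hair_count":
        return int(value) == row.head_hair_count
    if name == "mandible_sclerotization":
        if value not in SCLEROTIZATION_LEVELS:
            raise VocabularyError(
                f"unknown sclerotization level {value!r}; "
                f"expected one of {sorted(SCLEROTIZATION_LEVELS)}"
            )
        return value in row.mandible_sclerotization
    raise VocabularyError(f"unknown qualitative character {name!r}")


def diagnose_by_characters(
    observations: Mapping[str, object],
    key: Optional[CharacterKey] = None,
) -> set[int]:
    """Instars compatible with ALL qualitative observations.

    Monotone: adding an observation can only shrink the result.  An
    empty set means the observations are mutually inconsistent under
    the key.
    """
    if key is None:
        key = default_character_key()
    unknown = set(observations) - OBSERVATION_VOCABULARY
    if unknown:
        raise VocabularyError(
            f"unknown character name(s): {sorted(unknown)}; "
            f"vocabulary: {sorted(OBSERVATION_VOCABULARY)}"
        )
    compatible = set()
    for instar, row in key.rows.items():
        if all(_row_consistent(row, name, value) for name, value in observations.items()):
            compatible.add(instar)
    return compatible
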