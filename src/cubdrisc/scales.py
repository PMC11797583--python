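"""Scoring tables for the FINDRISC family of diabetes risk questionnaires.

The Finnish Diabetes Risk Score (FINDRISC) is an eight-item additive
questionnaire — age, body-mass index, waist circumference, daily physical
activity, daily fruit/vegetable consumption, antihypertensive medication,
history of high blood glucose, and family history of diabetes — whose total
runs from 0 to 26 points and maps to five 10-year diabetes-risk categories.
The Latin-American (LA-FINDRISC) and Cuban (CUBDRISC) variants keep seven of
the eight items identical and replace only the waist-circumference bands with
region-specific abdominal-obesity cut-points.

This module encodes the three scoring tables, scores individual participants
or whole tabular cohorts, and maps totals to risk categories.  Scale
definitions round-trip through JSON so national variants can be registered
without code changes.
"""
from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleName",
    "Sex",
    "FamilyHistory",
    "RiskCategory",
    "ParticipantRecord",
    "Band",
    "ScaleDefinition",
    "ScoreResult",
    "MissingItemError",
    "build_scale",
    "score_participant",
    "score_frame",
    "risk_category",
    "max_score",
    "read_participants",
    "write_participants",
    "PARTICIPANT_COLUMNS",
]


class ScaleName(str, enum.Enum):
    """The three questionnaire variants."""

    __str__ = str.__str__

    FINDRISC = "FINDRISC"
    LA_FINDRISC = "LA_FINDRISC"
    CUBDRISC = "CUBDRISC"


class Sex(str, enum.Enum):
    __str__ = str.__str__
    MAN = "M"
    WOMAN = "W"


class FamilyHistory(str, enum.Enum):
    """Closest diagnosed relative with diabetes (gestational diabetes in a
    spouse counts as second degree)."""

    __str__ = str.__str__

    NONE = "none"
    SECOND_DEGREE = "second_degree"
    FIRST_DEGREE = "first_degree"


class RiskCategory(str, enum.Enum):
    __str__ = str.__str__
    LOW = "low"
    SLIGHTLY_ELEVATED = "slightly_elevated"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"


#: Ten-year probability (%) of developing type 2 diabetes, as reported for
#: each risk category.  These are labels attached to score bands, not a model.
TEN_YEAR_RISK_PCT: dict[RiskCategory, int] = {
    RiskCategory.LOW: 1,
    RiskCategory.SLIGHTLY_ELEVATED: 4,
    RiskCategory.MODERATE: 17,
    RiskCategory.HIGH: 33,
    RiskCategory.VERY_HIGH: 50,
}


class MissingItemError(ValueError):
    """A questionnaire item needed for scoring is absent from the record."""

    def __init__(self, item: str) -> None:
        self.item = item
        super().__init__(f"questionnaire item {item!r} is missing; scoring requires all eight items")


@dataclass(frozen=True)
class ParticipantRecord:
    """One screened adult: the eight questionnaire items plus the OGTT pair.

    ``bmi`` may be given directly or derived from ``height_m``/``weight_kg``
    (weight / height², unrounded); an explicit ``bmi`` takes precedence.
    Glucose values are optional — records without an OGTT can be scored but
    not classified.
    """

    id: str
    age: int
    sex: Sex
    waist_cm: float
    physical_activity: bool
    daily_fruit_veg: bool
    antihypertensive_meds: bool
    history_high_glucose: bool
    family_history: FamilyHistory
    bmi: float | None = None
    height_m: float | None = None
    weight_kg: float | None = None
    fpg_mmol: float | None = None
    g2h_mmol: float | None = None

    def __post_init__(self) -> None:
        if int(self.age) != self.age or self.age < 19:
            raise ValueError(f"age must be an integer ≥ 19 years, got {self.age!r}")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if self.waist_cm is not None and self.waist_cm <= 0:
            raise ValueError(f"waist_cm must be positive, got {self.waist_cm}")
        for name in ("height_m", "weight_kg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("fpg_mmol", "g2h_mmol"):
            v = getattr(self, name)
            if v is not None and not (0 < v < 50):
                raise ValueError(f"{name} must lie in (0, 50) mmol/L, got {v}")

    @property
    def effective_bmi(self) -> float:
        """BMI in kg/m²: the explicit value, else weight / height²."""
        if self.bmi is not None:
            return float(self.bmi)
        if self.height_m is not None and self.weight_kg is not None:
            return self.weight_kg / self.height_m**2
        raise MissingItemError("bmi")


@dataclass(frozen=True)
class Band:
    """One scoring band: a (possibly half-open) interval and its points.

    ``None`` bounds are open ends.  Inclusivity flags express the table's
    wording: "25 - 30" is closed on both ends while the neighbouring
    "lower than 25" / "higher than 30" exclude the shared boundary.
    """

    lower: float | None
    upper: float | None
    points: int
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError("band points must be non-negative")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"band lower bound {self.lower} exceeds upper bound {self.upper}")

    def contains(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (value == self.lower and not self.lower_inclusive):
                return False
        if self.upper is not None:
            if value > self.upper or (value == self.upper and not self.upper_inclusive):
                return False
        return True

    def contains_array(self, values: np.ndarray) -> np.ndarray:
        mask = np.ones(values.shape, dtype=bool)
        if self.lower is not None:
            mask &= values >= self.lower if self.lower_inclusive else values > self.lower
        if self.upper is not None:
            mask &= values <= self.upper if self.upper_inclusive else values < self.upper
        return mask

    def to_json_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "points": self.points,
            "lower_inclusive": self.lower_inclusive,
            "upper_inclusive": self.upper_inclusive,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "Band":
        return cls(
            lower=d["lower"],
            upper=d["upper"],
            points=int(d["points"]),
            lower_inclusive=bool(d.get("lower_inclusive", True)),
            upper_inclusive=bool(d.get("upper_inclusive", True)),
        )


def _band_points(bands: Sequence[Band], value: float, item: str) -> int:
    for b in bands:
        if b.contains(value):
            return b.points
    raise ValueError(f"value {value!r} falls outside every band of item {item!r}")


def _band_points_array(bands: Sequence[Band], values: np.ndarray, item: str) -> np.ndarray:
    pts = np.full(values.shape, -1, dtype=np.int64)
    for b in bands:
        mask = (pts < 0) & b.contains_array(values)
        pts[mask] = b.points
    if (pts < 0).any():
        bad = values[pts < 0][0]
        raise ValueError(f"value {bad!r} falls outside every band of item {item!r}")
    return pts


#: The five fixed-point items shared by all three scales (Table-style wording:
#: points are earned by the risk-carrying answer; the protective answer is 0).
FIXED_ITEM_POINTS: dict[str, int] = {
    "physical_activity_no": 2,
    "fruit_veg_not_daily": 1,
    "antihypertensive_meds_yes": 2,
    "history_high_glucose_yes": 5,
    "family_history_second_degree": 3,
    "family_history_first_degree": 5,
}

ITEM_NAMES = (
    "age",
    "bmi",
    "waist",
    "physical_activity",
    "daily_fruit_veg",
    "antihypertensive_meds",
    "history_high_glucose",
    "family_history",
)


@dataclass(frozen=True)
class ScaleDefinition:
    """A complete scoring table: banded items plus fixed-point items."""

    name: str
    age_bands: tuple[Band, ...]
    bmi_bands: tuple[Band, ...]
    wc_bands_by_sex: Mapping[Sex, tuple[Band, ...]]
    fixed_item_points: Mapping[str, int] = field(
        default_factory=lambda: dict(FIXED_ITEM_POINTS)
    )

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "age_bands": [b.to_json_dict() for b in self.age_bands],
            "bmi_bands": [b.to_json_dict() for b in self.bmi_bands],
            "wc_bands_by_sex": {
                sex.value: [b.to_json_dict() for b in bands]
                for sex, bands in self.wc_bands_by_sex.items()
            },
            "fixed_item_points": dict(self.fixed_item_points),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ScaleDefinition":
        return cls(
            name=d["name"],
            age_bands=tuple(Band.from_json_dict(b) for b in d["age_bands"]),
            bmi_bands=tuple(Band.from_json_dict(b) for b in d["bmi_bands"]),
            wc_bands_by_sex={
                Sex(sex): tuple(Band.from_json_dict(b) for b in bands)
                for sex, bands in d["wc_bands_by_sex"].items()
            },
            fixed_item_points=dict(d["fixed_item_points"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "ScaleDefinition":
        return cls.from_json_dict(json.loads(s))


@dataclass(frozen=True)
class ScoreResult:
    scale: str
    per_item_points: Mapping[str, int]
    total: int
    category: RiskCategory
    ten_year_risk_pct: int


# Age and BMI bands are identical across the three scales; ages are integer
# years so the <45 / 45–54 / 55–64 / ≥65 bands tile the domain.
_AGE_BANDS = (
    Band(None, 45, 0, upper_inclusive=False),
    Band(45, 54, 2),
    Band(55, 64, 3),
    Band(65, None, 4),
)
_BMI_BANDS = (
    Band(None, 25, 0, upper_inclusive=False),
    Band(25, 30, 1),
    Band(30, None, 3, lower_inclusive=False),
)

_WC_BANDS: dict[ScaleName, dict[Sex, tuple[Band, ...]]] = {
    ScaleName.FINDRISC: {
        Sex.MAN: (
            Band(None, 94, 0, upper_inclusive=False),
            Band(94, 102, 3),
            Band(102, None, 4, lower_inclusive=False),
        ),
        Sex.WOMAN: (
            Band(None, 80, 0, upper_inclusive=False),
            Band(80, 88, 3),
            Band(88, None, 4, lower_inclusive=False),
        ),
    },
    ScaleName.LA_FINDRISC: {
        Sex.MAN: (Band(None, 94, 0, upper_inclusive=False), Band(94, None, 4)),
        Sex.WOMAN: (Band(None, 90, 0, upper_inclusive=False), Band(90, None, 4)),
    },
    ScaleName.CUBDRISC: {
        Sex.MAN: (Band(None, 90, 0, upper_inclusive=False), Band(90, None, 4)),
        Sex.WOMAN: (Band(None, 80, 0, upper_inclusive=False), Band(80, None, 4)),
    },
}


def build_scale(name: ScaleName | str) -> ScaleDefinition:
    """Build one of the three published scoring tables.

    The scales differ only in their waist-circumference bands: FINDRISC keeps
    the original European two-step bands (men 94–102 cm → 3 points,
    > 102 cm → 4; women 80–88 → 3, > 88 → 4) while LA-FINDRISC (men ≥ 94,
    women ≥ 90) and CUBDRISC (men ≥ 90, women ≥ 80) award a single 4-point
    abdominal-obesity band.
    """
    try:
        name = ScaleName(name)
    except ValueError:
        valid = ", ".join(s.value for s in ScaleName)
        raise ValueError(f"unknown scale {name!r}; expected one of: {valid}") from None
    return ScaleDefinition(
        name=name.value,
        age_bands=_AGE_BANDS,
        bmi_bands=_BMI_BANDS,
        wc_bands_by_sex=_WC_BANDS[name],
    )


def score_participant(record: ParticipantRecord, scale: ScaleDefinition) -> ScoreResult:
    """Score one participant on a scale; every item must be present.

    Raises :class:`MissingItemError` naming the first absent item — items are
    never silently imputed.
    """
    for item in (
        "age",
        "waist_cm",
        "physical_activity",
        "daily_fruit_veg",
        "antihypertensive_meds",
        "history_high_glucose",
        "family_history",
    ):
        if getattr(record, item) is None:
            raise MissingItemError(item)
    bmi = record.effective_bmi  # raises MissingItemError("bmi") if underivable

    fixed = scale.fixed_item_points
    fh = FamilyHistory(record.family_history)
    per_item = {
        "age": _band_points(scale.age_bands, record.age, "age"),
        "bmi": _band_points(scale.bmi_bands, bmi, "bmi"),
        "waist": _band_points(
            scale.wc_bands_by_sex[Sex(record.sex)], record.waist_cm, "waist"
        ),
        "physical_activity": 0 if record.physical_activity else fixed["physical_activity_no"],
        "daily_fruit_veg": 0 if record.daily_fruit_veg else fixed["fruit_veg_not_daily"],
        "antihypertensive_meds": fixed["antihypertensive_meds_yes"] if record.antihypertensive_meds else 0,
        "history_high_glucose": fixed["history_high_glucose_yes"] if record.history_high_glucose else 0,
        "family_history": {
            FamilyHistory.NONE: 0,
            FamilyHistory.SECOND_DEGREE: fixed["family_history_second_degree"],
            FamilyHistory.FIRST_DEGREE: fixed["family_history_first_degree"],
        }[fh],
    }
    total = int(sum(per_item.values()))
    category, pct = risk_category(total)
    return ScoreResult(
        scale=scale.name,
        per_item_points=per_item,
        total=total,
        category=category,
        ten_year_risk_pct=pct,
    )


def score_frame(frame: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Vectorised totals for a participant table (see :data:`PARTICIPANT_COLUMNS`).

    ``bmi`` is taken from the column when present and finite, else derived
    from ``height_m``/``weight_kg``.
    """
    n = len(frame)
    if n == 0:
        return pd.Series([], dtype=np.int64, name=scale.name)

    if "bmi" in frame.columns:
        bmi = frame["bmi"].to_numpy(dtype=float)
    else:
        bmi = np.full(n, np.nan)
    if "height_m" in frame.columns and "weight_kg" in frame.columns:
        derived = frame["weight_kg"].to_numpy(dtype=float) / frame["height_m"].to_numpy(dtype=float) ** 2
        bmi = np.where(np.isfinite(bmi), bmi, derived)
    if not np.isfinite(bmi).all():
        raise MissingItemError("bmi")

    total = _band_points_array(scale.age_bands, frame["age"].to_numpy(dtype=float), "age")
    total = total + _band_points_array(scale.bmi_bands, bmi, "bmi")

    sex = frame["sex"].astype(str).to_numpy()
    wc = frame["waist_cm"].to_numpy(dtype=float)
    wc_pts = np.zeros(n, dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    for s, bands in scale.wc_bands_by_sex.items():
        mask = sex == s.value
        if mask.any():
            wc_pts[mask] = _band_points_array(bands, wc[mask], "waist")
        seen |= mask
    if not seen.all():
        bad = sex[~seen][0]
        raise ValueError(f"unrecognised sex code {bad!r}; expected 'M' or 'W'")
    total = total + wc_pts

    fixed = scale.fixed_item_points

    def _bool(col: str) -> np.ndarray:
        v = frame[col]
        if v.isna().any():
            raise MissingItemError(col)
        return v.astype(bool).to_numpy()

    total = total + np.where(_bool("physical_activity"), 0, fixed["physical_activity_no"])
    total = total + np.where(_bool("daily_fruit_veg"), 0, fixed["fruit_veg_not_daily"])
    total = total + np.where(_bool("antihypertensive_meds"), fixed["antihypertensive_meds_yes"], 0)
    total = total + np.where(_bool("history_high_glucose"), fixed["history_high_glucose_yes"], 0)

    fh = frame["family_history"].astype(str).to_numpy()
    fh_pts = np.select(
        [fh == FamilyHistory.FIRST_DEGREE.value, fh == FamilyHistory.SECOND_DEGREE.value, fh == FamilyHistory.NONE.value],
        [fixed["family_history_first_degree"], fixed["family_history_second_degree"], 0],
        default=-1,
    )
    if (fh_pts < 0).any():
        bad = fh[fh_pts < 0][0]
        raise ValueError(f"unrecognised family_history code {bad!r}")
    total = total + fh_pts

    return pd.Series(total, index=frame.index, name=scale.name, dtype=np.int64)


# Risk categories per the printed table: <7 low, 7–11 slightly elevated,
# 12–14 moderate, 15–20 high, >20 very high.
_RISK_BANDS = (
    (6, RiskCategory.LOW),
    (11, RiskCategory.SLIGHTLY_ELEVATED),
    (14, RiskCategory.MODERATE),
    (20, RiskCategory.HIGH),
    (26, RiskCategory.VERY_HIGH),
)


def risk_category(total: int) -> tuple[RiskCategory, int]:
    """Map a total score to its risk category and reported 10-year risk (%)."""
    if not 0 <= total <= 26:
        raise ValueError(f"total score must lie in [0, 26], got {total}")
    for upper, cat in _RISK_BANDS:
        if total <= upper:
            return cat, TEN_YEAR_RISK_PCT[cat]
    raise AssertionError("unreachable")


def max_score(scale: ScaleDefinition) -> int:
    """Maximum attainable total: the sum over items of the maximal band points."""
    banded = sum(
        max(b.points for b in bands)
        for bands in (scale.age_bands, scale.bmi_bands)
    )
    if scale.wc_bands_by_sex:
        banded += max(
            max(b.points for b in bands) for bands in scale.wc_bands_by_sex.values()
        )
    fixed = scale.fixed_item_points
    return int(
        banded
        + fixed["physical_activity_no"]
        + fixed["fruit_veg_not_daily"]
        + fixed["antihypertensive_meds_yes"]
        + fixed["history_high_glucose_yes"]
        + max(fixed["family_history_second_degree"], fixed["family_history_first_degree"])
    )


# ---------------------------------------------------------------------------
# Participant CSV dialect: one header row, sex coded M/W, booleans 1/0,
# family history as the enum values, glucose columns optional/blank.
# ---------------------------------------------------------------------------

PARTICIPANT_COLUMNS = (
    "id",
    "age",
    "sex",
    "bmi",
    "waist_cm",
    "physical_activity",
    "daily_fruit_veg",
    "antihypertensive_meds",
    "history_high_glucose",
    "family_history",
    "fpg_mmol",
    "g2h_mmol",
)

_BOOL_COLUMNS = (
    "physical_activity",
    "daily_fruit_veg",
    "antihypertensive_meds",
    "history_high_glucose",
)


def read_participants(path) -> pd.DataFrame:
    """Read a participant CSV, validating codes and required columns."""
    frame = pd.read_csv(path, dtype={"id": str, "sex": str, "family_history": str})
    required = set(PARTICIPANT_COLUMNS) - {"fpg_mmol", "g2h_mmol", "bmi"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"participant CSV is missing columns: {sorted(missing)}")
    if len(frame) == 0:
        raise ValueError("participant CSV contains no records")
    for col in _BOOL_COLUMNS:
        vals = set(frame[col].astype(int).unique()) - {0, 1}
        if vals:
            raise ValueError(f"column {col!r} must be coded 0/1, found {sorted(vals)}")
        frame[col] = frame[col].astype(int).astype(bool)
    bad_sex = set(frame["sex"].unique()) - {s.value for s in Sex}
    if bad_sex:
        raise ValueError(f"column 'sex' must be coded M/W, found {sorted(bad_sex)}")
    bad_fh = set(frame["family_history"].unique()) - {f.value for f in FamilyHistory}
    if bad_fh:
        raise ValueError(f"unrecognised family_history codes: {sorted(bad_fh)}")
    return frame


def write_participants(frame: pd.DataFrame, path) -> None:
    """Write a participant table in the CSV dialect (booleans 1/0)."""
    out = frame.copy()
    for col in _BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    cols = [c for c in PARTICIPANT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False, lineterminator="\n")
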