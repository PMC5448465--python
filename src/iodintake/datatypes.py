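"""Shared domain types for the iodine-intake calculation model.

Unit conventions used throughout the package:

* food amounts — grams per day (``A_food``);
* food composition — per 100 g food: natural iodine in µg/100 g
  (``C_food``) and added salt in g/100 g (``Z_food``);
* salt iodine concentrations — mg iodine per kg salt (``C_z``);
* intakes — µg iodine per day.

The bridging identity is ``g salt × (mg I / kg salt) = µg I``: one gram of
salt carrying ``c`` mg/kg contributes exactly ``c`` µg of iodine.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when an input row, record or configuration violates an invariant."""


SEXES = ("male", "female")

DISCRETIONARY_STATUSES = ("never_adds_salt", "adds_salt", "unknown")

#: The four intake sources that sum to total iodine intake.
SOURCES = ("natural", "manufacturer_salt", "discretionary_salt", "supplement")

DAYS = (1, 2)


@dataclass
class Subject:
    """One survey participant with two 24-h recall days.

    ``supplement_recall`` maps a recall day (1 or 2) to the supplemental
    iodine dose in µg reported on that day; days without a reported
    supplement are simply absent from the mapping.
    """

    subject_id: str
    age: int
    sex: str
    survey_weight: float
    discretionary_status: str = "unknown"
    supplement_recall: dict[int, float] = field(default_factory=dict)
    supplement_questionnaire_user: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        if not (self.survey_weight > 0):
            raise ValidationError(
                f"subject {self.subject_id}: survey_weight must be > 0, got {self.survey_weight!r}"
            )
        if self.discretionary_status not in DISCRETIONARY_STATUSES:
            raise ValidationError(
                f"subject {self.subject_id}: discretionary_status must be one of "
                f"{DISCRETIONARY_STATUSES}, got {self.discretionary_status!r}"
            )
        for day, dose in self.supplement_recall.items():
            if day not in DAYS:
                raise ValidationError(
                    f"subject {self.subject_id}: supplement recall day must be in {DAYS}, got {day!r}"
                )
            if dose < 0:
                raise ValidationError(
                    f"subject {self.subject_id}: negative supplement dose {dose!r} on day {day}"
                )

    @property
    def is_supplement_user(self) -> bool:
        """Potential supplement user: reported iodine on a recall day and/or
        reported use of an iodine-containing supplement category in the
        questionnaire."""
        return bool(self.supplement_recall) or self.supplement_questionnaire_user


@dataclass
class ConsumptionRecord:
    """One food eaten by one subject on one recall day (amount in g)."""

    subject_id: str
    day: int
    food_code: str
    food_group: str
    amount: float

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValidationError(
                f"record for subject {self.subject_id}: day must be in {DAYS}, got {self.day!r}"
            )
        if self.amount < 0:
            raise ValidationError(
                f"record for subject {self.subject_id}, food {self.food_code}: "
                f"amount must be >= 0, got {self.amount!r}"
            )


@dataclass
class FoodComposition:
    """Composition entry for one food code.

    ``manufacturer_group`` names the iodised-salt assignment category the
    food belongs to (bread, pizza, ...) or is ``None`` for foods outside the
    manufacturer-salt branch.  Foods produced with salt are never eligible
    for discretionary salt addition.
    """

    food_code: str
    iodine_nat: float  # µg / 100 g food
    added_salt: float  # g salt / 100 g food
    manufacturer_group: str | None = None
    discretionary_eligible: bool = False
    produced_with_salt: bool = False

    def __post_init__(self) -> None:
        if self.iodine_nat < 0:
            raise ValidationError(
                f"food {self.food_code}: iodine_nat must be >= 0, got {self.iodine_nat!r}"
            )
        if self.added_salt < 0:
            raise ValidationError(
                f"food {self.food_code}: added_salt must be >= 0, got {self.added_salt!r}"
            )
        if self.produced_with_salt and self.discretionary_eligible:
            raise ValidationError(
                f"food {self.food_code}: a food produced with salt cannot be "
                "eligible for discretionary salt addition"
            )


def sodium_to_salt(added_sodium_mg_per_100g: float) -> float:
    """Convert added sodium (mg Na/100 g food) to added salt (g NaCl/100 g).

    Optional helper: 1 g NaCl contains 400 mg Na, i.e. salt = Na × 2.5 / 1000.
    """
    if added_sodium_mg_per_100g < 0:
        raise ValidationError("added sodium must be >= 0")
    return added_sodium_mg_per_100g * 2.5 / 1000.0


@dataclass
class ManufacturerGroupPolicy:
    """Iodised-salt assumptions for one manufacturer food group."""

    market_share: float  # fraction of consumed product containing iodised salt
    iodine_conc: float  # mg iodine per kg salt
    salt_fraction: float = 1.0  # fraction of the food's salt attributable to iodised salt

    def __post_init__(self) -> None:
        if not (0.0 <= self.market_share <= 1.0):
            raise ValidationError(f"market_share must be in [0, 1], got {self.market_share!r}")
        if not (0.0 <= self.salt_fraction <= 1.0):
            raise ValidationError(f"salt_fraction must be in [0, 1], got {self.salt_fraction!r}")
        if self.iodine_conc < 0:
            raise ValidationError(f"iodine_conc must be >= 0, got {self.iodine_conc!r}")


@dataclass
class DiscretionaryGroupPolicy:
    """Discretionary salt assumptions for one eligible food group."""

    added_amount: float  # g salt added per 100 g food
    use_fraction: float  # fraction of salt-adding subjects who salt this group

    def __post_init__(self) -> None:
        if self.added_amount < 0:
            raise ValidationError(f"added_amount must be >= 0, got {self.added_amount!r}")
        if not (0.0 <= self.use_fraction <= 1.0):
            raise ValidationError(f"use_fraction must be in [0, 1], got {self.use_fraction!r}")


@dataclass
class SaltPolicy:
    """Full iodised-salt policy configuration.

    ``never_user_proportions`` maps ``(age_low, age_high, sex)`` — bands
    inclusive on both ends — to the fraction of the stratum that never adds
    salt during meal preparation or consumption.
    """

    manufacturer: dict[str, ManufacturerGroupPolicy]
    discretionary_iodine_conc: float
    discretionary_groups: dict[str, DiscretionaryGroupPolicy]
    never_user_proportions: dict[tuple[int, int, str], float]

    def __post_init__(self) -> None:
        if self.discretionary_iodine_conc < 0:
            raise ValidationError("discretionary_iodine_conc must be >= 0")
        for band, prop in self.never_user_proportions.items():
            low, high, sex = band
            if sex not in SEXES:
                raise ValidationError(f"never_user_proportions band {band}: unknown sex")
            if low > high:
                raise ValidationError(f"never_user_proportions band {band}: age_low > age_high")
            if not (0.0 <= prop <= 1.0):
                raise ValidationError(
                    f"never_user_proportions band {band}: proportion must be in [0, 1], got {prop!r}"
                )

    def never_user_band(self, age: int, sex: str) -> tuple[int, int, str]:
        for (low, high, band_sex) in self.never_user_proportions:
            if band_sex == sex and low <= age <= high:
                return (low, high, band_sex)
        raise ValidationError(
            f"no never_user_proportions band covers age {age}, sex {sex}"
        )

    def never_user_proportion(self, age: int, sex: str) -> float:
        return self.never_user_proportions[self.never_user_band(age, sex)]

    def check_coverage(self, ages: list[int], sexes: list[str]) -> None:
        """Raise listing every (age, sex) cell not covered by a band."""
        uncovered = sorted(
            {
                (age, sex)
                for age, sex in zip(ages, sexes)
                if not any(
                    s == sex and lo <= age <= hi
                    for (lo, hi, s) in self.never_user_proportions
                )
            }
        )
        if uncovered:
            raise ValidationError(
                "never_user_proportions does not cover (age, sex) cells: "
                + ", ".join(f"({a}, {s})" for a, s in uncovered)
            )


@dataclass
class DRIBand:
    """EAR and UL (µg/d) for one age band (inclusive) and sex."""

    age_low: int
    age_high: int
    sex: str
    ear: float
    ul: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"DRI band: sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_low > self.age_high:
            raise ValidationError(
                f"DRI band ({self.age_low}-{self.age_high}, {self.sex}): age_low > age_high"
            )
        if not (self.ear < self.ul):
            raise ValidationError(
                f"DRI band ({self.age_low}-{self.age_high}, {self.sex}): "
                f"EAR ({self.ear}) must be < UL ({self.ul})"
            )

    @property
    def label(self) -> str:
        return f"{self.age_low}-{self.age_high} {self.sex}"

    def contains(self, age: int, sex: str) -> bool:
        return sex == self.sex and self.age_low <= age <= self.age_high


@dataclass
class DRITable:
    """Dietary reference intakes by age band and sex; bands must not overlap."""

    bands: list[DRIBand]

    def __post_init__(self) -> None:
        for sex in SEXES:
            rows = sorted(
                (b for b in self.bands if b.sex == sex), key=lambda b: b.age_low
            )
            for a, b in zip(rows, rows[1:]):
                if b.age_low <= a.age_high:
                    raise ValidationError(
                        f"DRI bands overlap for sex {sex}: "
                        f"({a.age_low}-{a.age_high}) and ({b.age_low}-{b.age_high})"
                    )

    def lookup(self, age: int, sex: str) -> DRIBand:
        for band in self.bands:
            if band.contains(age, sex):
                return band
        raise ValidationError(f"no DRI band covers age {age}, sex {sex}")

    def check_coverage(self, age_low: int, age_high: int) -> None:
        for sex in SEXES:
            for age in range(age_low, age_high + 1):
                self.lookup(age, sex)
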