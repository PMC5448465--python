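"""Readers and writers for the package's tabular and configuration formats.

All data tables are UTF-8 CSV with a header row; the salt policy and DRI
tables are JSON documents.  Validation is total: a malformed input raises a
:class:`~iodintake.datatypes.ValidationError` naming the offending row or
field, never yielding a partial dataset.

CSV schemas
-----------
``subjects.csv``
    subject_id, age, sex, survey_weight, discretionary_status,
    supp_day1, supp_day2, supp_questionnaire
    (supp_day1/2 in µg, blank when no supplemental iodine was reported that
    day; supp_questionnaire in {0, 1}).
``consumption.csv``
    subject_id, day, food_code, food_group, amount_g
``composition.csv``
    food_code, iodine_nat_ug_per100g, added_salt_g_per100g,
    manufacturer_group (blank for none), discretionary_eligible,
    produced_with_salt
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .datatypes import (
    ConsumptionRecord,
    DiscretionaryGroupPolicy,
    DRIBand,
    DRITable,
    FoodComposition,
    ManufacturerGroupPolicy,
    SaltPolicy,
    Subject,
    ValidationError,
)

DEFAULT_AGE_BOUNDS = (7, 69)

SUBJECT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "survey_weight",
    "discretionary_status",
    "supp_day1",
    "supp_day2",
    "supp_questionnaire",
]
CONSUMPTION_COLUMNS = ["subject_id", "day", "food_code", "food_group", "amount_g"]
COMPOSITION_COLUMNS = [
    "food_code",
    "iodine_nat_ug_per100g",
    "added_salt_g_per100g",
    "manufacturer_group",
    "discretionary_eligible",
    "produced_with_salt",
]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing required column(s): {', '.join(missing)}")


def _num(value, what: str):
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{what}: non-numeric value {value!r}") from None
    if math.isnan(out):
        raise ValidationError(f"{what}: missing value")
    return out


def read_subjects(
    path: str | Path, age_bounds: tuple[int, int] = DEFAULT_AGE_BOUNDS
) -> list[Subject]:
    """Read ``subjects.csv``; every row becomes a validated :class:`Subject`."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _check_columns(df, SUBJECT_COLUMNS, f"subjects file {path}")
    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        age = _num(row["age"], f"subject {sid}: age")
        if age != int(age):
            raise ValidationError(f"subject {sid}: age must be an integer, got {age!r}")
        age = int(age)
        if not (age_bounds[0] <= age <= age_bounds[1]):
            raise ValidationError(
                f"subject {sid}: age {age} outside configured bounds "
                f"{age_bounds[0]}-{age_bounds[1]}"
            )
        weight = _num(row["survey_weight"], f"subject {sid}: survey_weight")
        recall: dict[int, float] = {}
        for day, col in ((1, "supp_day1"), (2, "supp_day2")):
            value = row[col]
            if pd.notna(value) and str(value).strip() != "":
                recall[day] = _num(value, f"subject {sid}: {col}")
        subjects.append(
            Subject(
                subject_id=sid,
                age=age,
                sex=str(row["sex"]),
                survey_weight=weight,
                discretionary_status=str(row["discretionary_status"]),
                supplement_recall=recall,
                supplement_questionnaire_user=bool(int(row["supp_questionnaire"])),
            )
        )
    return subjects


def write_subjects(subjects: list[Subject], path: str | Path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "survey_weight": s.survey_weight,
                "discretionary_status": s.discretionary_status,
                "supp_day1": s.supplement_recall.get(1, ""),
                "supp_day2": s.supplement_recall.get(2, ""),
                "supp_questionnaire": int(s.supplement_questionnaire_user),
            }
        )
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_consumption(path: str | Path) -> list[ConsumptionRecord]:
    """Read ``consumption.csv``; an empty file (header only) is valid."""
    df = pd.read_csv(path, dtype={"subject_id": str, "food_code": str})
    _check_columns(df, CONSUMPTION_COLUMNS, f"consumption file {path}")
    records = []
    for i, row in df.iterrows():
        sid = str(row["subject_id"])
        day = _num(row["day"], f"consumption row {i} (subject {sid}): day")
        records.append(
            ConsumptionRecord(
                subject_id=sid,
                day=int(day),
                food_code=str(row["food_code"]),
                food_group=str(row["food_group"]),
                amount=_num(row["amount_g"], f"consumption row {i} (subject {sid}): amount_g"),
            )
        )
    return records


def write_consumption(records: list[ConsumptionRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "day": r.day,
            "food_code": r.food_code,
            "food_group": r.food_group,
            "amount_g": r.amount,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CONSUMPTION_COLUMNS).to_csv(path, index=False)


def read_composition(path: str | Path) -> list[FoodComposition]:
    df = pd.read_csv(path, dtype={"food_code": str, "manufacturer_group": str})
    _check_columns(df, COMPOSITION_COLUMNS, f"composition file {path}")
    foods = []
    for _, row in df.iterrows():
        code = str(row["food_code"])
        group = row["manufacturer_group"]
        group = None if (pd.isna(group) or str(group).strip() == "") else str(group)
        foods.append(
            FoodComposition(
                food_code=code,
                iodine_nat=_num(row["iodine_nat_ug_per100g"], f"food {code}: iodine_nat"),
                added_salt=_num(row["added_salt_g_per100g"], f"food {code}: added_salt"),
                manufacturer_group=group,
                discretionary_eligible=bool(int(row["discretionary_eligible"])),
                produced_with_salt=bool(int(row["produced_with_salt"])),
            )
        )
    return foods


def write_composition(foods: list[FoodComposition], path: str | Path) -> None:
    rows = [
        {
            "food_code": f.food_code,
            "iodine_nat_ug_per100g": f.iodine_nat,
            "added_salt_g_per100g": f.added_salt,
            "manufacturer_group": f.manufacturer_group or "",
            "discretionary_eligible": int(f.discretionary_eligible),
            "produced_with_salt": int(f.produced_with_salt),
        }
        for f in foods
    ]
    pd.DataFrame(rows, columns=COMPOSITION_COLUMNS).to_csv(path, index=False)


def policy_from_dict(doc: dict) -> SaltPolicy:
    try:
        manufacturer = {
            name: ManufacturerGroupPolicy(
                market_share=entry["market_share"],
                iodine_conc=entry["iodine_conc"],
                salt_fraction=entry.get("salt_fraction", 1.0),
            )
            for name, entry in doc["manufacturer_groups"].items()
        }
        disc = doc["discretionary"]
        groups = {
            name: DiscretionaryGroupPolicy(
                added_amount=entry["added_amount"],
                use_fraction=entry["use_fraction"],
            )
            for name, entry in disc["groups"].items()
        }
        never = {
            (int(row["age_low"]), int(row["age_high"]), str(row["sex"])): float(
                row["proportion"]
            )
            for row in disc["never_user_proportions"]
        }
        return SaltPolicy(
            manufacturer=manufacturer,
            discretionary_iodine_conc=disc["iodine_conc"],
            discretionary_groups=groups,
            never_user_proportions=never,
        )
    except KeyError as exc:
        raise ValidationError(f"salt policy: missing required key {exc}") from None


def policy_to_dict(policy: SaltPolicy) -> dict:
    return {
        "manufacturer_groups": {
            name: {
                "market_share": g.market_share,
                "iodine_conc": g.iodine_conc,
                "salt_fraction": g.salt_fraction,
            }
            for name, g in policy.manufacturer.items()
        },
        "discretionary": {
            "iodine_conc": policy.discretionary_iodine_conc,
            "groups": {
                name: {"added_amount": g.added_amount, "use_fraction": g.use_fraction}
                for name, g in policy.discretionary_groups.items()
            },
            "never_user_proportions": [
                {"age_low": lo, "age_high": hi, "sex": sex, "proportion": p}
                for (lo, hi, sex), p in policy.never_user_proportions.items()
            ],
        },
    }


def read_policy(path: str | Path) -> SaltPolicy:
    with open(path, encoding="utf-8") as fh:
        return policy_from_dict(json.load(fh))


def write_policy(policy: SaltPolicy, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(policy_to_dict(policy), fh, indent=2, sort_keys=True)
        fh.write("\n")


def dri_from_dict(rows: list[dict]) -> DRITable:
    try:
        bands = [
            DRIBand(
                age_low=int(r["age_low"]),
                age_high=int(r["age_high"]),
                sex=str(r["sex"]),
                ear=float(r["ear"]),
                ul=float(r["ul"]),
            )
            for r in rows
        ]
    except KeyError as exc:
        raise ValidationError(f"DRI table: missing required key {exc}") from None
    return DRITable(bands=bands)


def read_dri(
    path: str | Path, age_bounds: tuple[int, int] | None = None
) -> DRITable:
    """Read ``dri.json``; with ``age_bounds`` set, checks full coverage."""
    with open(path, encoding="utf-8") as fh:
        table = dri_from_dict(json.load(fh))
    if age_bounds is not None:
        table.check_coverage(*age_bounds)
    return table


def write_dri(table: DRITable, path: str | Path) -> None:
    rows = [
        {"age_low": b.age_low, "age_high": b.age_high, "sex": b.sex, "ear": b.ear, "ul": b.ul}
        for b in table.bands
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rows, fh, indent=2, sort_keys=True)
        fh.write("\n")


def subjects_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Subjects as a DataFrame indexed by subject_id (internal workhorse)."""
    df = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "survey_weight": [s.survey_weight for s in subjects],
            "discretionary_status": [s.discretionary_status for s in subjects],
        }
    )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id(s): {dupes}")
    return df.set_index("subject_id")


def records_frame(records: list[ConsumptionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "day": [r.day for r in records],
            "food_code": [r.food_code for r in records],
            "food_group": [r.food_group for r in records],
            "amount": [r.amount for r in records],
        }
    )


def composition_frame(foods: list[FoodComposition]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "food_code": [f.food_code for f in foods],
            "iodine_nat": [f.iodine_nat for f in foods],
            "added_salt": [f.added_salt for f in foods],
            "manufacturer_group": [f.manufacturer_group for f in foods],
            "discretionary_eligible": [f.discretionary_eligible for f in foods],
            "produced_with_salt": [f.produced_with_salt for f in foods],
        }
    )
    return df.set_index("food_code")
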