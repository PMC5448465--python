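"""Per-subject-per-day iodine intakes for each of the four sources.

Every operation returns a tidy DataFrame with columns ``subject_id``,
``day``, ``source`` and ``intake`` (µg/d) containing exactly one row per
(subject, day) — days without eligible foods carry an explicit zero — so the
four source tables are additive row-by-row.

Unit bridge (documented in :mod:`iodintake.datatypes` and tested):
``amount g x added_salt g/100 g / 100 = g salt``, and
``g salt x iodine_conc mg/kg = µg iodine``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import SaltPolicy, Subject, ValidationError
from .io_config import composition_frame, records_frame, subjects_frame


def _full_grid(subjects: list[Subject]) -> pd.DataFrame:
    ids = [s.subject_id for s in subjects]
    return pd.DataFrame(
        {"subject_id": np.repeat(ids, 2), "day": np.tile([1, 2], len(ids))}
    )


def _as_source_table(sums: pd.DataFrame, subjects: list[Subject], source: str) -> pd.DataFrame:
    grid = _full_grid(subjects)
    out = grid.merge(sums, on=["subject_id", "day"], how="left")
    out["intake"] = pd.to_numeric(out["intake"], errors="coerce").fillna(0.0)
    out["source"] = source
    return out[["subject_id", "day", "source", "intake"]]


def _join_composition(records, composition) -> pd.DataFrame:
    rec = records_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    comp = (
        composition_frame(composition)
        if not isinstance(composition, pd.DataFrame)
        else composition
    )
    unresolved = sorted(set(rec["food_code"]) - set(comp.index))
    if unresolved:
        raise ValidationError(f"food codes missing from composition table: {unresolved}")
    return rec.join(comp, on="food_code")


def natural_iodine(records, composition, subjects: list[Subject]) -> pd.DataFrame:
    """Iodine naturally present in foods, µg/d per subject-day.

    Foods carrying a ``manufacturer_group`` (bread and other foods known to
    be produced with iodised salt) are excluded here; their iodine is
    accounted for in the manufacturer-salt source.
    """
    df = _join_composition(records, composition)
    df = df[df["manufacturer_group"].isna()]
    df = df.assign(intake=df["amount"] * df["iodine_nat"] / 100.0)
    sums = df.groupby(["subject_id", "day"], as_index=False)["intake"].sum()
    return _as_source_table(sums, subjects, "natural")


def manufacturer_iodine(
    records, composition, policy: SaltPolicy, assignment, subjects: list[Subject]
) -> pd.DataFrame:
    """Iodine from iodised salt added by food manufacturers, µg/d.

    A food contributes only when the assignment flags its (subject,
    manufacturer_group) pair as consuming the iodised-salt variant:
    ``amount x added_salt/100 x salt_fraction x iodine_conc``.
    """
    df = _join_composition(records, composition)
    df = df[df["manufacturer_group"].notna()].copy()
    missing = sorted(set(df["manufacturer_group"]) - set(policy.manufacturer))
    if missing:
        raise ValidationError(
            f"manufacturer group(s) lacking a salt-policy entry: {missing}"
        )
    if df.empty:
        return _as_source_table(
            pd.DataFrame(columns=["subject_id", "day", "intake"]), subjects,
            "manufacturer_salt",
        )
    iodised = assignment.iodised
    flagged = [
        (sid, grp) in iodised
        for sid, grp in zip(df["subject_id"], df["manufacturer_group"])
    ]
    df = df[np.asarray(flagged, dtype=bool)]
    conc = df["manufacturer_group"].map(lambda g: policy.manufacturer[g].iodine_conc)
    frac = df["manufacturer_group"].map(lambda g: policy.manufacturer[g].salt_fraction)
    df = df.assign(intake=df["amount"] * df["added_salt"] / 100.0 * frac * conc)
    sums = df.groupby(["subject_id", "day"], as_index=False)["intake"].sum()
    return _as_source_table(sums, subjects, "manufacturer_salt")


def discretionary_iodine(
    records, composition, policy: SaltPolicy, subjects: list[Subject], assignment
) -> pd.DataFrame:
    """Iodine from salt added during meal preparation or at the table, µg/d.

    Only foods that are discretionary-eligible (and not produced with salt)
    count, and only for subjects the assignment marks as salt adders for
    that food group: ``amount x added_amount/100 x iodine_conc``.
    Questionnaire-confirmed never-users always contribute zero.
    """
    df = _join_composition(records, composition)
    df = df[df["discretionary_eligible"] & ~df["produced_with_salt"]].copy()
    missing = sorted(set(df["food_group"]) - set(policy.discretionary_groups))
    if missing:
        raise ValidationError(
            f"discretionary-eligible food group(s) without a configured added_amount: {missing}"
        )
    disc_user = assignment.discretionary_user
    for s in subjects:
        if s.discretionary_status == "never_adds_salt" and disc_user.get(s.subject_id, False):
            raise ValidationError(
                f"assignment marks never-user {s.subject_id} as a discretionary salt user"
            )
    if not df.empty:
        adds = assignment.adds_salt
        flagged = [
            disc_user.get(sid, False) and (sid, grp) in adds
            for sid, grp in zip(df["subject_id"], df["food_group"])
        ]
        df = df[np.asarray(flagged, dtype=bool)]
        added = df["food_group"].map(lambda g: policy.discretionary_groups[g].added_amount)
        df = df.assign(
            intake=df["amount"] * added / 100.0 * policy.discretionary_iodine_conc
        )
    sums = df.groupby(["subject_id", "day"], as_index=False)["intake"].sum() if len(df) else (
        pd.DataFrame(columns=["subject_id", "day", "intake"])
    )
    return _as_source_table(sums, subjects, "discretionary_salt")


def supplement_daily(subjects: list[Subject]) -> pd.DataFrame:
    """Reported supplemental iodine per recall day, µg/d (0 when none)."""
    rows = []
    for s in subjects:
        for day in (1, 2):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "day": day,
                    "source": "supplement",
                    "intake": float(s.supplement_recall.get(day, 0.0)),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "day", "source", "intake"])


def total_daily(*source_tables: pd.DataFrame) -> pd.DataFrame:
    """Row-wise sum of source tables into a total per subject-day."""
    merged = pd.concat(source_tables, ignore_index=True)
    out = merged.groupby(["subject_id", "day"], as_index=False)["intake"].sum()
    out["source"] = "total"
    return out[["subject_id", "day", "source", "intake"]]


def group_contributions(records, composition, subjects: list[Subject]) -> pd.Series:
    """Survey-weighted mean fraction of natural iodine per food group.

    For each subject the 2-day mean natural-iodine intake per food group is
    divided by the subject's 2-day mean total; the survey-weighted mean of
    these per-subject proportions is reported per group.  Subjects with an
    all-zero total carry no defined proportion and are excluded.
    """
    df = _join_composition(records, composition)
    df = df[df["manufacturer_group"].isna()]
    df = df.assign(intake=df["amount"] * df["iodine_nat"] / 100.0)
    per_group = (
        df.groupby(["subject_id", "food_group"])["intake"].sum().div(2.0).unstack(fill_value=0.0)
    )
    sub = subjects_frame(subjects)
    per_group = per_group.reindex(sub.index, fill_value=0.0)
    totals = per_group.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValidationError("every subject has zero natural iodine intake")
    props = per_group.loc[keep].div(totals[keep], axis=0)
    w = sub.loc[keep, "survey_weight"]
    shares = props.mul(w, axis=0).sum(axis=0) / w.sum()
    return shares.sort_values(ascending=False)
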