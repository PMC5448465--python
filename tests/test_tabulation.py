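"""Source-specific daily intake arithmetic and contribution shares."""

import numpy as np
import pandas as pd
import pytest

import iodintake as it
from iodintake import tabulation
from iodintake.assignment import Assignment, draw_assignment
from iodintake.datatypes import ValidationError


MILK = it.FoodComposition("milk", iodine_nat=16.0, added_salt=0.0)
BREAD = it.FoodComposition("bread", iodine_nat=0.0, added_salt=1.25,
                           manufacturer_group="bread", produced_with_salt=True)
PIZZA = it.FoodComposition("pizza", iodine_nat=0.0, added_salt=1.5,
                           manufacturer_group="pizza", produced_with_salt=True)
POTATO = it.FoodComposition("potatoes", iodine_nat=0.0, added_salt=0.0,
                            discretionary_eligible=True)


def one_subject(status="adds_salt"):
    return [it.Subject("a", 30, "male", 1.0, discretionary_status=status)]


def policy(pizza_conc=25.0):
    return it.SaltPolicy(
        manufacturer={
            "bread": it.ManufacturerGroupPolicy(0.95, 58.0),
            "pizza": it.ManufacturerGroupPolicy(0.40, pizza_conc, salt_fraction=0.5),
        },
        discretionary_iodine_conc=20.0,
        discretionary_groups={"potatoes": it.DiscretionaryGroupPolicy(1.0, 0.5)},
        never_user_proportions={(7, 69, "male"): 0.3, (7, 69, "female"): 0.3},
    )


def get(table, day):
    return float(table.loc[table["day"] == day, "intake"].iloc[0])


def test_natural_milk_arithmetic():
    records = [it.ConsumptionRecord("a", 1, "milk", "dairy", 200.0)]
    nat = tabulation.natural_iodine(records, [MILK], one_subject())
    assert get(nat, 1) == pytest.approx(200 * 16 / 100)  # 32 ug
    assert get(nat, 2) == 0.0  # day without records carries an explicit zero


def test_manufacturer_foods_excluded_from_natural():
    records = [it.ConsumptionRecord("a", 1, "bread", "bread", 100.0)]
    nat = tabulation.natural_iodine(records, [BREAD], one_subject())
    assert get(nat, 1) == 0.0


def test_unresolvable_food_code_errors():
    records = [it.ConsumptionRecord("a", 1, "mystery", "dairy", 10.0)]
    with pytest.raises(ValidationError, match="mystery"):
        tabulation.natural_iodine(records, [MILK], one_subject())


def test_manufacturer_bread_arithmetic():
    records = [it.ConsumptionRecord("a", 1, "bread", "bread", 120.0)]
    asg = Assignment(0, iodised={("a", "bread")})
    man = tabulation.manufacturer_iodine(records, [BREAD], policy(), asg, one_subject())
    assert get(man, 1) == pytest.approx(120 * 1.25 / 100 * 58)  # 87 ug


def test_manufacturer_unassigned_subject_gets_zero():
    records = [it.ConsumptionRecord("a", 1, "bread", "bread", 120.0)]
    man = tabulation.manufacturer_iodine(records, [BREAD], policy(), Assignment(0),
                                         one_subject())
    assert get(man, 1) == 0.0


def test_manufacturer_pizza_salt_fraction():
    records = [it.ConsumptionRecord("a", 1, "pizza", "pizza", 200.0)]
    asg = Assignment(0, iodised={("a", "pizza")})
    man = tabulation.manufacturer_iodine(records, [PIZZA], policy(), asg, one_subject())
    assert get(man, 1) == pytest.approx(200 * 1.5 / 100 * 0.5 * 25)  # 37.5 ug


def test_manufacturer_group_without_policy_errors():
    records = [it.ConsumptionRecord("a", 1, "bread", "bread", 120.0)]
    bad = policy()
    del bad.manufacturer["bread"]
    with pytest.raises(ValidationError, match="bread"):
        tabulation.manufacturer_iodine(records, [BREAD], bad, Assignment(0), one_subject())


def test_discretionary_potatoes_arithmetic():
    records = [it.ConsumptionRecord("a", 1, "potatoes", "potatoes", 300.0)]
    asg = Assignment(0, discretionary_user={"a": True}, adds_salt={("a", "potatoes")})
    disc = tabulation.discretionary_iodine(records, [POTATO], policy(), one_subject(), asg)
    assert get(disc, 1) == pytest.approx(300 * 1.0 / 100 * 20)  # 60 ug


def test_discretionary_never_user_always_zero():
    records = [it.ConsumptionRecord("a", 1, "potatoes", "potatoes", 300.0)]
    asg = Assignment(0, discretionary_user={"a": False}, adds_salt={("a", "potatoes")})
    disc = tabulation.discretionary_iodine(
        records, [POTATO], policy(), one_subject("never_adds_salt"), asg
    )
    assert get(disc, 1) == 0.0


def test_discretionary_group_not_drawn_gives_zero():
    records = [it.ConsumptionRecord("a", 1, "potatoes", "potatoes", 300.0)]
    asg = Assignment(0, discretionary_user={"a": True}, adds_salt=set())
    disc = tabulation.discretionary_iodine(records, [POTATO], policy(), one_subject(), asg)
    assert get(disc, 1) == 0.0


def test_supplement_daily_day_attribution():
    sub = it.Subject("a", 30, "male", 1.0, supplement_recall={1: 150.0})
    table = tabulation.supplement_daily([sub])
    assert get(table, 1) == 150.0 and get(table, 2) == 0.0
    non_user = it.Subject("b", 30, "male", 1.0)
    table = tabulation.supplement_daily([non_user])
    assert table["intake"].tolist() == [0.0, 0.0]


def test_additivity_and_linearity(survey_data):
    """Total = sum of the four sources exactly; doubling amounts doubles intakes."""
    subjects, records, composition, _ = survey_data
    pol = it.default_policy()
    asg = draw_assignment(subjects, records, composition, pol, seed=1, iteration=0)
    parts = [
        tabulation.natural_iodine(records, composition, subjects),
        tabulation.manufacturer_iodine(records, composition, pol, asg, subjects),
        tabulation.discretionary_iodine(records, composition, pol, subjects, asg),
        tabulation.supplement_daily(subjects),
    ]
    total = tabulation.total_daily(*parts)
    by_hand = sum(
        p.sort_values(["subject_id", "day"])["intake"].to_numpy() for p in parts
    )
    assert np.allclose(total.sort_values(["subject_id", "day"])["intake"], by_hand)

    doubled = [
        it.ConsumptionRecord(r.subject_id, r.day, r.food_code, r.food_group, 2 * r.amount)
        for r in records
    ]
    for fn, args in [
        (tabulation.natural_iodine, (composition, subjects)),
        (lambda rec, comp, subs: tabulation.manufacturer_iodine(rec, comp, pol, asg, subs),
         (composition, subjects)),
    ]:
        base = fn(records, *args).sort_values(["subject_id", "day"])["intake"].to_numpy()
        twice = fn(doubled, *args).sort_values(["subject_id", "day"])["intake"].to_numpy()
        assert np.allclose(twice, 2 * base)


def test_group_contributions_single_group_is_one():
    records = [it.ConsumptionRecord("a", 1, "milk", "dairy", 100.0)]
    shares = tabulation.group_contributions(records, [MILK], one_subject())
    assert shares["dairy"] == pytest.approx(1.0)


def test_group_contributions_fixed_split():
    water = it.FoodComposition("water", iodine_nat=10.0, added_salt=0.0)
    records = []
    subs = []
    for sid in ("a", "b"):
        subs.append(it.Subject(sid, 30, "male", 1.0))
        for day in (1, 2):
            records.append(it.ConsumptionRecord(sid, day, "milk", "dairy", 187.5))  # 30 ug
            records.append(it.ConsumptionRecord(sid, day, "water", "drinks", 100.0))  # 10 ug
    shares = tabulation.group_contributions(records, [MILK, water], subs)
    assert shares["dairy"] == pytest.approx(0.75)
    assert shares["drinks"] == pytest.approx(0.25)


def test_group_contributions_weighted_oracle(three_subjects):
    """Matches a hand-computed survey-weighted mean of per-subject proportions."""
    water = it.FoodComposition("water", iodine_nat=10.0, added_salt=0.0)
    records = []
    dairy_share = {"a": 0.8, "b": 0.5, "c": 0.2}
    for s in three_subjects:
        frac = dairy_share[s.subject_id]
        for day in (1, 2):
            records.append(
                it.ConsumptionRecord(s.subject_id, day, "milk", "dairy", frac * 100 / 0.16)
            )
            records.append(
                it.ConsumptionRecord(s.subject_id, day, "water", "drinks",
                                     (1 - frac) * 100 / 0.10)
            )
    shares = tabulation.group_contributions(records, [MILK, water], three_subjects)
    expected = (1.0 * 0.8 + 2.0 * 0.5 + 3.0 * 0.2) / 6.0
    assert shares["dairy"] == pytest.approx(expected)
    assert shares.sum() == pytest.approx(1.0, abs=1e-9)


def test_group_contributions_all_zero_errors(three_subjects):
    records = [it.ConsumptionRecord("a", 1, "potatoes", "potatoes", 100.0)]
    with pytest.raises(ValidationError, match="zero"):
        tabulation.group_contributions(records, [POTATO], three_subjects)


def test_contributions_sum_to_one_on_survey(survey_data):
    subjects, records, composition, _ = survey_data
    shares = tabulation.group_contributions(records, composition, subjects)
    assert (shares >= 0).all()
    assert shares.sum() == pytest.approx(1.0, abs=1e-9)
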