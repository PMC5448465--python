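"""Synthetic survey populations and 2-day recall datasets with known truth.

The generator emulates the statistical structure the estimation pipeline
assumes: per-source person-day intakes built as
``back-transform(f(age) + b_i + e_ij)`` with the person effect ``b_i`` and
day effect ``e_ij`` normal on the Box-Cox transformed scale, episodic food
groups with true never-consumers, supplement use defined by recall and/or
questionnaire, and age/sex-stratified never-discretionary-salt proportions.
All randomness flows from a single seed.

The default parameter set sketches a Western survey population: a natural
iodine intake of the order of 150 µg/d dominated by dairy and drinks, daily
bread consumption around 120 g/d, a ~10 % supplement-user fraction with
typical label doses, and never-salting proportions of 25-45 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datatypes import FoodComposition, Subject, ValidationError
from .habitual import boxcox_inverse

AGE_BANDS = ((7, 8), (9, 13), (14, 18), (19, 30), (31, 50), (51, 69))


@dataclass
class SourceParams:
    """One continuous intake source on a Box-Cox transformed scale.

    ``f(age) = intercept + age_slope x age`` is the age trend on the
    transformed scale; ``sigma_between``/``sigma_within`` the person- and
    day-level standard deviations on that scale.
    """

    lam: float
    intercept: float
    age_slope: float = 0.0
    sigma_between: float = 0.0
    sigma_within: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValidationError("sigma_between and sigma_within must be >= 0")

    def mean_at(self, age) -> np.ndarray:
        return self.intercept + self.age_slope * np.asarray(age, dtype=float)


@dataclass
class EpisodicParams:
    """Consumption pattern of an episodic food group."""

    consumption_prob: float = 1.0  # chance a consumer eats the group on a day
    never_consumer_fraction: float = 0.0  # true non-consumers of the group

    def __post_init__(self) -> None:
        for p in (self.consumption_prob, self.never_consumer_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must be in [0, 1]")


@dataclass
class SupplementTruth:
    user_fraction: float = 0.10
    doses: tuple = (50.0, 100.0, 150.0)  # typical label doses, µg
    dose_probs: tuple = (0.3, 0.5, 0.2)
    report_prob: float = 0.6  # chance a user reports the dose on a given recall day

    def __post_init__(self) -> None:
        if not (0.0 <= self.user_fraction <= 1.0):
            raise ValidationError("user_fraction must be in [0, 1]")
        if abs(sum(self.dose_probs) - 1.0) > 1e-9:
            raise ValidationError("dose_probs must sum to 1")


def _default_never_props() -> dict:
    values = {
        (7, 8): 0.45, (9, 13): 0.40, (14, 18): 0.35,
        (19, 30): 0.30, (31, 50): 0.25, (51, 69): 0.25,
    }
    out = {}
    for (lo, hi), p in values.items():
        out[(lo, hi, "male")] = p
        out[(lo, hi, "female")] = p + 0.05
    return out


@dataclass
class GroundTruth:
    """Full parameterisation of the synthetic survey; see module docstring."""

    natural: SourceParams = field(
        default_factory=lambda: SourceParams(
            lam=0.0, intercept=4.55, age_slope=0.008, sigma_between=0.25, sigma_within=0.35
        )
    )
    natural_group_shares: dict = field(
        default_factory=lambda: {"dairy": 0.45, "drinks": 0.20, "cereals": 0.20, "fruit": 0.15}
    )
    bread_amount: SourceParams = field(
        default_factory=lambda: SourceParams(
            lam=0.0, intercept=4.4, age_slope=0.006, sigma_between=0.30, sigma_within=0.40
        )
    )
    bread_episodic: EpisodicParams = field(
        default_factory=lambda: EpisodicParams(consumption_prob=0.95, never_consumer_fraction=0.02)
    )
    pizza_amount: SourceParams = field(
        default_factory=lambda: SourceParams(lam=0.0, intercept=5.3, sigma_between=0.2, sigma_within=0.3)
    )
    pizza_episodic: EpisodicParams = field(
        default_factory=lambda: EpisodicParams(consumption_prob=0.08, never_consumer_fraction=0.40)
    )
    disc_amounts: dict = field(
        default_factory=lambda: {
            "potatoes": SourceParams(lam=0.0, intercept=5.0, sigma_between=0.3, sigma_within=0.4),
            "vegetables": SourceParams(lam=0.0, intercept=4.9, sigma_between=0.3, sigma_within=0.4),
            "meat": SourceParams(lam=0.0, intercept=4.6, sigma_between=0.3, sigma_within=0.4),
        }
    )
    disc_episodic: dict = field(
        default_factory=lambda: {
            "potatoes": EpisodicParams(consumption_prob=0.75),
            "vegetables": EpisodicParams(consumption_prob=0.80),
            "meat": EpisodicParams(consumption_prob=0.70),
        }
    )
    never_discretionary: dict = field(default_factory=_default_never_props)
    known_status_fraction: float = 1.0 / 3.0  # survey year with the salt questionnaire
    supplement: SupplementTruth = field(default_factory=SupplementTruth)
    age_range: tuple = (7, 69)

    def never_prop(self, age: int, sex: str) -> float:
        for (lo, hi, s), p in self.never_discretionary.items():
            if s == sex and lo <= age <= hi:
                return p
        raise ValidationError(f"no never-discretionary proportion for age {age}, sex {sex}")


#: Conditions for the parameter-recovery suite: identity transform, constant
#: age mean 150 µg/d, sigma_b = 20, sigma_w = 30.
def recovery_truth() -> GroundTruth:
    return GroundTruth(
        natural=SourceParams(lam=1.0, intercept=150.0, age_slope=0.0,
                             sigma_between=20.0, sigma_within=30.0),
    )


def synthetic_composition() -> list[FoodComposition]:
    """The fixed synthetic food list (one food per modelled group).

    Foods in the manufacturer-salt and discretionary branches carry zero
    natural iodine so that each branch's ground truth stays exact; bread and
    pizza are produced with salt, hence never discretionary-eligible.
    """
    return [
        FoodComposition("milk", iodine_nat=16.0, added_salt=0.0),
        FoodComposition("water", iodine_nat=8.0, added_salt=0.0),
        FoodComposition("cereal", iodine_nat=12.0, added_salt=0.0),
        FoodComposition("fruit", iodine_nat=5.0, added_salt=0.0),
        FoodComposition("bread", iodine_nat=0.0, added_salt=1.25,
                        manufacturer_group="bread", produced_with_salt=True),
        FoodComposition("pizza", iodine_nat=0.0, added_salt=1.5,
                        manufacturer_group="pizza", produced_with_salt=True),
        FoodComposition("potatoes", iodine_nat=0.0, added_salt=0.0,
                        discretionary_eligible=True),
        FoodComposition("vegetables", iodine_nat=0.0, added_salt=0.0,
                        discretionary_eligible=True),
        FoodComposition("meat", iodine_nat=0.0, added_salt=0.0,
                        discretionary_eligible=True),
        FoodComposition("snack", iodine_nat=0.0, added_salt=1.0,
                        produced_with_salt=True),
    ]

FOOD_GROUP = {
    "milk": "dairy", "water": "drinks", "cereal": "cereals", "fruit": "fruit",
    "bread": "bread", "pizza": "pizza", "potatoes": "potatoes",
    "vegetables": "vegetables", "meat": "meat", "snack": "snacks",
}
NATURAL_FOOD = {"dairy": "milk", "drinks": "water", "cereals": "cereal", "fruit": "fruit"}


def generate_population(
    n: int, strata_weights: dict | None = None, seed: int = 0,
    age_range: tuple = (7, 69),
) -> list[Subject]:
    """Draw ``n`` subjects stratified by age band and sex.

    ``strata_weights`` maps ``((age_low, age_high), sex)`` to the target
    population share (any nonnegative numbers, not all zero); the default is
    uniform over the six reporting bands x sex.  Survey weights are inverse
    sampling fractions: population share / realised sample share.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if strata_weights is None:
        strata_weights = {(band, sex): 1.0 for band in AGE_BANDS for sex in ("male", "female")}
    keys = sorted(strata_weights, key=str)
    probs = np.array([strata_weights[k] for k in keys], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValidationError("strata weights must be nonnegative and not all zero")
    probs = probs / probs.sum()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 100)))
    counts = rng.multinomial(n, probs)
    subjects = []
    i = 0
    for (band, sex), count in zip(keys, counts):
        lo, hi = max(band[0], age_range[0]), min(band[1], age_range[1])
        ages = rng.integers(lo, hi + 1, size=count)
        share = probs[keys.index((band, sex))]
        weight = share / (count / n) if count else 1.0
        for age in ages:
            subjects.append(
                Subject(
                    subject_id=f"s{i:05d}",
                    age=int(age),
                    sex=sex,
                    survey_weight=float(weight),
                )
            )
            i += 1
    return subjects


def _person_day_amounts(
    rng: np.random.Generator, params: SourceParams, ages: np.ndarray
) -> np.ndarray:
    """(n, 2) array of back-transformed person-day values, clipped at 0."""
    n = len(ages)
    b = rng.normal(0.0, params.sigma_between, size=n)
    e = rng.normal(0.0, params.sigma_within, size=(n, 2))
    y = params.mean_at(ages)[:, None] + b[:, None] + e
    return np.maximum(boxcox_inverse(y, params.lam), 0.0)


def generate_recalls(
    population: list[Subject], ground_truth: GroundTruth, seed: int = 0
):
    """Generate 2-day consumption records and the composition table.

    Also annotates the passed population in place: salt-questionnaire
    status (known for a ``known_status_fraction`` of subjects, mirroring
    the survey year that carried the questionnaire) and supplement recall /
    questionnaire fields.  Returns ``(records, composition)``.
    """
    gt = ground_truth
    rng = np.random.default_rng(np.random.SeedSequence((seed, 200)))
    ages = np.array([s.age for s in population], dtype=float)
    n = len(population)
    records = []

    # (a) natural source: split the person-day total over the natural groups
    totals = _person_day_amounts(rng, gt.natural, ages)
    comp = {f.food_code: f for f in synthetic_composition()}
    for i, s in enumerate(population):
        for day in (1, 2):
            t = totals[i, day - 1]
            if t <= 0:
                continue
            for group, share in gt.natural_group_shares.items():
                food = NATURAL_FOOD[group]
                conc = comp[food].iodine_nat
                amount = share * t / (conc / 100.0)
                if amount > 0:
                    records.append((s.subject_id, day, food, group, amount))

    # (b) manufacturer foods: bread (near-daily) and pizza (episodic)
    for food, amount_params, episodic in (
        ("bread", gt.bread_amount, gt.bread_episodic),
        ("pizza", gt.pizza_amount, gt.pizza_episodic),
    ):
        never = rng.random(n) < episodic.never_consumer_fraction
        amounts = _person_day_amounts(rng, amount_params, ages)
        eats = rng.random((n, 2)) < episodic.consumption_prob
        for i, s in enumerate(population):
            if never[i]:
                continue
            for day in (1, 2):
                if eats[i, day - 1] and amounts[i, day - 1] > 0:
                    records.append(
                        (s.subject_id, day, food, FOOD_GROUP[food], amounts[i, day - 1])
                    )

    # (c) discretionary-eligible groups
    for group, amount_params in gt.disc_amounts.items():
        episodic = gt.disc_episodic.get(group, EpisodicParams())
        never = rng.random(n) < episodic.never_consumer_fraction
        amounts = _person_day_amounts(rng, amount_params, ages)
        eats = rng.random((n, 2)) < episodic.consumption_prob
        for i, s in enumerate(population):
            if never[i]:
                continue
            for day in (1, 2):
                if eats[i, day - 1] and amounts[i, day - 1] > 0:
                    records.append((s.subject_id, day, group, group, amounts[i, day - 1]))

    # salt-questionnaire status: known for the questionnaire-year subjects
    known = rng.random(n) < gt.known_status_fraction
    for i, s in enumerate(population):
        if known[i]:
            p_never = gt.never_prop(s.age, s.sex)
            s.discretionary_status = (
                "never_adds_salt" if rng.random() < p_never else "adds_salt"
            )
        else:
            s.discretionary_status = "unknown"

    # (d) supplements
    supp = gt.supplement
    users = rng.random(n) < supp.user_fraction
    for i, s in enumerate(population):
        s.supplement_recall = {}
        s.supplement_questionnaire_user = False
        if not users[i]:
            continue
        dose = float(rng.choice(supp.doses, p=supp.dose_probs))
        reported = {day for day in (1, 2) if rng.random() < supp.report_prob}
        s.supplement_recall = {day: dose for day in sorted(reported)}
        s.supplement_questionnaire_user = True

    from .datatypes import ConsumptionRecord

    record_objs = [
        ConsumptionRecord(subject_id=sid, day=day, food_code=code, food_group=grp, amount=amt)
        for sid, day, code, grp, amt in records
    ]
    return record_objs, synthetic_composition()


def true_prevalence_below(params: SourceParams, threshold: float, age: float | None = None):
    """Analytic P(habitual < threshold) for a one-part source.

    Defined in closed form for the identity (``lam=1``) and log (``lam=0``)
    transforms with a constant age mean (or a supplied ``age``): habitual
    intake is Normal(f, sigma_b^2) for lam=1 and
    exp(N(f, sigma_b^2)) x exp(sigma_w^2 / 2) for lam=0.
    """
    if params.age_slope != 0.0 and age is None:
        raise ValidationError("age-dependent mean: pass the age to evaluate at")
    f = float(params.mean_at(age if age is not None else 0.0))
    if params.lam == 1.0:
        if params.sigma_between == 0.0:
            return float(max(f, 0.0) < threshold)
        if threshold <= 0.0:  # daily values are clipped at zero
            return 0.0
        return float(stats.norm.cdf((threshold - f) / params.sigma_between))
    if params.lam == 0.0:
        if threshold <= 0.0:
            return 0.0
        shifted = np.log(threshold) - params.sigma_within**2 / 2.0
        if params.sigma_between == 0.0:
            return float(f < shifted)
        return float(stats.norm.cdf((shifted - f) / params.sigma_between))
    raise ValidationError("closed form available only for lam in {0, 1}")


def simulate_dataset(
    n: int = 2000,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
    preset: str | None = None,
):
    """Generate a full dataset; returns (subjects, records, composition, truth).

    ``preset='recovery'`` uses the parameter-recovery conditions
    (lam=1, f=150, sigma_b=20, sigma_w=30); the default preset is the
    survey-like parameterisation of :class:`GroundTruth`.
    """
    if ground_truth is None:
        if preset == "recovery":
            ground_truth = recovery_truth()
        elif preset in (None, "survey"):
            ground_truth = GroundTruth()
        else:
            raise ValidationError(f"unknown preset {preset!r}")
    subjects = generate_population(n, seed=seed, age_range=ground_truth.age_range)
    records, composition = generate_recalls(subjects, ground_truth, seed=seed)
    return subjects, records, composition, ground_truth
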