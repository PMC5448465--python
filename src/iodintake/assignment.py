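"""Monte Carlo assignment of iodised-salt use.

Detailed information on who uses iodised salt is lacking in the survey, so
salt use is assigned probabilistically and the assignment repeated (100
iterations by default) to quantify the assumption uncertainty:

* discretionary use — within each (age band, sex) stratum, a fraction of
  the status-unknown subjects equal to the configured never-user proportion
  is drawn (without replacement) as never-users; subjects whose
  questionnaire status is known keep it deterministically in every
  iteration;
* iodised-variant consumption — per manufacturer food group, a fraction of
  its consumers equal to the market share is assigned to the
  iodised-salt-containing product; per discretionary-eligible food group, a
  configured fraction of the salt-adding consumers of the group is assigned
  to actually salt that group.

Sampling is exact-fraction (permute the candidates and take
``round-half-even(p x n)`` of them) rather than independent Bernoulli
draws, which reproduces the fixed-proportion design and removes binomial
noise from the assigned counts.  Randomness derives from
``numpy.random.SeedSequence((root_seed, iteration, stream))`` so each
iteration is independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FoodComposition, SaltPolicy, Subject, ValidationError
from .io_config import composition_frame, records_frame


@dataclass
class Assignment:
    """One Monte Carlo realisation of all salt-use flags."""

    iteration: int
    discretionary_user: dict[str, bool] = field(default_factory=dict)
    adds_salt: set = field(default_factory=set)  # (subject_id, food_group)
    iodised: set = field(default_factory=set)  # (subject_id, manufacturer_group)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def _take_fraction(rng: np.random.Generator, candidates: list[str], fraction: float) -> set:
    """Draw round-half-even(fraction x n) candidates without replacement."""
    n_take = _round_half_even(fraction * len(candidates))
    if n_take <= 0:
        return set()
    perm = rng.permutation(len(candidates))
    return {candidates[i] for i in perm[:n_take]}


def _rng(seed: int, iteration: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, iteration, stream)))


def draw_discretionary(
    subjects: list[Subject], policy: SaltPolicy, seed: int, iteration: int
) -> dict[str, bool]:
    """Per-subject discretionary-salt-user flags for one iteration.

    Known questionnaire status (collected in the 3rd survey year) passes
    through deterministically; unknown-status subjects are sampled within
    their (age band, sex) stratum at the configured never-user proportion.
    """
    unknown = [s for s in subjects if s.discretionary_status == "unknown"]
    policy.check_coverage([s.age for s in unknown], [s.sex for s in unknown])
    flags = {}
    for s in subjects:
        if s.discretionary_status == "never_adds_salt":
            flags[s.subject_id] = False
        elif s.discretionary_status == "adds_salt":
            flags[s.subject_id] = True
    rng = _rng(seed, iteration, 0)
    strata: dict[tuple, list[str]] = {}
    for s in unknown:
        strata.setdefault(policy.never_user_band(s.age, s.sex), []).append(s.subject_id)
    for band in sorted(strata):
        members = sorted(strata[band])
        never = _take_fraction(rng, members, policy.never_user_proportions[band])
        for sid in members:
            flags[sid] = sid not in never
    return flags


def draw_food_group_use(
    subjects: list[Subject],
    records,
    composition: list[FoodComposition],
    policy: SaltPolicy,
    seed: int,
    iteration: int,
    discretionary_user: dict[str, bool] | None = None,
) -> tuple[set, set]:
    """Draw (adds_salt, iodised) flag sets for one iteration.

    Flags are drawn only among consumers of each group — subjects with at
    least one recall record of the group.  Within an iteration, a subject's
    products in a group are all iodised or all not (subject-level
    assignment).
    """
    if discretionary_user is None:
        discretionary_user = draw_discretionary(subjects, policy, seed, iteration)
    rec = records_frame(records) if not isinstance(records, pd.DataFrame) else records
    comp = composition_frame(composition) if not isinstance(composition, pd.DataFrame) else composition
    df = rec.join(comp, on="food_code")

    # manufacturer groups present in the records must have a policy entry
    man = df[df["manufacturer_group"].notna()]
    missing = sorted(set(man["manufacturer_group"]) - set(policy.manufacturer))
    if missing:
        raise ValidationError(f"manufacturer group(s) absent from policy: {missing}")
    rng_man = _rng(seed, iteration, 1)
    iodised: set = set()
    for group in sorted(policy.manufacturer):
        consumers = sorted(set(man.loc[man["manufacturer_group"] == group, "subject_id"]))
        share = policy.manufacturer[group].market_share
        iodised |= {(sid, group) for sid in _take_fraction(rng_man, consumers, share)}

    disc = df[df["discretionary_eligible"] & ~df["produced_with_salt"]]
    missing = sorted(set(disc["food_group"]) - set(policy.discretionary_groups))
    if missing:
        raise ValidationError(f"discretionary food group(s) absent from policy: {missing}")
    rng_disc = _rng(seed, iteration, 2)
    adds_salt: set = set()
    for group in sorted(policy.discretionary_groups):
        consumers = sorted(
            sid
            for sid in set(disc.loc[disc["food_group"] == group, "subject_id"])
            if discretionary_user.get(sid, False)
        )
        frac = policy.discretionary_groups[group].use_fraction
        adds_salt |= {(sid, group) for sid in _take_fraction(rng_disc, consumers, frac)}
    return adds_salt, iodised


def draw_assignment(
    subjects: list[Subject],
    records,
    composition: list[FoodComposition],
    policy: SaltPolicy,
    seed: int,
    iteration: int,
) -> Assignment:
    """One complete assignment realisation, reproducible from (seed, iteration)."""
    disc_user = draw_discretionary(subjects, policy, seed, iteration)
    adds_salt, iodised = draw_food_group_use(
        subjects, records, composition, policy, seed, iteration,
        discretionary_user=disc_user,
    )
    return Assignment(
        iteration=iteration,
        discretionary_user=disc_user,
        adds_salt=adds_salt,
        iodised=iodised,
    )


def build_ensemble(
    subjects: list[Subject],
    records,
    composition: list[FoodComposition],
    policy: SaltPolicy,
    n_iterations: int,
    seed: int,
) -> list[Assignment]:
    """Independent assignment realisations for iterations 0..n-1."""
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    return [
        draw_assignment(subjects, records, composition, policy, seed, i)
        for i in range(n_iterations)
    ]
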