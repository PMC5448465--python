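"""Monte Carlo combination of the four source distributions and evaluation.

The four habitual distributions (natural, manufacturer salt, discretionary
salt, supplements) are combined "first shrink then add": each source is
shrunken to its habitual per-person values separately, then a large Monte
Carlo sample of simulated individuals sums one habitual draw per source.
Draws are independent across sources conditional on the (age band, sex)
stratum — the key structural assumption; ``match_persons=True`` instead
keeps a subject's four sources attached (rank-correlated alternative for
sensitivity analysis).

Adequacy is evaluated with the EAR cut-point method (fraction of the
habitual distribution below the band's EAR) and safety as the fraction
above the UL.  Repeating the whole combination over the assignment ensemble
yields, per reported statistic, a median, SD and 2.5-97.5 range that
quantify the iodised-salt assumption uncertainty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DRITable, SaltPolicy, Subject, ValidationError
from . import assignment as assign_mod
from . import tabulation
from .habitual import (
    IntakeDistribution,
    OnePartModel,
    SupplementModel,
    TwoPartModel,
)

REPORT_PERCENTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


def _strata_from_bands(dist: IntakeDistribution, bands) -> list[np.ndarray]:
    masks = []
    for band in bands:
        lo, hi, sex = band
        masks.append((dist.age >= lo) & (dist.age <= hi) & (dist.sex == sex))
    return masks


def combine_sources(
    dists: dict[str, IntakeDistribution],
    mc_size: int,
    seed,
    bands=None,
    match_persons: bool = False,
    return_components: bool = False,
):
    """Simulate ``mc_size`` individuals summing one habitual value per source.

    ``bands`` is a list of ``(age_low, age_high, sex)`` strata; by default a
    single stratum covers the whole population.  A stratum is drawn with
    probability proportional to its survey weight, then one value per
    source is drawn within the stratum (weighted), independently across
    sources unless ``match_persons``.
    """
    names = list(dists)
    if not names:
        raise ValidationError("no source distributions to combine")
    ref = dists[names[0]]
    n = len(ref)
    for name in names[1:]:
        if len(dists[name]) != n:
            raise ValidationError("source distributions cover different populations")
    rng = np.random.default_rng(seed)

    if bands is None or ref.age is None:
        masks = [np.ones(n, dtype=bool)]
        band_list = [None]
    else:
        masks = _strata_from_bands(ref, bands)
        covered = np.logical_or.reduce(masks)
        if not covered.all():
            raise ValidationError("strata do not cover the whole population")
        band_list = list(bands)

    w = ref.weights
    stratum_w = np.array([w[m].sum() for m in masks], dtype=float)
    keep = stratum_w > 0
    masks = [m for m, k in zip(masks, keep) if k]
    band_list = [b for b, k in zip(band_list, keep) if k]
    stratum_w = stratum_w[keep]
    counts = rng.multinomial(mc_size, stratum_w / stratum_w.sum())

    total = np.empty(mc_size)
    sim_age = np.empty(mc_size)
    sim_sex = np.empty(mc_size, dtype=object)
    components = {name: np.empty(mc_size) for name in names}
    pos = 0
    for mask, band, n_s in zip(masks, band_list, counts):
        if n_s == 0:
            continue
        idx = np.flatnonzero(mask)
        p = w[idx] / w[idx].sum()
        sl = slice(pos, pos + n_s)
        if match_persons:
            draw = rng.choice(idx, size=n_s, p=p)
            for name in names:
                components[name][sl] = dists[name].values[draw]
        else:
            for name in names:
                draw = rng.choice(idx, size=n_s, p=p)
                components[name][sl] = dists[name].values[draw]
            draw = rng.choice(idx, size=n_s, p=p)  # carrier of age/sex labels
        if ref.age is not None:
            sim_age[sl] = ref.age[draw]
            sim_sex[sl] = ref.sex[draw]
        elif band is not None:
            sim_age[sl] = 0.5 * (band[0] + band[1])
            sim_sex[sl] = band[2]
        pos += n_s
    total = np.sum([components[name] for name in names], axis=0)

    dist = IntakeDistribution(
        values=total,
        weights=np.ones(mc_size),
        age=sim_age if ref.age is not None else None,
        sex=sim_sex if ref.sex is not None else None,
    )
    if return_components:
        return dist, components
    return dist


def prevalence(dist: IntakeDistribution, dri: DRITable, band) -> tuple[float, float]:
    """(fraction below EAR, fraction above UL) for subjects in the band."""
    if not isinstance(band, tuple):
        band = (band.age_low, band.age_high, band.sex)
    lo, hi, sex = band
    sub = dist.band_subset(lo, hi, sex)
    matches = [b for b in dri.bands if (b.age_low, b.age_high, b.sex) == (lo, hi, sex)]
    if not matches:
        raise ValidationError(f"band ({lo}-{hi}, {sex}) not in the DRI table")
    ref = matches[0]
    return sub.prob_below(ref.ear), sub.prob_above(ref.ul)


def source_shares(dists: dict[str, IntakeDistribution]) -> dict[str, dict[str, float]]:
    """Average contribution of each source to the total intake.

    Per individual each source's habitual value is divided by the total
    habitual; the survey-weighted mean and SD of these fractions are
    reported per source.  Individuals with a zero total carry no defined
    share and are excluded (their count is warned about and reported).
    """
    names = list(dists)
    ref = dists[names[0]]
    values = np.stack([dists[name].values for name in names])
    totals = values.sum(axis=0)
    keep = totals > 0
    n_excluded = int((~keep).sum())
    if n_excluded == len(totals):
        raise ValidationError("every individual has zero total intake")
    if n_excluded:
        warnings.warn(f"{n_excluded} individual(s) with zero total excluded from shares",
                      stacklevel=2)
    w = ref.weights[keep]
    out = {"n_excluded": n_excluded}
    for name, v in zip(names, values):
        share = v[keep] / totals[keep]
        mean = float(np.average(share, weights=w))
        sd = float(np.sqrt(np.average((share - mean) ** 2, weights=w)))
        out[name] = {"mean": mean, "sd": sd}
    return out


def _flatten(stats: dict, prefix: str = "") -> dict[str, float]:
    flat = {}
    for key, value in stats.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = float(value)
    return flat


def summarise_ensemble(per_iteration: list[dict]) -> dict[str, dict[str, float]]:
    """Median, SD and 2.5-97.5 range across iterations for every statistic.

    Accepts a list of (possibly nested) dicts of scalars — one per
    iteration — and returns, per flattened key, the ensemble summary.
    """
    if not per_iteration:
        raise ValidationError("at least one iteration is required")
    flats = [_flatten(stats) for stats in per_iteration]
    keys = flats[0].keys()
    out = {}
    for key in keys:
        arr = np.array([f[key] for f in flats], dtype=float)
        out[key] = {
            "median": float(np.median(arr)),
            "sd": float(np.std(arr)),
            "q025": float(np.quantile(arr, 0.025)),
            "q975": float(np.quantile(arr, 0.975)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    return out


@dataclass
class TotalIntakeResult:
    """Everything the pipeline computes, plus the ensemble summary."""

    per_iteration: list[dict]
    summary: dict
    natural_fit: OnePartModel
    group_contributions: pd.Series
    config: dict = field(default_factory=dict)

    def to_report(self) -> dict:
        return {
            "config": self.config,
            "group_contributions": {
                str(k): float(v) for k, v in self.group_contributions.items()
            },
            "natural_fit": self.natural_fit.to_dict(),
            "ensemble_summary": self.summary,
            "n_iterations": len(self.per_iteration),
        }


def _iteration_statistics(
    total: IntakeDistribution,
    dists: dict[str, IntakeDistribution],
    dri: DRITable,
) -> dict:
    stats: dict = {"overall": {}}
    for p, v in zip(REPORT_PERCENTILES, np.atleast_1d(total.percentile(REPORT_PERCENTILES))):
        stats["overall"][f"p{int(p * 100):02d}"] = float(v)
    for band in dri.bands:
        try:
            sub = total.band_subset(band.age_low, band.age_high, band.sex)
        except ValidationError:
            continue  # band empty in this simulated population
        entry = {}
        for p, v in zip(REPORT_PERCENTILES, np.atleast_1d(sub.percentile(REPORT_PERCENTILES))):
            entry[f"p{int(p * 100):02d}"] = float(v)
        entry["pct_below_ear"] = 100.0 * sub.prob_below(band.ear)
        entry["pct_above_ul"] = 100.0 * sub.prob_above(band.ul)
        stats[band.label] = entry
    shares = source_shares(dists)
    stats["shares_pct"] = {
        name: {"mean": 100.0 * s["mean"], "sd": 100.0 * s["sd"]}
        for name, s in shares.items()
        if isinstance(s, dict)
    }
    return stats


def run_pipeline(
    subjects: list[Subject],
    records,
    composition,
    policy: SaltPolicy,
    dri: DRITable,
    n_iterations: int = 100,
    mc_size: int = 100_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    match_persons: bool = False,
) -> TotalIntakeResult:
    """End-to-end estimation of the habitual total iodine intake distribution.

    Stages: tabulate daily intakes; fit the natural-source one-part model
    and the supplement model once (they do not depend on salt assignments);
    per assignment iteration, tabulate the two iodised-salt sources, fit
    their two-part models, combine the four habitual distributions by Monte
    Carlo and evaluate percentiles and %<EAR / %>UL per DRI band; finally
    summarise the ensemble.  Deterministic given ``seed``.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    nat_daily = stage("tabulation/natural", tabulation.natural_iodine,
                      records, composition, subjects)
    nat_fit = stage("habitual/natural", OnePartModel().fit, nat_daily, subjects)
    nat_dist = nat_fit.habitual_values()
    supp_dist = stage(
        "habitual/supplement",
        lambda: SupplementModel().fit(subjects).habitual_values(),
    )
    contributions = stage("tabulation/contributions", tabulation.group_contributions,
                          records, composition, subjects)

    bands = [(b.age_low, b.age_high, b.sex) for b in dri.bands]
    per_iteration = []
    for i in range(n_iterations):
        asg = stage("assignment", assign_mod.draw_assignment,
                    subjects, records, composition, policy, seed, i)
        man_daily = stage("tabulation/manufacturer", tabulation.manufacturer_iodine,
                          records, composition, policy, asg, subjects)
        disc_daily = stage("tabulation/discretionary", tabulation.discretionary_iodine,
                           records, composition, policy, subjects, asg)

        consumed_groups = {(sid, g) for (sid, g) in asg.iodised}
        man_never = [
            s.subject_id for s in subjects
            if not any(key[0] == s.subject_id for key in consumed_groups)
        ]
        disc_never = [
            s.subject_id for s in subjects if not asg.discretionary_user.get(s.subject_id, False)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            man_dist = stage(
                "habitual/manufacturer",
                lambda: TwoPartModel().fit(man_daily, subjects, never_consumers=man_never
                                           ).habitual_values(),
            )
            disc_dist = stage(
                "habitual/discretionary",
                lambda: TwoPartModel().fit(disc_daily, subjects, never_consumers=disc_never
                                           ).habitual_values(),
            )
        dists = {
            "natural": nat_dist,
            "manufacturer_salt": man_dist,
            "discretionary_salt": disc_dist,
            "supplement": supp_dist,
        }
        total = stage(
            "combine", combine_sources,
            dists, mc_size, np.random.SeedSequence((seed, 300, i)),
            bands=bands, match_persons=match_persons,
        )
        per_iteration.append(stage("evaluate", _iteration_statistics, total, dists, dri))

    summary = summarise_ensemble(per_iteration)
    result = TotalIntakeResult(
        per_iteration=per_iteration,
        summary=summary,
        natural_fit=nat_fit,
        group_contributions=contributions,
        config={
            "seed": seed,
            "n_iterations": n_iterations,
            "mc_size": mc_size,
            "match_persons": match_persons,
            "n_subjects": len(subjects),
        },
    )
    if out_dir is not None:
        write_report(result, dri, Path(out_dir))
    return result


def write_report(result: TotalIntakeResult, dri: DRITable, out_dir: Path) -> None:
    """Write report.json plus CSV tables (intake summary and contributions)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.to_report(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    rows = []
    for band in dri.bands:
        label = band.label
        row = {"band": label, "ear": band.ear, "ul": band.ul}
        for stat in ("p05", "p25", "p50", "p75", "p95", "pct_below_ear", "pct_above_ul"):
            key = f"{label}.{stat}"
            if key in result.summary:
                row[f"{stat}_median"] = result.summary[key]["median"]
                row[f"{stat}_sd"] = result.summary[key]["sd"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "intake_summary.csv", index=False)

    contrib = result.group_contributions.rename("weighted_mean_fraction")
    contrib.rename_axis("food_group").reset_index().to_csv(
        out_dir / "contributions.csv", index=False
    )
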