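"""Habitual (usual) intake estimation from 2-day recall data.

The measurement-error model works on a Box-Cox transformed scale:

.. math::

    y_{ij} = f(\\mathrm{age}_i) + b_i + e_{ij},
    \\qquad b_i \\sim N(0, \\sigma^2_b), \\; e_{ij} \\sim N(0, \\sigma^2_w),

where :math:`f` is a cubic B-spline age trend fitted separately by sex,
:math:`b_i` the person effect (between-person variation) and :math:`e_{ij}`
the day-to-day (within-person) variation.  A subject's habitual intake is the
expectation of the back-transformed daily intake over the within-person
noise, evaluated at the shrunken (BLUP) person effect:

.. math::

    H_i = \\int g^{-1}\\bigl(f(\\mathrm{age}_i) + \\hat b_i + e\\bigr)
          \\,\\varphi(e; \\sigma^2_w)\\,de,

computed by Gauss-Hermite quadrature.  Shrinkage pulls the observed 2-day
mean toward the age-specific population mean in proportion to the
within-person noise; the variance of the habitual values is therefore
smaller than the variance of raw 2-day means.

Three estimators cover the source types:

* :class:`OnePartModel` — sources consumed by (nearly) everyone every day
  (iodine naturally present in foods);
* :class:`TwoPartModel` — episodically consumed sources with true
  non-consumers (iodised salt from manufacturers or added discretionarily):
  habitual intake = P(consumption day) x habitual amount on consumption
  days, and structural zeros for never-consumers;
* :class:`SupplementModel` — supplemental iodine: reported recall amounts
  are taken as the habitual amount; questionnaire-only users receive a
  regression-tree prediction; non-users contribute zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from sklearn.tree import DecisionTreeRegressor

from .datatypes import Subject, ValidationError
from .io_config import subjects_frame

#: Tukey ladder of candidate Box-Cox powers profiled during fitting.
LAMBDA_LADDER = (0.0, 0.25, 1.0 / 3.0, 0.5, 2.0 / 3.0, 1.0)


# ---------------------------------------------------------------------------
# transforms

def boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox power transform.

    ``lam=0`` is the natural log and ``lam=1`` the plain identity (the
    conventional ``-1/lam`` affine shift is dropped for lam in {0, 1}; an
    affine shift on the transformed scale only moves the intercept and has
    no effect on variance components or habitual values).
    """
    x = np.asarray(x, dtype=float)
    if lam == 0.0:
        return np.log(x)
    if lam == 1.0:
        return x
    return (np.power(x, lam) - 1.0) / lam


def boxcox_inverse(y: np.ndarray, lam: float) -> np.ndarray:
    """Inverse of :func:`boxcox_transform`; out-of-image arguments clamp to 0."""
    y = np.asarray(y, dtype=float)
    if lam == 0.0:
        return np.exp(y)
    if lam == 1.0:
        return y
    arg = np.maximum(lam * y + 1.0, 0.0)
    with np.errstate(divide="ignore"):  # lam < 0 tails surface as inf, caught later
        return np.power(arg, 1.0 / lam)


def _select_lambda(pooled: np.ndarray, ladder=LAMBDA_LADDER) -> float:
    """Profile the Box-Cox log-likelihood over the ladder of powers."""
    if np.ptp(pooled) == 0.0:  # constant data: any power works; keep identity
        return 1.0
    llf = [stats.boxcox_llf(lam, pooled) for lam in ladder]
    return float(ladder[int(np.argmax(llf))])


# ---------------------------------------------------------------------------
# age trend basis

def _spline_knots(ages: np.ndarray, n_interior: int, degree: int = 3):
    """Clamped B-spline knot vector with interior knots at age quantiles.

    Falls back to a lower degree (down to a constant) when the ages do not
    support the requested basis — degenerate fixtures with a single age are
    fitted with an intercept only.
    """
    lo, hi = float(np.min(ages)), float(np.max(ages))
    n_distinct = len(np.unique(ages))
    if n_distinct == 1 or lo == hi:
        return None  # intercept-only
    degree = min(degree, n_distinct - 1)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(ages, qs)
        interior = np.unique(interior[(interior > lo) & (interior < hi)])
    else:
        interior = np.array([])
    # basis size must not exceed the number of distinct ages
    while degree + 1 + len(interior) > n_distinct and len(interior) > 0:
        interior = interior[:-1]
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return t, degree


def _design(ages: np.ndarray, knots) -> np.ndarray:
    if knots is None:
        return np.ones((len(ages), 1))
    t, degree = knots
    clipped = np.clip(ages, t[degree], t[-degree - 1])
    return interpolate.BSpline.design_matrix(clipped, t, degree).toarray()


@dataclass
class _AgeTrend:
    """Weighted least-squares B-spline fit of a response on age."""

    knots: object
    coef: np.ndarray

    @classmethod
    def fit(cls, ages, y, weights, n_interior: int) -> "_AgeTrend":
        ages = np.asarray(ages, float)
        knots = _spline_knots(ages, n_interior)
        X = _design(ages, knots)
        sw = np.sqrt(np.asarray(weights, float))
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return cls(knots=knots, coef=coef)

    def __call__(self, ages) -> np.ndarray:
        return _design(np.asarray(ages, float), self.knots) @ self.coef


# ---------------------------------------------------------------------------
# weighted distribution container

@dataclass
class IntakeDistribution:
    """Weighted per-individual habitual intakes representing a population.

    Carries age and sex so that percentile and prevalence queries can be
    restricted to an age-sex band.
    """

    values: np.ndarray
    weights: np.ndarray
    age: np.ndarray | None = None
    sex: np.ndarray | None = None
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValidationError("values and weights must have the same shape")
        if len(self.values) == 0:
            raise ValidationError("empty intake distribution")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValidationError("weights must be positive and finite")
        for name in ("age", "sex", "subject_id"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr))

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    def percentile(self, p) -> np.ndarray | float:
        """Survey-weighted quantile(s): the smallest value whose weighted ECDF
        reaches ``p`` (inverse-ECDF definition, monotone in ``p``)."""
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any((p_arr <= 0) | (p_arr >= 1)):
            raise ValidationError("percentile probabilities must be in (0, 1)")
        order = np.argsort(self.values, kind="stable")
        v = self.values[order]
        cw = np.cumsum(self.weights[order])
        idx = np.searchsorted(cw / cw[-1], p_arr, side="left")
        out = v[np.minimum(idx, len(v) - 1)]
        return out if np.ndim(p) else float(out[0])

    def prob_below(self, threshold: float) -> float:
        return float(np.average(self.values < threshold, weights=self.weights))

    def prob_above(self, threshold: float) -> float:
        return float(np.average(self.values > threshold, weights=self.weights))

    def subset(self, mask: np.ndarray) -> "IntakeDistribution":
        if not np.any(mask):
            raise ValidationError("subset selects no individuals")
        return IntakeDistribution(
            values=self.values[mask],
            weights=self.weights[mask],
            age=None if self.age is None else self.age[mask],
            sex=None if self.sex is None else self.sex[mask],
            subject_id=None if self.subject_id is None else self.subject_id[mask],
        )

    def band_subset(self, age_low: int, age_high: int, sex: str) -> "IntakeDistribution":
        if self.age is None or self.sex is None:
            raise ValidationError("distribution carries no age/sex information")
        mask = (self.age >= age_low) & (self.age <= age_high) & (self.sex == sex)
        return self.subset(mask)

    def to_frame(self) -> pd.DataFrame:
        data = {"habitual_ug": self.values, "weight": self.weights}
        if self.subject_id is not None:
            data = {"subject_id": self.subject_id, **data}
        return pd.DataFrame(data)


def weighted_percentiles(dist: IntakeDistribution, probs) -> np.ndarray:
    """Module-level convenience wrapper over :meth:`IntakeDistribution.percentile`."""
    return np.atleast_1d(dist.percentile(np.asarray(probs, dtype=float)))


# ---------------------------------------------------------------------------
# daily intake plumbing

def _daily_frame(daily) -> pd.DataFrame:
    """Accept a tidy DataFrame (subject_id, day, intake[_ug]) and normalise."""
    df = pd.DataFrame(daily).copy()
    if "intake" not in df.columns and "intake_ug" in df.columns:
        df = df.rename(columns={"intake_ug": "intake"})
    needed = {"subject_id", "day", "intake"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"daily intake table must have columns {sorted(needed)}; got {list(df.columns)}"
        )
    return df[["subject_id", "day", "intake"]]


# ---------------------------------------------------------------------------
# one-part model

class OnePartModel:
    """Habitual intake for a source consumed on (essentially) every day.

    Parameters
    ----------
    lam : float or "ladder"
        Box-Cox power.  The default profiles the pooled Box-Cox
        log-likelihood over the Tukey ladder ``{0, 1/4, 1/3, 1/2, 2/3, 1}``;
        pass a number to fix the transformation.
    n_knots : int
        Interior knots of the cubic B-spline age trend (per sex).
    gh_order : int
        Gauss-Hermite quadrature order for back-transformation.
    weighted : bool
        Use survey weights in the age trend and variance components.
    min_days : int
        Minimum recall days per subject (2 for the full-survey design; the
        two-part amount model relaxes this to 1).

    Fitted attributes (trailing underscore) include ``lam_``, ``shift_``,
    ``sigma2_between_``, ``sigma2_within_``, ``trend_`` (per sex),
    ``shrunken_effect_`` and ``location_`` (``f(age_i) + b_i`` per subject,
    transformed scale).
    """

    def __init__(self, lam="ladder", n_knots: int = 3, gh_order: int = 15,
                 weighted: bool = True, min_days: int = 2):
        self.lam = lam
        self.n_knots = n_knots
        self.gh_order = gh_order
        self.weighted = weighted
        self.min_days = min_days

    def get_params(self) -> dict:
        return {
            "lam": self.lam,
            "n_knots": self.n_knots,
            "gh_order": self.gh_order,
            "weighted": self.weighted,
            "min_days": self.min_days,
        }

    def set_params(self, **params) -> "OnePartModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ----------------------------------------------------------

    def fit(self, daily, subjects: list[Subject]) -> "OnePartModel":
        df = _daily_frame(daily)
        sub = subjects_frame(subjects)
        counts = df.groupby("subject_id").size()
        missing = sub.index.difference(counts.index)
        short = counts[counts < self.min_days]
        if len(missing) or len(short):
            bad = sorted(set(missing) | set(short.index))
            raise ValidationError(
                f"subjects with fewer than {self.min_days} recall day(s): {bad[:10]}"
            )
        unknown = counts.index.difference(sub.index)
        if len(unknown):
            raise ValidationError(f"daily intakes reference unknown subjects: {sorted(unknown)[:10]}")

        x = df["intake"].to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValidationError("daily intakes must be >= 0")
        # incidental zeros: shift by half the minimum positive value
        self.shift_ = 0.0
        if np.any(x == 0):
            positive = x[x > 0]
            if len(positive) == 0:
                raise ValidationError("all daily intakes are zero; nothing to fit")
            self.shift_ = 0.5 * float(positive.min())
            warnings.warn(
                f"zero daily intakes shifted by {self.shift_:.4g} before transformation",
                stacklevel=2,
            )
        pooled = x + self.shift_

        self.lam_ = (
            _select_lambda(pooled) if isinstance(self.lam, str) else float(self.lam)
        )
        df = df.assign(y=boxcox_transform(pooled, self.lam_))

        per = df.groupby("subject_id")["y"].agg(["mean", "count"])
        per = per.join(sub, how="left")
        w = per["survey_weight"].to_numpy() if self.weighted else np.ones(len(per))

        # within-person variance from day-to-day differences (2-day subjects)
        two = df[df.groupby("subject_id")["day"].transform("size") >= 2]
        if len(two):
            wide = two.pivot_table(index="subject_id", columns="day", values="y")
            wide = wide.dropna()
            d = wide.iloc[:, 0].to_numpy() - wide.iloc[:, 1].to_numpy()
            wd = (
                sub.loc[wide.index, "survey_weight"].to_numpy()
                if self.weighted
                else np.ones(len(wide))
            )
            self.sigma2_within_ = float(np.average(d**2, weights=wd) / 2.0)
        else:
            self.sigma2_within_ = 0.0
            warnings.warn("no subject with 2 recall days; within-person variance set to 0",
                          stacklevel=2)

        # age trend per sex on subject means
        self.trend_ = {}
        fhat = np.empty(len(per))
        for sex, idx in per.groupby("sex").groups.items():
            rows = per.index.get_indexer(idx)
            trend = _AgeTrend.fit(
                per["age"].to_numpy()[rows],
                per["mean"].to_numpy()[rows],
                w[rows],
                self.n_knots,
            )
            self.trend_[sex] = trend
            fhat[rows] = trend(per["age"].to_numpy()[rows])

        resid = per["mean"].to_numpy() - fhat
        n_days = per["count"].to_numpy(dtype=float)
        m = len(per)
        var_means = float(np.average(resid**2, weights=w)) * (m / max(m - 1, 1))
        # Var(ybar_i) = sigma2_b + sigma2_w / n_i; use the typical n
        mean_inv_n = float(np.average(1.0 / n_days, weights=w))
        sigma2_b = var_means - self.sigma2_within_ * mean_inv_n
        if sigma2_b < 0:
            warnings.warn("between-person variance estimate clipped to 0", stacklevel=2)
            sigma2_b = 0.0
        self.sigma2_between_ = float(sigma2_b)

        # shrunken person effects, rescaled so their variance matches
        # sigma2_between: the raw BLUP distribution is too narrow by the
        # shrinkage factor, which would bias the tails of the population
        # habitual distribution
        denom = self.sigma2_between_ + self.sigma2_within_ / n_days
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(denom > 0, self.sigma2_between_ / denom, 0.0)
        self.shrinkage_ = k
        blup = k * resid
        var_blup = float(np.average(blup**2, weights=w)) * (m / max(m - 1, 1))
        if self.sigma2_between_ > 0 and var_blup > 0:
            scale = np.sqrt(self.sigma2_between_ / var_blup)
        else:
            scale = 0.0
        self.shrunken_effect_ = scale * blup
        self.location_ = fhat + self.shrunken_effect_
        self.subject_id_ = per.index.to_numpy()
        self.age_ = per["age"].to_numpy()
        self.sex_ = per["sex"].to_numpy()
        self.weight_ = per["survey_weight"].to_numpy()
        self.n_days_ = n_days
        self.subject_mean_y_ = per["mean"].to_numpy()
        return self

    # -- back-transformation ----------------------------------------------

    def _gh_expectation(self, mu: np.ndarray, sigma2: float) -> np.ndarray:
        """E[g^-1(mu + e)] with e ~ N(0, sigma2), by Gauss-Hermite quadrature."""
        if sigma2 <= 0:
            vals = boxcox_inverse(mu, self.lam_)
        else:
            nodes, wts = np.polynomial.hermite.hermgauss(self.gh_order)
            e = np.sqrt(2.0 * sigma2) * nodes
            grid = mu[:, None] + e[None, :]
            vals = boxcox_inverse(grid, self.lam_) @ (wts / np.sqrt(np.pi))
        if not np.all(np.isfinite(vals)):
            raise ValidationError(
                "back-transformation produced non-finite values; with a negative "
                "Box-Cox power, set a lambda floor (lam >= 0)"
            )
        return np.maximum(vals - self.shift_, 0.0)

    def habitual_values(self) -> IntakeDistribution:
        """Per-subject habitual intakes as a weighted population distribution."""
        self._check_fitted()
        values = self._gh_expectation(self.location_, self.sigma2_within_)
        return IntakeDistribution(
            values=values,
            weights=self.weight_,
            age=self.age_,
            sex=self.sex_,
            subject_id=self.subject_id_,
        )

    def predict_marginal(self, ages, sexes) -> np.ndarray:
        """Population-mean habitual intake at given ages/sexes, integrating
        over both person effect and within-person noise (used for subjects
        contributing no observed consumption day to the amount model)."""
        self._check_fitted()
        ages = np.asarray(ages, float)
        sexes = np.asarray(sexes)
        mu = np.empty(len(ages))
        for sex, trend in self.trend_.items():
            mask = sexes == sex
            if mask.any():
                mu[mask] = trend(ages[mask])
        leftover = ~np.isin(sexes, list(self.trend_))
        if leftover.any():
            any_trend = next(iter(self.trend_.values()))
            mu[leftover] = any_trend(ages[leftover])
        return self._gh_expectation(mu, self.sigma2_between_ + self.sigma2_within_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "lam_"):
            raise ValidationError("model is not fitted")

    def to_dict(self) -> dict:
        """JSON-serialisable audit summary of the fit."""
        self._check_fitted()
        return {
            "lam": self.lam_,
            "shift": self.shift_,
            "sigma2_between": self.sigma2_between_,
            "sigma2_within": self.sigma2_within_,
            "n_subjects": int(len(self.subject_id_)),
        }


def fit_one_part(daily, subjects: list[Subject], **params) -> OnePartModel:
    """Functional wrapper: fit a :class:`OnePartModel` and return it."""
    return OnePartModel(**params).fit(daily, subjects)


def habitual_values(fit: OnePartModel, subjects=None) -> IntakeDistribution:
    """Functional wrapper over :meth:`OnePartModel.habitual_values`."""
    return fit.habitual_values()


# ---------------------------------------------------------------------------
# two-part model

class TwoPartModel:
    """Two-part habitual intake for episodic sources with true non-consumers.

    The probability part models the chance that a potential consumer has a
    consumption day, as an age-dependent proportion per sex (logistic
    regression on the spline age basis).  The amount part is a
    :class:`OnePartModel` fitted to positive consumption days only.  Habitual
    intake is ``p_i x amount_i`` for potential consumers and a structural 0
    for never-consumers.
    """

    def __init__(self, lam="ladder", n_knots: int = 3, gh_order: int = 15,
                 weighted: bool = True):
        self.lam = lam
        self.n_knots = n_knots
        self.gh_order = gh_order
        self.weighted = weighted

    def get_params(self) -> dict:
        return {"lam": self.lam, "n_knots": self.n_knots,
                "gh_order": self.gh_order, "weighted": self.weighted}

    def fit(self, daily, subjects: list[Subject], never_consumers=()) -> "TwoPartModel":
        import statsmodels.api as sm

        df = _daily_frame(daily)
        sub = subjects_frame(subjects)
        never = set(never_consumers)
        unknown_never = never.difference(sub.index)
        if unknown_never:
            raise ValidationError(
                f"never_consumers reference unknown subjects: {sorted(unknown_never)[:10]}"
            )
        potential = [s for s in subjects if s.subject_id not in never]
        if not potential:
            raise ValidationError("no potential consumers")
        pot_ids = {s.subject_id for s in potential}
        dfp = df[df["subject_id"].isin(pot_ids)]
        positive = dfp[dfp["intake"] > 0]
        if positive.empty:
            raise ValidationError("no positive consumption days at all")

        # probability part: consumption-day indicators among potential consumers
        ind = dfp.assign(consumed=(dfp["intake"] > 0).astype(float))
        ind = ind.merge(sub.reset_index(), on="subject_id", how="left")
        self.prob_trend_ = {}
        if ind["consumed"].nunique() == 1:
            const_p = float(ind["consumed"].iloc[0])
            self.prob_trend_ = {"__const__": const_p}
        else:
            for sex, grp in ind.groupby("sex"):
                wts = grp["survey_weight"].to_numpy() if self.weighted else np.ones(len(grp))
                if grp["consumed"].nunique() == 1:
                    self.prob_trend_[sex] = ("const", float(grp["consumed"].iloc[0]), None)
                    continue
                knots = _spline_knots(grp["age"].to_numpy(float), self.n_knots)
                X = _design(grp["age"].to_numpy(float), knots)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.GLM(
                            grp["consumed"].to_numpy(),
                            X,
                            family=sm.families.Binomial(),
                            var_weights=wts,
                        ).fit(maxiter=100)
                    if not np.all(np.isfinite(res.params)):
                        raise ValueError("non-finite GLM parameters")
                    self.prob_trend_[sex] = ("glm", res.params, knots)
                except Exception:
                    mean_p = float(np.average(grp["consumed"], weights=wts))
                    self.prob_trend_[sex] = ("const", mean_p, None)

        # amount part on positive days only; subjects may have 1 positive day
        self.amount_model_ = OnePartModel(
            lam=self.lam, n_knots=self.n_knots, gh_order=self.gh_order,
            weighted=self.weighted, min_days=1,
        ).fit(positive, [s for s in potential if s.subject_id in set(positive["subject_id"])])

        self.subjects_ = list(subjects)
        self.never_consumers_ = never
        total_w = sum(s.survey_weight for s in subjects)
        self.never_consumer_fraction_ = (
            sum(s.survey_weight for s in subjects if s.subject_id in never) / total_w
        )
        return self

    def _predict_prob(self, ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
        if "__const__" in self.prob_trend_:
            return np.full(len(ages), self.prob_trend_["__const__"])
        from scipy.special import expit

        p = np.empty(len(ages))
        for sex, spec in self.prob_trend_.items():
            mask = sexes == sex
            if not mask.any():
                continue
            kind, payload, knots = spec
            if kind == "const":
                p[mask] = payload
            else:
                p[mask] = expit(_design(ages[mask], knots) @ payload)
        missing_sex = ~np.isin(sexes, list(self.prob_trend_))
        if missing_sex.any():
            p[missing_sex] = np.mean([  # fall back to pooled mean probability
                s[1] if s[0] == "const" else 0.5 for s in self.prob_trend_.values()
            ])
        return np.clip(p, 0.0, 1.0)

    def habitual_values(self) -> IntakeDistribution:
        self._check_fitted()
        sub = subjects_frame(self.subjects_)
        ages = sub["age"].to_numpy(float)
        sexes = sub["sex"].to_numpy()
        ids = sub.index.to_numpy()

        amount = np.empty(len(ids))
        fitted_ids = pd.Index(self.amount_model_.subject_id_)
        pos = pd.Index(ids).get_indexer(fitted_ids)
        amount_fit = self.amount_model_.habitual_values().values
        amount[:] = np.nan
        amount[pos] = amount_fit
        # potential consumers without an observed positive day: population mean
        no_pos = np.isnan(amount)
        if no_pos.any():
            amount[no_pos] = self.amount_model_.predict_marginal(ages[no_pos], sexes[no_pos])

        p = self._predict_prob(ages, sexes)
        values = p * amount
        is_never = np.isin(ids, list(self.never_consumers_))
        values[is_never] = 0.0
        return IntakeDistribution(
            values=values,
            weights=sub["survey_weight"].to_numpy(),
            age=sub["age"].to_numpy(),
            sex=sexes,
            subject_id=ids,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "amount_model_"):
            raise ValidationError("model is not fitted")


def fit_two_part(daily, subjects: list[Subject], never_consumers=(), **params) -> TwoPartModel:
    """Functional wrapper: fit a :class:`TwoPartModel` and return it."""
    return TwoPartModel(**params).fit(daily, subjects, never_consumers=never_consumers)


# ---------------------------------------------------------------------------
# supplement model

class SupplementModel:
    """Habitual supplemental iodine intake.

    Users with a reported recall amount keep the mean of their reported
    daily amounts as the habitual amount.  Questionnaire-only users (use
    reported in the frequency questionnaire but no amount in either recall)
    receive a prediction from a recursive-partitioning regressor trained on
    users with known amounts (covariates: age and sex by default).
    Non-users contribute a structural zero.
    """

    def __init__(self, min_samples_leaf: int = 10, random_state: int = 0):
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, subjects: list[Subject]) -> "SupplementModel":
        known_X, known_y = [], []
        for s in subjects:
            if s.supplement_recall:
                known_X.append([s.age, 1.0 if s.sex == "male" else 0.0])
                known_y.append(float(np.mean(list(s.supplement_recall.values()))))
        q_only = [s for s in subjects if s.supplement_questionnaire_user and not s.supplement_recall]
        self.tree_ = None
        if q_only:
            if not known_y:
                raise ValidationError(
                    "questionnaire-only supplement users present but no user "
                    "with a known recall amount to train the predictor"
                )
            self.tree_ = DecisionTreeRegressor(
                min_samples_leaf=min(self.min_samples_leaf, len(known_y)),
                random_state=self.random_state,
            ).fit(np.asarray(known_X), np.asarray(known_y))
        self.subjects_ = list(subjects)
        return self

    def habitual_values(self) -> IntakeDistribution:
        if not hasattr(self, "subjects_"):
            raise ValidationError("model is not fitted")
        values, weights, ages, sexes, ids = [], [], [], [], []
        for s in self.subjects_:
            if s.supplement_recall:
                v = float(np.mean(list(s.supplement_recall.values())))
            elif s.supplement_questionnaire_user:
                v = float(
                    self.tree_.predict([[s.age, 1.0 if s.sex == "male" else 0.0]])[0]
                )
            else:
                v = 0.0
            values.append(v)
            weights.append(s.survey_weight)
            ages.append(s.age)
            sexes.append(s.sex)
            ids.append(s.subject_id)
        return IntakeDistribution(
            values=np.array(values), weights=np.array(weights),
            age=np.array(ages), sex=np.array(sexes), subject_id=np.array(ids),
        )


def supplement_habitual(subjects: list[Subject], **params) -> IntakeDistribution:
    """Fit the supplement model and return the habitual distribution."""
    return SupplementModel(**params).fit(subjects).habitual_values()
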