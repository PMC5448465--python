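"""Measurement-error model: transforms, shrinkage, two-part and supplements."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import iodintake as it
from iodintake import tabulation
from iodintake.datatypes import ValidationError
from iodintake.habitual import (
    IntakeDistribution,
    OnePartModel,
    SupplementModel,
    TwoPartModel,
    boxcox_inverse,
    boxcox_transform,
)


def make_daily(values_by_subject):
    rows = []
    for sid, (v1, v2) in values_by_subject.items():
        rows.append({"subject_id": sid, "day": 1, "intake": v1})
        rows.append({"subject_id": sid, "day": 2, "intake": v2})
    return pd.DataFrame(rows)


def equal_weight_subjects(ids, age=30):
    return [it.Subject(sid, age, "male", 1.0) for sid in ids]


# ---------------------------------------------------------------------------
# transforms and quantiles

@given(
    x=st.floats(min_value=0.01, max_value=1e4),
    lam=st.sampled_from([0.0, 0.25, 1.0 / 3.0, 0.5, 1.0]),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_boxcox_round_trip(x, lam):
    assert boxcox_inverse(boxcox_transform(np.array([x]), lam), lam)[0] == pytest.approx(
        x, rel=1e-9
    )


def test_weighted_percentile_point_mass_and_sequence():
    point = IntakeDistribution(values=np.full(5, 100.0), weights=np.ones(5))
    for p in (0.05, 0.5, 0.95):
        assert point.percentile(p) == 100.0
    seq = IntakeDistribution(values=np.arange(1.0, 100.0), weights=np.ones(99))
    assert seq.percentile(0.5) == 50.0


@given(
    values=st.lists(st.floats(min_value=0, max_value=1e3), min_size=1, max_size=30),
    weights=st.lists(st.floats(min_value=0.1, max_value=10), min_size=30, max_size=30),
    p=st.floats(min_value=0.01, max_value=0.99),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_weighted_percentile_matches_brute_force(values, weights, p):
    """Inverse weighted ECDF oracle: smallest value whose cumulative weight share >= p."""
    w = np.array(weights[: len(values)])
    v = np.array(values)
    dist = IntakeDistribution(values=v, weights=w)
    order = np.argsort(v, kind="stable")
    expected = v[order][-1]
    cum = 0.0
    for i in order:
        cum += w[i]
        if cum / w.sum() >= p:
            expected = v[i]
            break
    assert dist.percentile(p) == expected


def test_percentile_monotone_in_p():
    rng = np.random.default_rng(0)
    dist = IntakeDistribution(values=rng.gamma(2, 50, 200), weights=rng.uniform(0.5, 2, 200))
    ps = np.linspace(0.05, 0.95, 19)
    qs = np.atleast_1d(dist.percentile(ps))
    assert np.all(np.diff(qs) >= 0)


def test_empty_distribution_rejected():
    with pytest.raises(ValidationError):
        IntakeDistribution(values=np.array([]), weights=np.array([]))


# ---------------------------------------------------------------------------
# one-part model

def test_degenerate_constant_data():
    daily = make_daily({sid: (100.0, 100.0) for sid in "abcd"})
    fit = OnePartModel().fit(daily, equal_weight_subjects("abcd"))
    assert fit.sigma2_within_ == 0.0
    assert fit.sigma2_between_ == 0.0
    assert np.allclose(fit.habitual_values().values, 100.0)


def test_requires_two_days_per_subject():
    daily = make_daily({"a": (100.0, 110.0)}).iloc[:1]
    with pytest.raises(ValidationError, match="fewer than 2"):
        OnePartModel().fit(daily, equal_weight_subjects("a"))


def test_sigma_recovery_identity_transform(recovery_data):
    """Synthetic truth lam=1, f=150, sigma_b=20, sigma_w=30 at n=2000."""
    subjects, records, composition, _ = recovery_data
    nat = tabulation.natural_iodine(records, composition, subjects)
    fit = OnePartModel().fit(nat, subjects)
    assert fit.lam_ == 1.0
    assert 18.0 <= np.sqrt(fit.sigma2_between_) <= 22.0
    assert 28.5 <= np.sqrt(fit.sigma2_within_) <= 31.5


def test_lambda_recovery_log_scale():
    from iodintake.synthetic import GroundTruth, SourceParams

    gt = GroundTruth(
        natural=SourceParams(lam=0.0, intercept=np.log(100.0),
                             sigma_between=0.2, sigma_within=0.3)
    )
    subjects = it.generate_population(2000, seed=21)
    records, composition = it.generate_recalls(subjects, gt, seed=21)
    nat = tabulation.natural_iodine(records, composition, subjects)
    fit = OnePartModel().fit(nat, subjects)
    assert abs(fit.lam_ - 0.0) <= 0.15


def test_lognormal_closed_form_oracle():
    """lam=0: habitual equals exp(f + b) * exp(sigma_w^2 / 2) to 1e-6."""
    rng = np.random.default_rng(3)
    n = 400
    b = rng.normal(0, 0.25, n)
    e = rng.normal(0, 0.35, (n, 2))
    ids = [f"s{i}" for i in range(n)]
    daily = make_daily(
        {sid: tuple(np.exp(4.6 + b[i] + e[i])) for i, sid in enumerate(ids)}
    )
    fit = OnePartModel(lam=0.0).fit(daily, equal_weight_subjects(ids))
    got = fit.habitual_values().values
    expected = np.exp(fit.location_) * np.exp(fit.sigma2_within_ / 2.0)
    assert np.allclose(got, expected, rtol=1e-6)


def test_zero_within_variance_returns_two_day_mean():
    rng = np.random.default_rng(4)
    means = rng.uniform(80, 200, 50)
    ids = [f"s{i}" for i in range(50)]
    daily = make_daily({sid: (means[i], means[i]) for i, sid in enumerate(ids)})
    fit = OnePartModel(lam=1.0).fit(daily, equal_weight_subjects(ids))
    assert fit.sigma2_within_ == 0.0
    dist = fit.habitual_values()
    by_id = dict(zip(dist.subject_id, dist.values))
    assert np.allclose([by_id[sid] for sid in ids], means)


def test_mean_preservation_identity_transform(recovery_data):
    """lam=1: weighted mean of habitual values equals weighted mean of daily intakes."""
    subjects, records, composition, _ = recovery_data
    nat = tabulation.natural_iodine(records, composition, subjects)
    fit = OnePartModel(lam=1.0).fit(nat, subjects)
    dist = fit.habitual_values()
    sub = pd.DataFrame({"subject_id": [s.subject_id for s in subjects],
                        "w": [s.survey_weight for s in subjects]})
    daily = nat.merge(sub, on="subject_id")
    daily_mean = np.average(
        daily.groupby("subject_id")["intake"].mean(),
        weights=sub.set_index("subject_id").loc[
            daily.groupby("subject_id")["intake"].mean().index, "w"
        ],
    )
    assert dist.mean() == pytest.approx(daily_mean, abs=1e-9)


def test_shrinkage_reduces_variance(recovery_data):
    subjects, records, composition, _ = recovery_data
    nat = tabulation.natural_iodine(records, composition, subjects)
    fit = OnePartModel().fit(nat, subjects)
    assert fit.sigma2_within_ > 0
    habitual_var = np.var(fit.habitual_values().values)
    mean_var = np.var(nat.groupby("subject_id")["intake"].mean().to_numpy())
    assert habitual_var < mean_var


def test_variance_components_match_mixedlm_reml():
    """Independent route: statsmodels MixedLM REML on a balanced design."""
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    n = 300
    b = rng.normal(0, 15.0, n)
    e = rng.normal(0, 25.0, (n, 2))
    y = 150.0 + b[:, None] + e
    ids = [f"s{i}" for i in range(n)]
    daily = make_daily({sid: tuple(y[i]) for i, sid in enumerate(ids)})
    fit = OnePartModel(lam=1.0, weighted=False).fit(daily, equal_weight_subjects(ids))

    groups = np.repeat(np.arange(n), 2)
    endog = y.ravel()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mlm = sm.MixedLM(endog, np.ones((2 * n, 1)), groups=groups).fit(reml=True)
    assert fit.sigma2_within_ == pytest.approx(mlm.scale, rel=0.05)
    assert fit.sigma2_between_ == pytest.approx(
        float(np.asarray(mlm.cov_re)[0, 0]), rel=0.05
    )


def test_negative_lambda_tail_raises_instructive_error():
    daily = make_daily({"a": (100.0, 120.0), "b": (50.0, 700.0), "c": (60.0, 65.0)})
    model = OnePartModel(lam=-1.0, gh_order=15)
    model.fit(daily, equal_weight_subjects("abc"))
    model.sigma2_within_ = 50.0  # force quadrature into the invalid tail
    with pytest.raises(ValidationError, match="lambda floor"):
        model.habitual_values()


# ---------------------------------------------------------------------------
# two-part model

def test_two_part_never_consumer_zero_and_full_consumer():
    daily = make_daily({"a": (100.0, 100.0), "b": (100.0, 100.0), "n": (0.0, 0.0)})
    subs = equal_weight_subjects(["a", "b", "n"])
    fit = TwoPartModel().fit(daily, subs, never_consumers=["n"])
    dist = fit.habitual_values()
    values = dict(zip(dist.subject_id, dist.values))
    assert values["n"] == 0.0
    assert values["a"] == pytest.approx(100.0)
    assert fit.never_consumer_fraction_ == pytest.approx(1 / 3)


def test_two_part_requires_positive_days():
    daily = make_daily({"a": (0.0, 0.0)})
    with pytest.raises(ValidationError, match="positive"):
        TwoPartModel().fit(daily, equal_weight_subjects("a"))


def test_two_part_probability_recovery():
    """p = 0.6 uniform consumption probability recovered within [0.57, 0.63]."""
    rng = np.random.default_rng(12)
    n = 2000
    ids = [f"s{i}" for i in range(n)]
    consumed = rng.random((n, 2)) < 0.6
    amounts = rng.lognormal(4.0, 0.3, (n, 2)) * consumed
    daily = make_daily({sid: tuple(amounts[i]) for i, sid in enumerate(ids)})
    subs = equal_weight_subjects(ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = TwoPartModel().fit(daily, subs)
    dist = fit.habitual_values()
    sub_frame = pd.DataFrame({"age": [30.0] * n, "sex": ["male"] * n})
    p_hat = fit._predict_prob(sub_frame["age"].to_numpy(), sub_frame["sex"].to_numpy())
    assert 0.57 <= float(np.mean(p_hat)) <= 0.63
    assert len(dist) == n


def test_two_part_converges_to_one_part():
    """No never-consumers and p = 1: identical percentiles to the one-part model."""
    rng = np.random.default_rng(13)
    n = 500
    b = rng.normal(0, 0.2, n)
    e = rng.normal(0, 0.3, (n, 2))
    ids = [f"s{i}" for i in range(n)]
    daily = make_daily({sid: tuple(np.exp(4.5 + b[i] + e[i])) for i, sid in enumerate(ids)})
    subs = equal_weight_subjects(ids)
    one = OnePartModel().fit(daily, subs).habitual_values()
    two = TwoPartModel().fit(daily, subs).habitual_values()
    ps = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
    assert np.allclose(one.percentile(ps), two.percentile(ps), rtol=1e-2)


# ---------------------------------------------------------------------------
# supplements

def test_supplement_recall_amount_is_habitual():
    subs = [
        it.Subject("u", 30, "male", 1.0, supplement_recall={1: 150.0}),
        it.Subject("v", 40, "female", 1.0),
    ]
    dist = it.supplement_habitual(subs)
    values = dict(zip(dist.subject_id, dist.values))
    assert values["u"] == 150.0
    assert values["v"] == 0.0


def test_supplement_two_day_mean():
    subs = [it.Subject("u", 30, "male", 1.0, supplement_recall={1: 100.0, 2: 200.0})]
    assert it.supplement_habitual(subs).values[0] == pytest.approx(150.0)


def test_supplement_questionnaire_only_constant_leaf():
    subs = [
        it.Subject(f"k{i}", 20 + i, "male", 1.0, supplement_recall={1: 100.0})
        for i in range(5)
    ]
    subs.append(
        it.Subject("q", 35, "female", 1.0, supplement_questionnaire_user=True)
    )
    dist = it.supplement_habitual(subs)
    values = dict(zip(dist.subject_id, dist.values))
    assert values["q"] == pytest.approx(100.0)


def test_supplement_questionnaire_only_without_known_users_errors():
    subs = [it.Subject("q", 35, "female", 1.0, supplement_questionnaire_user=True)]
    with pytest.raises(ValidationError, match="questionnaire-only"):
        SupplementModel().fit(subs)
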