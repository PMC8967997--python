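"""Event rates, Kaplan-Meier estimation, log-rank and group comparisons."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from coherent.stats import (
    EventType,
    FollowUp,
    compare_groups,
    event_rate,
    km_estimate,
    log_rank,
)

D0 = date(2018, 6, 1)


def fu(pid, death=None, hosp=(), ed=()):
    return FollowUp(
        patient_id=pid,
        discharge_date=D0,
        death_date=D0 + timedelta(days=death) if death is not None else None,
        hospitalization_starts=tuple(D0 + timedelta(days=d) for d in hosp),
        ed_starts=tuple(D0 + timedelta(days=d) for d in ed),
    )


def test_event_rate_counts_patients_not_events():
    fus = [fu("a", hosp=(5, 12)), fu("b", hosp=(29,)), fu("c"), fu("d", ed=(3,))]
    r = event_rate(fus, EventType.READMISSION, 30)
    assert (r.numerator, r.denominator) == (2, 4)
    assert r.rate == 0.5
    assert event_rate(fus, EventType.READMISSION, 365).rate == 0.5
    assert event_rate([fu("a"), fu("b")], EventType.RE_ED_VISIT, 30).rate == 0.0


def test_event_window_is_half_open_after_discharge():
    # an event on the discharge day itself is not post-discharge; day 30 is in
    fus = [fu("a", hosp=(0,)), fu("b", hosp=(30,)), fu("c", hosp=(31,))]
    assert event_rate(fus, EventType.READMISSION, 30).numerator == 1


def test_mortality_includes_in_hospital_deaths():
    # death on the discharge date (in-hospital death) counts at every cutoff
    fus = [fu("a", death=0), fu("b", death=200), fu("c")]
    assert event_rate(fus, EventType.DEATH, 30).rate == pytest.approx(1 / 3)
    assert event_rate(fus, EventType.DEATH, 365).rate == pytest.approx(2 / 3)


def test_rates_monotone_in_cutoff(small_cohort, small_strata):
    from coherent.stats import build_followups

    fus = build_followups(
        small_strata.select(arm="HOSPITALIZED"), small_cohort.episodes, small_cohort.vitals
    )
    for ev in (EventType.DEATH, EventType.READMISSION, EventType.RE_ED_VISIT):
        assert event_rate(fus, ev, 30).rate <= event_rate(fus, ev, 365).rate


def _km_oracle(durations, observed):
    """Hand-rolled product-limit estimator over the distinct event times."""
    durations = np.asarray(durations, float)
    observed = np.asarray(observed, bool)
    times = np.unique(durations[observed])
    s, out = 1.0, {}
    for t in times:
        at_risk = np.sum(durations >= t)
        deaths = np.sum((durations == t) & observed)
        s *= 1 - deaths / at_risk
        out[t] = s
    return out


def test_km_trivial_cases():
    curve = km_estimate([10, 20, 30], [False, False, False])
    assert np.all(curve.survival == 1.0)
    curve = km_estimate([2, 5, 5, 5, 5], [True, False, False, False, False])
    assert curve.at(2) == pytest.approx(0.8)
    assert curve.at(1.9) == pytest.approx(1.0)


def test_km_matches_product_limit_oracle():
    rng = np.random.default_rng(42)
    durations = rng.integers(0, 40, size=60).astype(float)
    observed = rng.random(60) < 0.6
    if not observed.any():  # pragma: no cover - seed gives events
        observed[0] = True
    curve = km_estimate(durations, observed)
    for t, s in _km_oracle(durations, observed).items():
        assert curve.at(t) == pytest.approx(s, abs=1e-12)


def test_km_without_censoring_is_empirical_survival():
    durations = np.array([1, 3, 3, 7, 9], float)
    curve = km_estimate(durations, [True] * 5)
    for t in range(10):
        assert curve.at(t) == pytest.approx(np.mean(durations > t))


def test_log_rank_identical_groups_is_null():
    dur = [3, 8, 15, 30]
    obs = [True, True, False, True]
    res = log_rank(dur, obs, dur, obs)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def _logrank_oracle(dur_a, obs_a, dur_b, obs_b):
    """Observed-minus-expected chi-square over the pooled risk sets."""
    dur_a, dur_b = np.asarray(dur_a, float), np.asarray(dur_b, float)
    obs_a, obs_b = np.asarray(obs_a, bool), np.asarray(obs_b, bool)
    all_dur = np.concatenate([dur_a, dur_b])
    all_obs = np.concatenate([obs_a, obs_b])
    group = np.concatenate([np.zeros(len(dur_a)), np.ones(len(dur_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(all_dur[all_obs]):
        at_risk = all_dur >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((all_dur == t) & all_obs).sum()
        d_a = ((all_dur == t) & all_obs & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_log_rank_matches_observed_minus_expected_oracle():
    dur_a, obs_a = [2, 5, 9], [True, True, False]
    dur_b, obs_b = [1, 4, 9], [True, True, True]
    res = log_rank(dur_a, obs_a, dur_b, obs_b)
    assert res.statistic == pytest.approx(_logrank_oracle(dur_a, obs_a, dur_b, obs_b))


def test_log_rank_requires_events():
    with pytest.raises(ValueError):
        log_rank([5, 5], [False, False], [4, 4], [False, False])


def test_log_rank_consistent_with_permutation_null():
    rng = np.random.default_rng(7)
    dur_a = rng.exponential(50, 25).round()
    dur_b = rng.exponential(25, 25).round()
    obs = np.ones(25, bool)
    analytic = log_rank(dur_a, obs, dur_b, obs).p_value
    pooled = np.concatenate([dur_a, dur_b])
    stat0 = log_rank(dur_a, obs, dur_b, obs).statistic
    hits = 0
    n_perm = 200
    for _ in range(n_perm):
        perm = rng.permutation(50)
        pa, pb = pooled[perm[:25]], pooled[perm[25:]]
        if log_rank(pa, obs, pb, obs).statistic >= stat0:
            hits += 1
    p_perm = hits / n_perm
    mc_err = 3 * np.sqrt(max(analytic, p_perm, 0.01) / n_perm)
    assert abs(p_perm - analytic) < mc_err + 0.02


def test_chi_square_without_continuity_correction():
    res = compare_groups([[10, 90], [20, 80]], scale="categorical")
    assert res.test_name == "chi_square"
    assert res.statistic == pytest.approx(3.92, abs=0.005)


def test_identical_categorical_distributions_give_null():
    res = compare_groups([[30, 70], [60, 140]], scale="categorical")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_t_statistic_zero_for_identical_means():
    a = [1.0, 2.0, 3.0, 4.0]
    b = [2.0, 3.0, 1.0, 4.0]
    res = compare_groups(a, b, scale="continuous_normal")
    assert res.test_name == "t"
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_mann_whitney_dispatch():
    rng = np.random.default_rng(1)
    res = compare_groups(rng.lognormal(0, 1, 30), rng.lognormal(0.5, 1, 30),
                         scale="continuous_skewed")
    assert res.test_name == "mann_whitney"
    assert 0 <= res.p_value <= 1


def test_log_rank_pvalues_uniform_under_null():
    """With both groups simulated from one survival law, the test rejects at
    ~5%: over 200 cohort pairs the rejection fraction stays in [0.01, 0.10]."""
    rng = np.random.default_rng(2018)
    rejections = 0
    n_pairs = 200
    for _ in range(n_pairs):
        dur_a = np.minimum(rng.exponential(300, 100), 365)
        dur_b = np.minimum(rng.exponential(300, 100), 365)
        obs_a, obs_b = dur_a < 365, dur_b < 365
        if obs_a.sum() + obs_b.sum() == 0:
            continue
        p = log_rank(dur_a, obs_a, dur_b, obs_b).p_value
        rejections += p < 0.05
    assert 0.01 <= rejections / n_pairs <= 0.10
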