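"""Statistical wrappers against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ksdcohort.stats import (
    SurvivalRecord,
    chi_square_2x2,
    cox_ph,
    km_estimate,
    kruskal_wallis,
    logrank,
    mann_whitney,
    multiple_recurrence_summary,
    shapiro_gate,
)


def rec(iid, t, event, strong, age=50.0, sex="M", n_rec=None):
    return SurvivalRecord(
        individual_id=iid,
        time_days=t,
        event=event,
        age=age,
        sex=sex,
        strong_risk_factor=strong,
        n_recurrences=(int(event) if n_rec is None else n_rec),
    )


class TestChiSquare:
    def test_equal_proportions_statistic_zero(self):
        r = chi_square_2x2(10, 90, 10, 90)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_identical_rows(self):
        assert chi_square_2x2(5, 5, 5, 5).statistic == pytest.approx(0.0)

    def test_zero_margin_fails(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 10, 0, 20)

    def test_no_continuity_correction_applied(self):
        # hand Pearson statistic sum((O-E)^2/E) on a small table
        a, b, c, d = 12, 8, 5, 15
        n = a + b + c + d
        expected_stat = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        assert chi_square_2x2(a, b, c, d).statistic == pytest.approx(
            expected_stat, rel=1e-12
        )


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert mann_whitney(x, x).p_value > 0.9

    def test_complete_separation_exact_enumeration(self):
        # 3 vs 3, no overlap: only 1 of C(6,3)=20 orderings as extreme
        # each tail -> two-sided exact p = 2/20 = 0.1
        r = mann_whitney([1, 2, 3], [10, 11, 12])
        assert r.method == "mann_whitney_exact"
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert min(r.statistic, 9 - r.statistic) == 0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(0.5, size=35)
        r1 = mann_whitney(x, y)
        r2 = mann_whitney(np.exp(x), np.exp(y))
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_empty_sample_fails(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_constant_groups_h_zero_p_one(self):
        r = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_two_groups_tracks_mann_whitney(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=60)
        y = rng.normal(0.6, size=55)
        p_kw = kruskal_wallis([x, y]).p_value
        p_mw = mann_whitney(x, y).p_value
        # same rank information, asymptotically equivalent tests
        assert np.log(p_kw) == pytest.approx(np.log(p_mw), rel=0.1)

    def test_planted_shift_detected_more_often_than_null(self):
        rng = np.random.default_rng(5)
        n_reject_alt = n_reject_null = 0
        for _ in range(60):
            groups = [rng.normal(size=50) for _ in range(4)]
            if kruskal_wallis(groups).p_value < 0.05:
                n_reject_null += 1
            groups[0] = groups[0] + 0.8
            if kruskal_wallis(groups).p_value < 0.05:
                n_reject_alt += 1
        assert n_reject_alt > n_reject_null
        assert n_reject_alt >= 50  # ~1.0 power at this shift


class TestShapiroGate:
    def test_uniform_sample_reported_nonparametrically(self):
        rng = np.random.default_rng(0)
        out = shapiro_gate(rng.uniform(size=500))
        assert out["summary_type"] == "nonparametric"
        assert "median" in out and "iqr" in out

    def test_gaussian_sample_reported_parametrically(self):
        rng = np.random.default_rng(1)
        out = shapiro_gate(rng.normal(size=200))
        assert out["summary_type"] == "parametric"
        assert "mean" in out and "sd" in out

    def test_minimal_n_and_degenerate_sample(self):
        assert shapiro_gate([1.0, 1.0 + 1e-9, 1.0 + 2e-9])
        assert shapiro_gate([2.0, 2.0, 2.0])["summary_type"] == (
            "nonparametric"
        )


def km_oracle(times, events):
    """Brute-force product-limit estimator over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_events_survival_constant_one(self):
        records = [rec(f"I{i}", 100.0 + i, False, False) for i in range(5)]
        curves = km_estimate(records)
        assert np.allclose(curves[0]["survival"], 1.0)

    def test_single_event_among_two(self):
        records = [rec("A", 10.0, True, False), rec("B", 50.0, False, False)]
        curve = curves = km_estimate(records)[0]
        s_after = curve[curve["time"] >= 10.0]["survival"].iloc[0]
        assert s_after == pytest.approx(0.5)

    def test_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(21)
        times = rng.exponential(100, size=10).round(1)
        events = rng.random(10) < 0.7
        records = [
            rec(f"I{i}", t, bool(e), False)
            for i, (t, e) in enumerate(zip(times, events))
        ]
        curve = km_estimate(records)[0].set_index("time")
        for t, s in km_oracle(times, events).items():
            assert curve.loc[t, "survival"] == pytest.approx(s, abs=1e-12)

    def test_at_risk_conservation(self):
        rng = np.random.default_rng(9)
        records = [
            rec(f"I{i}", float(t), bool(e), False)
            for i, (t, e) in enumerate(
                zip(rng.integers(1, 50, 30), rng.random(30) < 0.5)
            )
        ]
        curve = km_estimate(records)[0]
        # at each time, those at risk either have the event, are censored,
        # or carry forward to the next row
        carried = curve["at_risk"] - curve["events"] - curve["censored"]
        assert (carried.values[:-1] >= curve["at_risk"].values[1:]).all()
        assert (carried >= 0).all()


class TestLogrank:
    def test_mirrored_groups_statistic_zero(self):
        base = [(10.0, True), (20.0, False), (30.0, True), (40.0, False)]
        records = [
            rec(f"A{i}", t, e, False) for i, (t, e) in enumerate(base)
        ] + [rec(f"B{i}", t, e, True) for i, (t, e) in enumerate(base)]
        assert logrank(records).statistic == pytest.approx(0.0, abs=1e-10)

    def test_needs_two_groups_and_an_event(self):
        with pytest.raises(ValueError):
            logrank([rec("A", 10.0, True, False)])
        with pytest.raises(ValueError):
            logrank(
                [rec("A", 10.0, False, False), rec("B", 5.0, False, True)]
            )

    def test_equals_cox_score_test_at_beta_zero(self):
        # hand-coded score statistic U^2/V of the Cox partial likelihood
        # at beta=0 (binary group, no ties) equals the log-rank chi-square
        rng = np.random.default_rng(17)
        n = 40
        group = rng.random(n) < 0.5
        raw = np.round(
            np.where(group, rng.exponential(50, n), rng.exponential(100, n)),
            3,
        )
        _, first = np.unique(raw, return_index=True)  # ensure no ties
        keep = np.sort(first)
        times = raw[keep]
        group = group[keep]
        n = len(times)
        events = rng.random(n) < 0.8
        u = 0.0
        v = 0.0
        order = np.argsort(times)
        for idx in order:
            if not events[idx]:
                continue
            at_risk = times >= times[idx]
            n1 = np.sum(group & at_risk)
            ntot = np.sum(at_risk)
            u += group[idx] - n1 / ntot
            v += (n1 / ntot) * (1 - n1 / ntot)
        records = [
            rec(f"I{i}", float(times[i]), bool(events[i]), bool(group[i]))
            for i in range(n)
        ]
        assert logrank(records).statistic == pytest.approx(
            u * u / v, rel=1e-9
        )


def partial_likelihood_oracle(times, events, x):
    """Negative log partial likelihood (no ties), minimized by brute force."""

    def nll(beta):
        order = np.argsort(times)
        ll = 0.0
        for idx in order:
            if not events[idx]:
                continue
            at_risk = times >= times[idx]
            ll += beta * x[idx] - np.log(np.sum(np.exp(beta * x[at_risk])))
        return -ll

    res = minimize_scalar(nll, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestCox:
    def test_six_record_oracle(self):
        times = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        events = np.array([1, 1, 0, 1, 1, 1], bool)
        x = np.array([1, 0, 1, 0, 1, 0], float)
        records = [
            rec(f"I{i}", times[i], bool(events[i]), bool(x[i]))
            for i in range(6)
        ]
        fit = cox_ph(records, covariates=["strong_risk_factor"])
        beta_oracle = partial_likelihood_oracle(times, events, x)
        assert fit.loc["strong_risk_factor", "coef"] == pytest.approx(
            beta_oracle, abs=1e-4
        )

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(23)
        n = 400
        times = rng.exponential(300, n)
        cens = np.minimum(times, 1095)
        records = [
            rec(
                f"I{i}",
                float(cens[i]),
                bool(times[i] <= 1095),
                bool(rng.random() < 0.5),  # label independent of hazard
                age=float(rng.uniform(20, 80)),
                sex="M" if rng.random() < 0.5 else "F",
            )
            for i in range(n)
        ]
        fit = cox_ph(records)
        assert abs(fit.loc["strong_risk_factor", "coef"]) < 0.4
        assert fit.loc["strong_risk_factor", "p"] > 0.001

    def test_needs_two_events(self):
        records = [rec("A", 10.0, True, False), rec("B", 20.0, False, True)]
        with pytest.raises(ValueError):
            cox_ph(records)


def test_benjamini_hochberg_monotone_and_bounded():
    from ksdcohort.stats import benjamini_hochberg

    p = [0.001, 0.01, 0.03, 0.5, 0.9]
    q = benjamini_hochberg(p)
    assert (np.diff(q) >= 0).all()
    assert (q >= p).all() and (q <= 1).all()


class TestMultipleRecurrence:
    def test_printed_percentages(self):
        records = [
            rec(f"S{i}", 100.0, True, True, n_rec=2 if i < 5 else 1)
            for i in range(48)
        ] + [
            rec(f"O{i}", 100.0, True, False, n_rec=2 if i < 7 else 0)
            for i in range(302)
        ]
        table = multiple_recurrence_summary(records).set_index("group")
        assert table.loc["strong_risk", "percent"] == 10.4
        assert table.loc["no_strong_risk", "percent"] == 2.3
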