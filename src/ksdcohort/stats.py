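"""Cohort comparison and recurrence survival statistics.

Thin, convention-fixing wrappers: Pearson chi-square without continuity
correction (the study's categorical test), two-sided Mann-Whitney U
(exact for small untied samples), tie-corrected Kruskal-Wallis, a
Shapiro-Wilk gate choosing median (IQR) versus mean ± SD reporting, and
the recurrence suite — Kaplan-Meier product-limit curves, the log-rank
test, and Cox proportional hazards with Efron tie handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diagnosis import round_pct


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    group_sizes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Time from enrollment to first stone recurrence or censoring."""

    individual_id: str
    time_days: float
    event: bool
    age: float
    sex: str  # "M" | "F"
    strong_risk_factor: bool
    n_recurrences: int = 0

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("time_days must be >= 0")
        if self.event and self.time_days <= 0:
            raise ValueError("events require time > 0")
        if self.n_recurrences < 0:
            raise ValueError("n_recurrences must be >= 0")


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "time_days": [r.time_days for r in records],
            "event": [int(r.event) for r in records],
            "age": [r.age for r in records],
            "sex_male": [int(r.sex == "M") for r in records],
            "strong_risk_factor": [int(r.strong_risk_factor) for r in records],
            "n_recurrences": [r.n_recurrences for r in records],
        }
    )


# ---------------------------------------------------------------------------
# group comparison tests
# ---------------------------------------------------------------------------


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on [[a, b], [c, d]], df=1, no continuity
    correction (matches the study's reported categorical comparisons)."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), "chi_square_pearson", df=float(df),
                      group_sizes=(a + b, c + d))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 8
) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null enumeration when both samples are small and untied,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = (
        "exact"
        if (max(x.size, y.size) <= exact_threshold and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        f"mann_whitney_{method}",
        group_sizes=(x.size, y.size),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k − 1).

    All-identical pooled data (tie correction degenerate) returns H = 0,
    p = 1 rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            0.0, 1.0, "kruskal_wallis", df=float(len(arrays) - 1),
            group_sizes=tuple(a.size for a in arrays),
        )
    stat, p = sps.kruskal(*arrays)
    return TestResult(
        float(stat), float(p), "kruskal_wallis",
        df=float(len(arrays) - 1),
        group_sizes=tuple(a.size for a in arrays),
    )


def shapiro_gate(sample: Sequence[float], alpha: float = 0.05) -> dict:
    """Normality-gated summary, matching the reporting convention:
    median (IQR) when Shapiro-Wilk rejects normality, else mean ± SD."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        # degenerate constant sample: W undefined; report nonparametric
        p = 0.0
    else:
        p = float(sps.shapiro(x).pvalue)
    if p < alpha:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {
            "summary_type": "nonparametric",
            "shapiro_p": p,
            "median": float(med),
            "iqr": (float(q1), float(q3)),
        }
    return {
        "summary_type": "parametric",
        "shapiro_p": p,
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
    }


# ---------------------------------------------------------------------------
# survival suite
# ---------------------------------------------------------------------------


def km_estimate(
    records: Sequence[SurvivalRecord], group_by: str = "strong_risk_factor"
) -> dict[int, pd.DataFrame]:
    """Product-limit survival curves per group with at-risk tables."""
    from lifelines import KaplanMeierFitter

    df = survival_frame(records)
    out: dict[int, pd.DataFrame] = {}
    for value, sub in df.groupby(group_by):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub["event"])
        ev = kmf.event_table
        curve = pd.DataFrame(
            {
                "time": ev.index.values,
                "survival": kmf.survival_function_["KM_estimate"].values,
                "at_risk": ev["at_risk"].values,
                "events": ev["observed"].values,
                "censored": ev["censored"].values,
            }
        )
        out[int(value)] = curve
    return out


def logrank(
    records: Sequence[SurvivalRecord], group_by: str = "strong_risk_factor"
) -> TestResult:
    """Two-group log-rank test (chi-square, df = 1)."""
    from lifelines.statistics import logrank_test

    df = survival_frame(records)
    values = sorted(df[group_by].unique())
    if len(values) != 2:
        raise ValueError("log-rank needs exactly 2 groups")
    if df["event"].sum() == 0:
        raise ValueError("log-rank needs >= 1 event")
    g0 = df[df[group_by] == values[0]]
    g1 = df[df[group_by] == values[1]]
    res = logrank_test(
        g0["time_days"], g1["time_days"], g0["event"], g1["event"]
    )
    return TestResult(
        float(res.test_statistic),
        float(res.p_value),
        "logrank",
        df=1.0,
        group_sizes=(len(g0), len(g1)),
    )


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str] = ("strong_risk_factor", "age", "sex_male"),
) -> pd.DataFrame:
    """Cox proportional hazards (Efron ties), Wald CI and p per covariate.

    Returns a frame indexed by covariate with columns coef, HR, ci_low,
    ci_high, p.  Non-convergence or separation raises with a diagnostic.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = survival_frame(records)
    if df["event"].sum() < 2:
        raise ValueError("Cox regression needs >= 2 events")
    cph = CoxPHFitter()
    try:
        cph.fit(
            df[["time_days", "event", *covariates]],
            duration_col="time_days",
            event_col="event",
        )
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox partial likelihood did not converge: {exc}")
    summary = cph.summary
    return pd.DataFrame(
        {
            "coef": summary["coef"],
            "HR": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional FDR adjustment (off by default everywhere: the primary
    analyses report unadjusted p-values for small genotype subgroups)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def multiple_recurrence_summary(
    records: Sequence[SurvivalRecord],
) -> pd.DataFrame:
    """Share of individuals with more than one recurrence, by risk group
    (printed-percentage rounding)."""
    df = survival_frame(records)
    rows = []
    for label, flag in (("strong_risk", 1), ("no_strong_risk", 0)):
        sub = df[df["strong_risk_factor"] == flag]
        n_multi = int((sub["n_recurrences"] > 1).sum())
        rows.append(
            {
                "group": label,
                "n": len(sub),
                "n_multiple_recurrence": n_multi,
                "percent": round_pct(n_multi, len(sub)) if len(sub) else
                float("nan"),
            }
        )
    return pd.DataFrame(rows)
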