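"""Test-retest reliability via the intraclass correlation coefficient.

Each measured parameter is recorded for n subjects in k = 2 sessions; the
agreement between sessions is quantified by the one-way random-effects,
single-measures ICC,

    ICC(1,1) = (MSB - MSW) / (MSB + (k - 1) MSW),

where MSB and MSW are the between- and within-subject mean squares of the
one-way ANOVA. Confidence bounds follow the F-distribution interval: with
F = (1 + (k-1) ICC) / (1 - ICC),

    lower from F_L = F / F_{1-a/2}(n-1, n(k-1)),
    upper from F_U = F * F_{1-a/2}(n(k-1), n-1),

each mapped back through ICC = (F* - 1) / (F* + k - 1). This interval
arithmetic reproduces the printed 95% bounds of the published static
test-retest table from its printed ICCs at n = 19, k = 2, which is why the
one-way single-measures form is the default (two-way forms of the
statistic exist but do not reproduce that table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityRecord",
    "icc_oneway",
    "icc_confint",
    "reliability_table",
    "simulate_two_session_cohort",
]


@dataclass(frozen=True)
class ReliabilityRecord:
    """One parameter's two-session values and its ICC with 95% bounds."""

    parameter: str
    session1: np.ndarray
    session2: np.ndarray
    icc: float
    ci_lower: float
    ci_upper: float

    @property
    def n_subjects(self) -> int:
        return len(self.session1)


def _mean_squares(table: np.ndarray) -> tuple[float, float]:
    n, k = table.shape
    subject_means = table.mean(axis=1)
    grand = table.mean()
    msb = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    msw = np.sum((table - subject_means[:, None]) ** 2) / (n * (k - 1))
    return float(msb), float(msw)


def icc_oneway(table) -> float:
    """One-way random-effects single-measures ICC of an n x k value table.

    Requires n >= 2 subjects, k >= 2 sessions and no missing cells (no
    imputation is ever performed). Returns NaN when the table has zero
    total variance, where the ratio is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be n x k with n >= 2 subjects, k >= 2 sessions")
    if not np.all(np.isfinite(t)):
        raise ValueError("missing or non-finite cells; reliability is computed on complete pairs")
    msb, msw = _mean_squares(t)
    k = t.shape[1]
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return (msb - msw) / denom


def icc_confint(icc: float, n: int, k: int = 2, alpha: float = 0.05) -> tuple[float, float]:
    """F-based confidence interval for a one-way single-measures ICC.

    Accepts the point estimate (so printed ICCs can be re-intervalled
    without raw data). An ICC of exactly 1 is degenerate: the lower bound
    is still computable in the limit and the upper bound is 1.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if not icc <= 1:
        raise ValueError("ICC cannot exceed 1")
    df1, df2 = n - 1, n * (k - 1)
    fu_quant = stats.f.ppf(1 - alpha / 2, df1, df2)
    fl_quant = stats.f.ppf(1 - alpha / 2, df2, df1)
    if icc == 1.0:
        # F -> infinity: both mapped bounds collapse onto 1 in the limit
        return 1.0, 1.0
    F = (1 + (k - 1) * icc) / (1 - icc)
    FL = F / fu_quant
    FU = F * fl_quant
    lower = (FL - 1) / (FL + k - 1)
    upper = (FU - 1) / (FU + k - 1)
    return float(lower), float(upper)


def _parameter_class(name: str) -> str:
    if name.startswith("∠"):
        return "angle"
    if "(direction)" in name:
        return "direction"
    if "(distance)" in name:
        return "distance"
    return "other"


def reliability_table(
    session1: pd.DataFrame,
    session2: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[ReliabilityRecord], pd.DataFrame]:
    """ICC + 95% CI per parameter across two analysis sessions.

    Both inputs are tidy frames with columns (subject, parameter, value)
    covering identical subject and parameter sets. Returns the per-parameter
    records plus class averages (distance / angle / direction mean ICCs).
    """
    for col in ("subject", "parameter", "value"):
        if col not in session1.columns or col not in session2.columns:
            raise ValueError(f"both sessions need a {col!r} column")
    p1, p2 = set(session1["parameter"]), set(session2["parameter"])
    if p1 != p2:
        raise ValueError(f"parameter sets differ between sessions: {sorted(p1 ^ p2)}")
    records = []
    params = [p for p in session1["parameter"].drop_duplicates()]
    for param in params:
        s1 = session1[session1["parameter"] == param].set_index("subject")["value"]
        s2 = session2[session2["parameter"] == param].set_index("subject")["value"]
        subjects = s1.index.intersection(s2.index)
        if len(subjects) < len(s1.index.union(s2.index)):
            # pairwise exclusion of subjects missing in either session
            pass
        v1 = s1.loc[subjects].to_numpy(dtype=float)
        v2 = s2.loc[subjects].to_numpy(dtype=float)
        icc = icc_oneway(np.column_stack([v1, v2]))
        if np.isnan(icc):
            lo = hi = float("nan")
        else:
            lo, hi = icc_confint(icc, n=len(subjects), k=2, alpha=alpha)
        records.append(ReliabilityRecord(param, v1, v2, float(icc), lo, hi))
    per_class = (
        pd.DataFrame(
            {"class": [_parameter_class(r.parameter) for r in records],
             "icc": [r.icc for r in records]}
        )
        .groupby("class", sort=True)["icc"]
        .mean()
        .rename("mean_icc")
        .reset_index()
    )
    return records, per_class


def simulate_two_session_cohort(
    n_subjects: int = 19,
    between_sd: float = 5.0,
    within_sd: float = 0.5,
    mean: float = 50.0,
    seed: int = 0,
) -> np.ndarray:
    """Variance-components cohort for one parameter: n x 2 value table.

    Each subject has a true value ~ N(mean, between_sd^2); each of the two
    sessions observes it with independent N(0, within_sd^2) error. The
    population ICC is between_sd^2 / (between_sd^2 + within_sd^2).
    """
    rng = np.random.default_rng(seed)
    truth = rng.normal(mean, between_sd, size=n_subjects)
    return truth[:, None] + rng.normal(0.0, within_sd, size=(n_subjects, 2))
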