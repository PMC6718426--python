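"""Cohort-level statistics: initiating-event prevalence, exact
co-occurrence tests, group ANOVA with Tukey post-test, Kaplan-Meier /
logrank survival, and profile-type chi-square.

The Fisher machinery reports the conditional maximum-likelihood odds
ratio with an exact (noncentral hypergeometric) confidence interval, the
convention of R's ``fisher.test``; zero cells give a one-sided finite
bound rather than any continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .cnv import fraction_genome_altered
from .genome import GenomeBuild
from .model import CaseRecord
from .taxonomy import EventMatrix


# ------------------------------------------------------------- prevalence

@dataclass(frozen=True)
class Prevalence:
    count: int
    total: int

    @property
    def pct(self) -> float:
        """Percentage at one decimal."""
        return round(100.0 * self.count / self.total, 1)

    def __str__(self) -> str:
        return f"{self.count}/{self.total} ({self.pct}%)"


def prevalence_by_grade(events: EventMatrix, groups: dict[str, str],
                        event_genes: list[str]) -> dict[str, Prevalence]:
    """Fraction of cases per group carrying >= 1 event among
    ``event_genes`` (e.g. the initiating set KRAS/BRAF/CDKN2A)."""
    sub = events.data.loc[[g for g in event_genes if g in events.data.index]]
    hit = sub.max(axis=0)  # per case: any event in the set
    out: dict[str, Prevalence] = {}
    for group in dict.fromkeys(groups.values()):
        ids = [cid for cid, g in groups.items() if g == group]
        if not ids:
            raise ValueError(f"empty group {group!r}")
        present = [i for i in ids if i in hit.index]
        if not present:
            raise ValueError(f"group {group!r} has no cases in the event matrix")
        out[group] = Prevalence(int(hit[present].sum()), len(present))
    return out


# ----------------------------------------------------------- Fisher exact

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d of an eventA x eventB cross-tabulation."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("table entries must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    conf_level: float
    orientation: str = "rows=eventA(yes/no), cols=eventB(yes/no); OR = odds(B|A)/odds(B|notA)"


def _nch(psi: float, M: int, n: int, N: int):
    return sps.nchypergeom_fisher(M, n, N, psi)


def _cond_mle_or(x: int, M: int, n: int, N: int) -> float:
    lo, hi = max(0, N - (M - n)), min(n, N)
    if x == lo:
        return 0.0
    if x == hi:
        return math.inf
    f = lambda t: _nch(math.exp(t), M, n, N).mean() - x
    return math.exp(brentq(f, -40, 40, xtol=1e-12))


def _exact_ci(x: int, M: int, n: int, N: int, alpha: float) -> tuple[float, float]:
    lo, hi = max(0, N - (M - n)), min(n, N)
    if x == lo:
        lower = 0.0
    else:
        f = lambda t: _nch(math.exp(t), M, n, N).sf(x - 1) - alpha / 2
        lower = math.exp(brentq(f, -40, 40, xtol=1e-12))
    if x == hi:
        upper = math.inf
    else:
        f = lambda t: _nch(math.exp(t), M, n, N).cdf(x) - alpha / 2
        upper = math.exp(brentq(f, -40, 40, xtol=1e-12))
    return lower, upper


def fisher_cooccurrence(table: ContingencyTable2x2,
                        conf_level: float = 0.95) -> FisherResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio and
    exact confidence interval.

    The p-value sums hypergeometric probabilities <= that of the observed
    table; the odds ratio maximizes the noncentral hypergeometric
    likelihood conditional on the margins, and the CI inverts its exact
    tail probabilities. Zero cells yield OR 0 or inf with a finite
    one-sided bound.
    """
    t = table
    _, p = sps.fisher_exact(t.array, alternative="two-sided")
    M = t.a + t.b + t.c + t.d
    n = t.a + t.b  # first row
    N = t.a + t.c  # first column
    x = t.a
    or_ = _cond_mle_or(x, M, n, N)
    lo, hi = _exact_ci(x, M, n, N, 1 - conf_level)
    return FisherResult(float(p), or_, lo, hi, conf_level)


# ----------------------------------------------------------------- ANOVA

@dataclass
class AnovaTukeyResult:
    f_statistic: float
    df_group: int
    df_resid: int
    p_value: float
    anova_table: pd.DataFrame
    tukey: pd.DataFrame  # pairwise comparisons on the group factor


def anova_tukey(values, groups, covariate=None) -> AnovaTukeyResult:
    """Linear-model ANOVA of a per-case statistic (FGA, burden) on group,
    optionally adjusting for a second factor (sequencing platform), with
    Tukey HSD on the group factor (studentized-range p-values)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"value": np.asarray(values, float),
                       "group": list(groups)})
    formula = "value ~ C(group)"
    if covariate is not None:
        df["covariate"] = list(covariate)
        formula += " + C(covariate)"
    counts = df.groupby("group").size()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 values each")
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(group)"]
    hsd = pairwise_tukeyhsd(df["value"], df["group"])
    tukey = pd.DataFrame(hsd.summary().data[1:],
                         columns=hsd.summary().data[0])
    return AnovaTukeyResult(
        f_statistic=float(row["F"]), df_group=int(row["df"]),
        df_resid=int(table.loc["Residual", "df"]),
        p_value=float(row["PR(>F)"]), anova_table=table, tukey=tukey)


def tukey_p(result: AnovaTukeyResult, g1: str, g2: str) -> float:
    t = result.tukey
    row = t[((t.group1 == g1) & (t.group2 == g2))
            | ((t.group1 == g2) & (t.group2 == g1))]
    if row.empty:
        raise KeyError(f"no Tukey comparison {g1} vs {g2}")
    return float(row["p-adj"].iloc[0])


# -------------------------------------------------------------- survival

@dataclass(frozen=True)
class SurvivalRecord:
    time: float  # months
    event: bool  # death of disease (other causes censored)
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("negative survival time")


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    curves: dict[str, pd.DataFrame]  # per group: KM step function


def km_logrank(records: list[SurvivalRecord]) -> LogrankResult:
    """Product-limit curves per group and the k-sample logrank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame([(r.time, r.event, r.group) for r in records],
                      columns=["time", "event", "group"])
    groups = df["group"].unique()
    if any((df["group"] == g).sum() == 0 for g in groups) or not len(groups):
        raise ValueError("every group needs records")
    curves = {}
    for g in groups:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[str(g)] = kmf.survival_function_.reset_index()
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return LogrankResult(float(res.test_statistic), len(groups) - 1,
                         float(res.p_value), curves)


def fga_survival_records(cases: list[CaseRecord], build: GenomeBuild,
                         cut: float | None = None,
                         ) -> tuple[list[SurvivalRecord], float]:
    """Dichotomize cases at an FGA cut point (median by default; the cut
    used is returned and should be logged) into FGA-high/FGA-low survival
    records. Disease-specific: only death-of-disease counts as an event."""
    from .cnv import call_segments

    usable = [c for c in cases if c.time is not None and c.event is not None]
    fga = {c.case_id: fraction_genome_altered(
        call_segments(c.segments) if any(s.call is None for s in c.segments)
        else c.segments, build) for c in usable}
    if cut is None:
        cut = float(np.median(list(fga.values())))
    records = [SurvivalRecord(
        time=c.time, event=c.event == "death-of-disease",
        group="FGA-high" if fga[c.case_id] > cut else "FGA-low")
        for c in usable]
    return records, cut


def cox_fit(df: pd.DataFrame, duration_col: str = "time",
            event_col: str = "event") -> pd.DataFrame:
    """Convenience multivariable Cox proportional-hazards fit (lifelines);
    returns the coefficient summary table."""
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph.summary


# ------------------------------------------------------------ chi-square

@dataclass
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected: bool  # any expected cell < 5


def profile_chisq(table) -> ChisqResult:
    """Pearson chi-square (no continuity correction) on a profile-type x
    grade contingency table; warns when any expected count < 5."""
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column in contingency table")
    chi2, p, df, expected = sps.chi2_contingency(arr, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("expected count < 5 in chi-square table", stacklevel=2)
    return ChisqResult(float(chi2), int(df), float(p), expected, low)
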