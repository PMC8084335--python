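"""Statistical tests used to summarise reaching-adaptation experiments.

The behavioural literature this package serves reports one-sample t-tests
against the target radius (often computed from printed mean/s.d./n only),
paired/unpaired t-tests, one-way repeated-measures ANOVA across trial
epochs with Greenhouse-Geisser df correction and partial eta squared, Tukey
post-hoc comparisons, and Bonferroni adjustment.  Everything here is a thin,
typed layer over scipy/pingouin/statsmodels, except the repeated-measures
Tukey (built from the RM-ANOVA within-error term, which no installed
package exposes directly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "TestResult",
    "t_one_sample_summary",
    "t_test_raw",
    "rm_anova_gg",
    "tukey_pairwise",
    "bonferroni",
]


@dataclass(frozen=True)
class SummaryStats:
    """(mean, sd, n) triple as printed in behavioural results tables."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError("n must be an integer >= 2")

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float | None = None  # partial eta squared where applicable
    note: str = ""


def t_one_sample_summary(s: SummaryStats, mu0: float) -> TestResult:
    """One-sample two-tailed t-test computed from summary statistics."""
    df = s.n - 1
    if s.sd == 0:
        if s.mean == mu0:
            return TestResult(0.0, df, 1.0)
        return TestResult(np.inf * np.sign(s.mean - mu0), df, 0.0, note="zero sd")
    t = (s.mean - mu0) / s.sem
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p))


def t_test_raw(x, y=None, mode: str = "one_sample", mu0: float = 0.0) -> TestResult:
    """t-test on raw vectors: ``one_sample`` (against mu0), ``paired`` or
    ``unpaired`` (pooled-variance)."""
    x = np.asarray(x, dtype=float)
    if mode == "one_sample":
        res = sps.ttest_1samp(x, mu0)
        df = x.size - 1
    elif mode == "paired":
        res = sps.ttest_rel(x, np.asarray(y, dtype=float))
        df = x.size - 1
    elif mode == "unpaired":
        y = np.asarray(y, dtype=float)
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(float(res.statistic), df, float(res.pvalue))


def _long_format(data: np.ndarray) -> pd.DataFrame:
    n, k = data.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "score": data.ravel(),
        }
    )


def rm_anova_gg(data) -> TestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is a participants x conditions matrix with no missing cells.
    Returns the F statistic, GG-corrected dfs (eps*(k-1), eps*(k-1)*(n-1)),
    the GG-corrected p value, and partial eta squared
    SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3 or data.shape[1] < 2:
        raise ValueError("need >= 3 participants and >= 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    if np.ptp(data.mean(axis=0)) < 1e-12 * max(1.0, np.abs(data).max()):
        # no condition effect at all; F is 0 by convention (0/0 otherwise
        # when the within-error also vanishes)
        return TestResult(0.0, (float(k - 1), float((k - 1) * (n - 1))), 1.0,
                          effect_size=0.0, note="GG eps=1.0000")
    aov = pg.rm_anova(
        data=_long_format(data), dv="score", within="condition",
        subject="subject", correction=True, effsize="np2", detailed=True,
    )
    row = aov.iloc[0]
    eps = float(row["eps"])
    F = float(row["F"])
    if "p_GG_corr" in aov.columns and np.isfinite(row.get("p_GG_corr", np.nan)):
        p = float(row["p_GG_corr"])
    else:  # pingouin omits the corrected p when sphericity holds trivially (k = 2)
        p = float(row["p_unc"])
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    return TestResult(F, (float(df1), float(df2)), p, effect_size=float(row["np2"]),
                      note=f"GG eps={eps:.4f}")


def _rm_error_term(data: np.ndarray) -> tuple[float, float]:
    """(MS_error, df_error) of the one-way RM decomposition."""
    n, k = data.shape
    grand = data.mean()
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_cond
    df_err = (n - 1) * (k - 1)
    return ss_err / df_err, df_err


def tukey_pairwise(data) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for a repeated-measures design.

    Uses the within-subject error term of the one-way RM-ANOVA (the context
    in which the post-hoc is reported) and the studentized-range
    distribution.  Returns a tidy frame with one row per condition pair.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ms_err, df_err = _rm_error_term(data)
    means = data.mean(axis=0)
    se = np.sqrt(ms_err / n)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            q = abs(diff) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
            rows.append({"a": i, "b": j, "mean_diff": diff, "q": q,
                         "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p values, capped at 1; m defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)
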