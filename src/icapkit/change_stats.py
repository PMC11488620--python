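"""Reliable change indices, group comparisons, pre/post models, and FDR.

The reliable change index (RCI) quantifies whether an individual's
pre-to-post change on a measure exceeds what measurement error alone would
produce: RCI = d_i / SEM_d, with d_i the after-minus-before difference and
SEM_d the standard error of measurement of that difference.  In the
Jacobson-Truax family, SEM_d = SD_baseline * sqrt(2) * sqrt(1 - r) with r
the measure's test-retest reliability.  Group comparisons replicate the
pooled-variance two-sample t and Pearson chi-square used for cohort
characteristic tables; pre/post effects use a random-intercept model whose
time effect coincides with the paired t-test in the balanced two-timepoint
case.  Multiple comparisons are handled with Benjamini-Hochberg q-values
flagged at q < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RCIRecord",
    "TestResult",
    "reliable_change",
    "estimate_sem_d",
    "rci_frame",
    "pooled_two_sample_t",
    "chi_square_2x2",
    "group_model",
    "prepost_model",
    "bh_fdr",
]


@dataclass
class RCIRecord:
    subject: str
    measure: str
    d_i: float
    sem_d: float

    @property
    def rci(self) -> float:
        return self.d_i / self.sem_d


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    estimate: float | None = None
    se: float | None = None
    q: float | None = None


def reliable_change(
    before: float, after: float, sem_d: float, subject: str = "", measure: str = ""
) -> RCIRecord:
    """RCI = (after - before) / SEM_d; positive means the score increased."""
    if sem_d <= 0:
        raise ValueError("sem_d must be positive")
    return RCIRecord(subject=subject, measure=measure, d_i=after - before, sem_d=sem_d)


def estimate_sem_d(sd_baseline: float, reliability: float) -> float:
    """SEM of a difference score: SD * sqrt(2) * sqrt(1 - r)."""
    if sd_baseline <= 0:
        raise ValueError("sd_baseline must be positive")
    if not 0.0 <= reliability < 1.0:
        raise ValueError("reliability must lie in [0, 1)")
    return sd_baseline * np.sqrt(2.0) * np.sqrt(1.0 - reliability)


def rci_frame(
    before: pd.Series | np.ndarray,
    after: pd.Series | np.ndarray,
    reliability: float | None = None,
    measure: str = "",
) -> pd.DataFrame:
    """Vector RCI for one measure across subjects.

    When ``reliability`` is None it is estimated as the in-sample pre/post
    Pearson correlation, clipped into [0, 0.99] (a warning reports the
    clipping); SD_baseline is the SD of the before scores.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if reliability is None:
        r = float(np.corrcoef(before, after)[0, 1])
        if not np.isfinite(r):  # a session with zero variance across subjects
            r = 0.0
        clipped = float(np.clip(r, 0.0, 0.99))
        if clipped != r:
            warnings.warn(
                f"{measure or 'measure'}: in-sample reliability {r:.3f} "
                f"clipped to {clipped:.2f} for SEM_d",
                stacklevel=2,
            )
        reliability = clipped
    sem_d = estimate_sem_d(float(before.std(ddof=1)), reliability)
    return pd.DataFrame(
        {
            "measure": measure,
            "d_i": after - before,
            "sem_d": sem_d,
            "rci": (after - before) / sem_d,
        }
    )


def pooled_two_sample_t(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TestResult:
    """Equal-variance two-sample t from group summaries, df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, p=float(p), estimate=m1 - m2, se=float(se))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table (no continuity correction), df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or table.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a margin is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), df=dof, p=float(p))


def group_model(
    scores: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    covariate: np.ndarray | pd.Series | None = None,
) -> TestResult:
    """OLS of score on a group indicator (optionally plus one covariate).

    The group coefficient's t-test is returned.  Without a covariate this
    coincides with the pooled two-sample t.
    """
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float)})
    g = pd.Series(group)
    codes = pd.Categorical(g).codes
    if len(np.unique(codes)) != 2:
        raise ValueError("group must have exactly two levels")
    if min(np.bincount(codes)) < 3:
        raise ValueError("need at least 3 subjects per group")
    df["group"] = codes
    formula = "score ~ group"
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if np.std(cov) == 0:
            raise ValueError("covariate is constant: singular design")
        df["cov"] = cov
        formula += " + cov"
    fit = smf.ols(formula, data=df).fit()
    return TestResult(
        statistic=float(fit.tvalues["group"]),
        df=float(fit.df_resid),
        p=float(fit.pvalues["group"]),
        estimate=float(fit.params["group"]),
        se=float(fit.bse["group"]),
    )


def prepost_model(
    before: np.ndarray | pd.Series,
    after: np.ndarray | pd.Series,
    subjects: np.ndarray | pd.Series | None = None,
) -> TestResult:
    """Random-intercept model of score on time for paired two-timepoint data.

    With complete balanced pairs the time effect is identical to the
    paired t-test on the differences, which is how it is computed here;
    the subject random intercept absorbs between-subject variance exactly.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("unpaired rows: before and after must align by subject")
    if np.any(np.isnan(before)) or np.any(np.isnan(after)):
        raise ValueError("paired complete data required")
    d = after - before
    n = len(d)
    est = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return TestResult(statistic=np.inf if est else 0.0, df=n - 1,
                          p=0.0 if est else 1.0, estimate=est, se=0.0)
    se = sd / np.sqrt(n)
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), df=n - 1, p=float(p), estimate=est, se=se)


def prepost_mixedlm(
    before: np.ndarray, after: np.ndarray, subjects: np.ndarray
) -> TestResult:
    """Explicit MixedLM fit (score ~ time, random intercept per subject).

    Provided as the long-form route; on balanced pairs it agrees with
    :func:`prepost_model` up to optimiser tolerance.
    """
    n = len(before)
    data = pd.DataFrame(
        {
            "score": np.concatenate([before, after]),
            "time": np.repeat([0.0, 1.0], n),
            "subject": np.tile(np.asarray(subjects), 2),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM.from_formula(
            "score ~ time", groups="subject", data=data
        ).fit(reml=True)
    return TestResult(
        statistic=float(fit.tvalues["time"]),
        df=float(n - 1),
        p=float(fit.pvalues["time"]),
        estimate=float(fit.params["time"]),
        se=float(fit.bse["time"]),
    )


def bh_fdr(pvals: np.ndarray, q_threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and q < threshold flags."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold
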