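"""Concurrent-validity statistics between two measurement systems.

Implements the two-way single-rater intraclass correlation coefficients
ICC(C,1) (consistency, insensitive to constant offsets) and ICC(A,1)
(absolute agreement), with F-distribution confidence intervals after McGraw &
Wong; Bland-Altman bias and 95% limits of agreement; the standard error of
measurement SEM = SD * sqrt(1 - ICC); RMSE; and a paired bias test that uses
a paired t-test when Shapiro-Wilk does not reject normality of the
differences and a Wilcoxon signed-rank test otherwise.

The pair table convention is column 0 = AR, column 1 = reference, so the
reported bias is reference minus AR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError, InsufficientDataError
from .timeseries import TrialPair, detrend_offset


@dataclass
class ICCResult:
    value: float
    ci: tuple
    form: str
    degenerate: bool = False


@dataclass
class TestResult:
    test: str        # "t" | "wilcoxon"
    statistic: float
    p: float


@dataclass
class AgreementReport:
    icc_form: str
    icc: float
    icc_ci: tuple
    rmse: float
    bias: float
    loa: tuple
    sem_value: float
    test: str
    statistic: float
    p: float
    n: int
    rmse_ci: tuple = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["icc_ci"] = list(self.icc_ci)
        d["loa"] = list(self.loa)
        if self.rmse_ci is not None:
            d["rmse_ci"] = list(self.rmse_ci)
        return d


def _as_table(pairs) -> np.ndarray:
    table = np.asarray(pairs, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise InputError("pair table must have shape (n, 2)")
    if np.any(~np.isfinite(table)):
        raise InputError("pair table contains missing values")
    return table


def _mean_squares(table: np.ndarray):
    """Two-way ANOVA mean squares for an n x k table (rows = subjects)."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((table - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(pairs, form: str = "A1", alpha: float = 0.05) -> ICCResult:
    """Two-way single-rater ICC with a 95% (or 1-alpha) confidence interval.

    ``form`` is "C1" (consistency) or "A1" (absolute agreement).  A table
    with no between-row variance is flagged degenerate (ICC undefined).
    """
    table = _as_table(pairs)
    n, k = table.shape
    if n < 3:
        raise InsufficientDataError("ICC needs at least 3 pairs")
    msr, msc, mse = _mean_squares(table)
    if msr < 1e-30:
        return ICCResult(np.nan, (np.nan, np.nan), form, degenerate=True)
    if form == "C1":
        value = (msr - mse) / (msr + (k - 1) * mse)
        if mse < 1e-30:
            return ICCResult(1.0, (1.0, 1.0), form)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    elif form == "A1":
        value = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        if mse < 1e-30 and msc < 1e-30:
            return ICCResult(1.0, (1.0, 1.0), form)
        # Satterthwaite df for the MSC/MSE mixture (McGraw & Wong)
        a = (k * value) / (n * (1 - value)) if value < 1 else np.inf
        b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
            ci = (lower, upper)
        else:
            ci = (1.0, 1.0)
    else:
        raise InputError(f"unknown ICC form {form!r}")
    return ICCResult(float(value), (float(ci[0]), float(ci[1])), form)


def bland_altman(pairs) -> tuple:
    """Bias and 95% limits of agreement of the paired differences.

    Differences are column 1 minus column 0 (reference minus AR); the limits
    are bias +/- 1.96 * SD (sample SD, n-1).  Returns ``(bias, (lo, hi))``.
    """
    table = _as_table(pairs)
    d = table[:, 1] - table[:, 0]
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def sem_measure(sd: float, icc_value: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC)."""
    if icc_value > 1:
        raise InputError("ICC cannot exceed 1")
    return float(sd * np.sqrt(max(0.0, 1.0 - icc_value)))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def paired_bias_test(pairs, alpha: float = 0.05) -> TestResult:
    """Normality-gated paired bias test (t-test or Wilcoxon signed-rank)."""
    table = _as_table(pairs)
    if len(table) < 3:
        raise InsufficientDataError("paired test needs at least 3 pairs")
    d = table[:, 1] - table[:, 0]
    if np.allclose(d, 0.0):
        return TestResult("t", 0.0, 1.0)
    sw_p = stats.shapiro(d).pvalue
    if sw_p >= alpha:
        res = stats.ttest_rel(table[:, 1], table[:, 0])
        return TestResult("t", float(res.statistic), float(res.pvalue))
    res = stats.wilcoxon(d)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue))


def pooled_sd(table: np.ndarray) -> float:
    """Average of the two columns' sample SDs (the SD entering the SEM)."""
    table = _as_table(table)
    return float(np.mean(table.std(axis=0, ddof=1)))


def agreement_report(pairs, form: str = "A1", alpha: float = 0.05) -> AgreementReport:
    """Full absolute-agreement summary for one metric's paired table."""
    table = _as_table(pairs)
    res = icc(table, form=form, alpha=alpha)
    bias, loa = bland_altman(table)
    sem_value = (np.nan if res.degenerate
                 else sem_measure(pooled_sd(table), res.value))
    test = paired_bias_test(table, alpha=alpha)
    return AgreementReport(
        icc_form=form, icc=res.value, icc_ci=res.ci,
        rmse=rmse(table[:, 0], table[:, 1]),
        bias=bias, loa=loa, sem_value=sem_value,
        test=test.test, statistic=test.statistic, p=test.p,
        n=len(table), degenerate=res.degenerate,
    )


def timeseries_consistency(pair: TrialPair, channel: str = "z",
                           alpha: float = 0.05) -> AgreementReport:
    """Frame-wise consistency of one channel between aligned systems.

    Both channels are offset-detrended, frames are treated as rows, and
    ICC(C,1) and RMSE are reported.  The RMSE interval uses the chi-square
    distribution of the summed squared errors (a normal-error approximation).
    """
    a = detrend_offset(pair.ar.channel(channel))
    b = detrend_offset(pair.ref.channel(channel))
    n = min(len(a), len(b))
    if n < pair.ar.rate:
        raise InsufficientDataError("need at least 1 s of aligned overlap")
    a, b = a[:n], b[:n]
    table = np.column_stack([a, b])
    res = icc(table, form="C1", alpha=alpha)
    err = rmse(a, b)
    if err > 0:
        rmse_ci = (err * np.sqrt(n / stats.chi2.ppf(1 - alpha / 2, n)),
                   err * np.sqrt(n / stats.chi2.ppf(alpha / 2, n)))
    else:
        rmse_ci = (0.0, 0.0)
    bias, loa = bland_altman(table)
    return AgreementReport(
        icc_form="C1", icc=res.value, icc_ci=res.ci, rmse=err,
        bias=bias, loa=loa,
        sem_value=np.nan if res.degenerate else sem_measure(pooled_sd(table), res.value),
        test="", statistic=np.nan, p=np.nan, n=n, rmse_ci=rmse_ci,
        degenerate=res.degenerate,
    )
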