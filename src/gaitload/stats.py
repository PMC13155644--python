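"""Cohort statistics: normality-gated paired comparisons, FDR control,
a priori power analysis, and responder summaries.

Paired differences are first screened with the Shapiro-Wilk test; normal
samples go to a two-sided paired t-test, non-normal ones to a two-sided
Wilcoxon signed-rank test (exact distribution for n <= 25 when there are no
ties). Exploratory outcomes are adjusted with the Benjamini-Hochberg
step-up procedure; the two primary outcomes bypass adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "PairedSample",
    "TestResult",
    "test_normality",
    "paired_compare",
    "bh_adjust",
    "paired_power_n",
    "cohort_summary",
]

NORMALITY_ALPHA = 0.05  # gate reuses the study-wide alpha


@dataclass(frozen=True)
class PairedSample:
    """Per-participant (baseline, feedback) pairs for one outcome."""

    outcome: str
    baseline: np.ndarray
    feedback: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.baseline, dtype=float)
        f = np.asarray(self.feedback, dtype=float)
        object.__setattr__(self, "baseline", b)
        object.__setattr__(self, "feedback", f)
        if b.size != f.size:
            raise ValueError("baseline/feedback lengths differ")
        if b.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(np.isnan(b)) or np.any(np.isnan(f)):
            raise ValueError("missing member of a pair")

    @property
    def differences(self) -> np.ndarray:
        return self.feedback - self.baseline


@dataclass
class TestResult:
    outcome: str
    test: str  # paired_t | wilcoxon | degenerate
    statistic: float
    p: float
    mean_diff: float
    sd_diff: float
    n: int
    p_adj: float | None = None
    degenerate: bool = False
    units: str = ""


def test_normality(x) -> float:
    """Shapiro-Wilk p-value for a sample of differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 values, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 values")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant sample")
    return float(sst.shapiro(x).pvalue)


def paired_compare(sample: PairedSample, alpha: float = 0.05) -> TestResult:
    """Normality-gated two-sided paired comparison.

    All-zero differences yield p = 1 with the degenerate flag; any other
    zero-variance sample is flagged degenerate with p = NaN (the statistic
    is undefined).
    """
    d = sample.differences
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    base = dict(
        outcome=sample.outcome, mean_diff=mean_d, sd_diff=sd_d,
        n=d.size, units=sample.units,
    )
    if np.ptp(d) == 0:
        p = 1.0 if d[0] == 0 else float("nan")
        return TestResult(test="degenerate", statistic=float("nan"), p=p,
                          degenerate=True, **base)
    # fewer than 3 pairs: the normality gate is untestable; default to t
    if d.size < 3 or test_normality(d) >= alpha:
        t = sst.ttest_rel(sample.feedback, sample.baseline)
        return TestResult(test="paired_t", statistic=float(t.statistic),
                          p=float(t.pvalue), **base)
    w = sst.wilcoxon(d, alternative="two-sided",
                     method="exact" if d.size <= 25 and not _has_ties(d) else "approx")
    return TestResult(test="wilcoxon", statistic=float(w.statistic),
                      p=float(w.pvalue), **base)


def _has_ties(d: np.ndarray) -> bool:
    a = np.abs(d[d != 0])
    return a.size != np.unique(a).size or np.any(d == 0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def paired_t_power(n: float, effect: float, alpha: float = 0.05,
                   two_sided: bool = True) -> float:
    """Power of a paired t-test at (possibly non-integer) n pairs, via the
    noncentral-t distribution with df = n - 1 and ncp = effect * sqrt(n)."""
    df = n - 1.0
    ncp = effect * np.sqrt(n)
    if two_sided:
        tc = sst.t.ppf(1.0 - alpha / 2.0, df)
        upper = sst.nct.sf(tc, df, ncp)
        lower = sst.nct.cdf(-tc, df, ncp)
        if np.isnan(lower):  # scipy far-tail quadrature glitch; term ~ 0 there
            lower = 0.0
        return float(upper + lower)
    tc = sst.t.ppf(1.0 - alpha, df)
    return float(sst.nct.sf(tc, df, ncp))


def paired_power_n(
    mean_diff: float,
    sd_diff: float,
    power: float = 0.9,
    alpha: float = 0.05,
    two_sided: bool = True,
    rounding: str = "nearest",
) -> int:
    """Required number of pairs for a paired t-test on
    Normal(mean_diff, sd_diff^2) differences (noncentral-t computation).

    The continuous sample size solving power(n) = target is found first
    (the computation standard power tools such as R's ``power.t.test``
    perform, with continuous df). ``rounding="nearest"`` reports the nearest
    integer — the convention of the study-size reports this mirrors —
    while ``rounding="ceil"`` returns the smallest integer n whose exact
    power meets the target.
    """
    if sd_diff <= 0:
        raise ValueError("sd_diff must be > 0")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if mean_diff == 0:
        raise ValueError("mean_diff must be nonzero")
    if rounding not in ("nearest", "ceil"):
        raise ValueError("rounding must be 'nearest' or 'ceil'")
    effect = abs(mean_diff) / sd_diff

    lo = 2.0
    if paired_t_power(lo, effect, alpha, two_sided) >= power:
        return 2  # implementation floor: at least two pairs
    hi = 4.0
    while paired_t_power(hi, effect, alpha, two_sided) < power:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("no attainable n reaches the target power")
    from scipy.optimize import brentq

    n_cont = brentq(
        lambda n: paired_t_power(n, effect, alpha, two_sided) - power, lo, hi,
        xtol=1e-10,
    )
    if rounding == "nearest":
        return max(2, int(round(n_cont)))
    return max(2, int(np.ceil(n_cont - 1e-9)))


def cohort_summary(changes: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary of per-participant outcome changes.

    ``changes``: one row per participant, one column per outcome (change =
    feedback - baseline). Returns mean, SD (NaN-flagged for n = 1),
    responder count (change < 0) and responder fraction per outcome.
    """
    if changes.shape[0] < 1:
        raise ValueError("need at least one participant")
    rows = []
    for col in changes.columns:
        x = changes[col].to_numpy(dtype=float)
        n = x.size
        rows.append(
            {
                "outcome": col,
                "n": n,
                "mean_change": float(x.mean()),
                "sd_change": float(x.std(ddof=1)) if n > 1 else float("nan"),
                "responders": int((x < 0).sum()),
                "responder_fraction": float((x < 0).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("outcome")
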