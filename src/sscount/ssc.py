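"""Single Sample Count prevalence estimation.

The reported total of each respondent is the sum of ``m`` independent
Bernoulli(p_i) innocuous answers and one Bernoulli(d) sensitive answer,
so the sample-wide affirmative count λ is the sum of ``m`` Binomial(n, p_i)
variables plus Binomial(n, d). Each binomial is approximated by its
matching normal; their sum is normal with

    mean = n * (sum_i p_i + d),   var = n * (sum_i p_i (1 - p_i) + d(1 - d)),

which yields the point estimate d̂ = λ/n − Σp_i and a Wald interval on the
count scale. The *simple* algorithm is the equal-probability special case
p_i = 1/2 (benchmark Σp_i = m/2, innocuous variance m/4).

Because d̂ can be negative, the d(1−d) variance plug-in is ambiguous.
``variance_plugin="clamped"`` (default) evaluates it at d̂ clipped to
[0, 1] — zero for out-of-range estimates, never a negative variance
contribution — while ``"raw"`` plugs in d̂ unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

from .designs import DesignError, PrevalenceEstimate, SSCDesign, SSCResponseSet

__all__ = [
    "estimate_ssc_simple",
    "estimate_ssc_general",
    "ssc_benchmark_t_test",
    "TTestResult",
]


def _plugin_term(d_raw: float, variance_plugin: str) -> float:
    if variance_plugin == "clamped":
        d = min(1.0, max(0.0, d_raw))
        return d * (1.0 - d)
    if variance_plugin == "raw":
        return d_raw * (1.0 - d_raw)
    raise ValueError(f"variance_plugin: expected 'clamped' or 'raw', got {variance_plugin!r}")


def _check_totals(responses: SSCResponseSet, m: int) -> None:
    if responses.n == 0:
        raise DesignError("n: response set is empty")
    if responses.n and int(responses.totals.max()) > m + 1:
        raise DesignError(
            f"totals: total {int(responses.totals.max())} exceeds m+1 = {m + 1}"
        )


def _estimate(
    responses: SSCResponseSet,
    probs: Tuple[float, ...],
    alpha: float,
    variance_plugin: str,
    method: str,
) -> PrevalenceEstimate:
    m = len(probs)
    _check_totals(responses, m)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha: must be in (0, 1), got {alpha}")
    n = responses.n
    lam = responses.sum_yes
    benchmark = float(sum(probs))

    d_raw = lam / n - benchmark
    var_unit = float(sum(p * (1.0 - p) for p in probs)) + _plugin_term(d_raw, variance_plugin)
    if var_unit < 0.0:
        raise DesignError(
            "variance: negative plug-in variance; use variance_plugin='clamped'"
        )
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    # Wald interval built on the count scale lambda ~ N(n*(benchmark+d), n*var_unit)
    half_width = z * np.sqrt(n * var_unit) / n
    se = float(np.sqrt(n * var_unit) / n)

    d_trunc = min(1.0, max(0.0, d_raw))
    diagnostics = {
        "variance_plugin": variance_plugin,
        "negative_estimate": d_raw < 0.0,
        # np > 5 rule of thumb for the sensitive Binomial(n, d) component
        "sensitive_normal_ok": (n * d_trunc > 5.0) and (n * (1.0 - d_trunc) > 5.0),
        "benchmark": benchmark,
        "z": float(z),
    }
    return PrevalenceEstimate(
        d_raw=float(d_raw),
        se=se,
        ci_raw=(float(d_raw - half_width), float(d_raw + half_width)),
        method=method,
        n=n,
        alpha=alpha,
        diagnostics=diagnostics,
    )


def estimate_ssc_simple(
    responses: SSCResponseSet,
    m: int = 4,
    alpha: float = 0.05,
    variance_plugin: str = "clamped",
) -> PrevalenceEstimate:
    """Estimate prevalence under the equal-probability (p_i = 1/2) design.

    d̂ = λ/n − m/2, with a Wald interval from λ ~ N(n(m/2 + d), n(m/4 + d(1−d))).

    Examples
    --------
    >>> est = estimate_ssc_simple(SSCResponseSet.from_counts(
    ...     {0: 15, 1: 64, 2: 89, 3: 51, 4: 16, 5: 2}), m=4)
    >>> round(est.d_raw, 6)
    -0.021097
    """
    if m < 1:
        raise DesignError(f"m: must be >= 1, got {m}")
    return _estimate(responses, (0.5,) * int(m), alpha, variance_plugin, "ssc_simple")


def estimate_ssc_general(
    responses: SSCResponseSet,
    design: SSCDesign,
    alpha: float = 0.05,
    variance_plugin: str = "clamped",
) -> PrevalenceEstimate:
    """Estimate prevalence with per-question innocuous probabilities.

    d̂ = λ/n − Σp_i; the variance sums each question's normal approximation
    n·p_i(1−p_i) plus the sensitive term. Reduces exactly to
    :func:`estimate_ssc_simple` when every p_i is 0.5.
    """
    est = _estimate(responses, design.probs, alpha, variance_plugin, "ssc_general")
    return est


@dataclass(frozen=True)
class TTestResult:
    """One-sample t-test of the mean reported total against the benchmark."""

    t_stat: float
    df: int
    p_value: float
    mean: float
    sd: float
    cohens_d: float
    benchmark: float
    ci_mean: Tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "mean": self.mean,
            "sd": self.sd,
            "cohens_d": self.cohens_d,
            "benchmark": self.benchmark,
            "ci_mean": list(self.ci_mean),
        }


def ssc_benchmark_t_test(
    responses: SSCResponseSet,
    design: SSCDesign,
    alpha: float = 0.05,
) -> TTestResult:
    """Test whether the mean reported total differs from the design benchmark.

    A mean indistinguishable from ``sum(p_i)`` means the sample carries no
    evidence of non-zero prevalence. Two-sided p-value; Cohen's d is
    |mean − benchmark| / sd.
    """
    if responses.n < 2:
        raise DesignError(f"n: t-test needs at least 2 respondents, got {responses.n}")
    _check_totals(responses, design.m)
    x = responses.totals.astype(float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DesignError("totals: zero variance, t-test undefined")
    benchmark = design.benchmark
    res = stats.ttest_1samp(x, popmean=benchmark)
    mean = float(np.mean(x))
    df = responses.n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    half = tcrit * sd / np.sqrt(responses.n)
    return TTestResult(
        t_stat=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        mean=mean,
        sd=sd,
        cohens_d=abs(mean - benchmark) / sd,
        benchmark=benchmark,
        ci_mean=(float(mean - half), float(mean + half)),
    )
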