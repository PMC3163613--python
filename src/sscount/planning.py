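"""Sample-size and power planning for SSC and FR surveys.

Three planners:

* :func:`ssc_ci_table` — exact Binomial(m·n, 1/2) confidence bounds for
  the mean innocuous total, showing how slowly the interval narrows in n;
* :func:`ssc_min_sample_size` — smallest n detecting an upward shift Δ of
  the mean total above the benchmark with a one-sided level-α test,
  n = (t·s/Δ)², where s is the per-respondent SD of the reported total;
* :func:`fr_min_sample_size` — smallest n achieving a target standard
  error for the Forced Response estimator under the worst case λ = 1/2,
  n = λ(1−λ)/(SE²·π₂²).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignError, FRDesign

__all__ = [
    "ssc_ci_table",
    "analytic_total_sd",
    "simulated_total_sd",
    "ssc_min_sample_size",
    "fr_min_sample_size",
]


def ssc_ci_table(
    m_values: Iterable[int] = (4, 5, 6),
    n_values: Iterable[int] = (100, 200, 300, 400, 500, 750, 1000, 1500, 2000),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact binomial CI bounds for the mean innocuous total, per m and n.

    With all innocuous probabilities 1/2, the sample-wide innocuous count
    is Binomial(m·n, 1/2); bounds are the alpha/2 and 1−alpha/2 quantiles
    (smallest integer whose CDF reaches the level) divided by n. The
    d = 0 sampling band the sample mean must clear to signal prevalence.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha: must be in (0, 1), got {alpha}")
    rows = []
    for n in n_values:
        if n < 1:
            raise DesignError(f"n: must be >= 1, got {n}")
        row: dict = {"n": int(n)}
        for m in m_values:
            if m < 1:
                raise DesignError(f"m: must be >= 1, got {m}")
            lo = stats.binom.ppf(alpha / 2.0, m * n, 0.5) / n
            hi = stats.binom.ppf(1.0 - alpha / 2.0, m * n, 0.5) / n
            row[f"m={m} lower"] = float(lo)
            row[f"m={m} upper"] = float(hi)
        rows.append(row)
    return pd.DataFrame(rows).set_index("n")


def analytic_total_sd(d: float, m: int = 4) -> float:
    """Closed-form SD of a respondent's reported total: sqrt(m/4 + d(1−d))."""
    if not (0.0 <= d <= 1.0):
        raise DesignError(f"d: prevalence must be in [0, 1], got {d}")
    return math.sqrt(m / 4.0 + d * (1.0 - d))


def simulated_total_sd(
    d: float,
    m: int = 4,
    reps: int = 10_000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> float:
    """Sample SD of ``reps`` simulated reported totals (mirrors planning by
    simulation; requires an explicit seed for reproducibility)."""
    if seed is None:
        raise ValueError("seed: simulation-based s requires an explicit seed")
    from .simulate import simulate_ssc  # local import to avoid cycle

    responses = simulate_ssc(d=d, n=reps, m=m, seed=seed)
    return float(np.std(responses.totals.astype(float), ddof=1))


def ssc_min_sample_size(
    delta: float,
    d: Optional[float] = None,
    alpha: float = 0.05,
    m: int = 4,
    s: Optional[float] = None,
    s_source: str = "analytic",
    reps: int = 10_000,
    seed: Optional[int] = None,
    rounding: str = "ceil",
) -> int:
    """Minimum n to detect a mean-total shift of Δ above the benchmark.

    Solves (x̄ − benchmark)/(s/√n) = t_crit for n, with t_crit the
    one-sided normal critical value at ``alpha`` (1.645 at 0.05):
    n = (t_crit·s/Δ)².

    ``s`` may be given directly; otherwise it comes from the analytic
    closed form at prevalence ``d`` (default) or from a seeded simulation
    (``s_source="simulated"``). ``rounding="ceil"`` is the conservative
    default; ``"trunc"`` drops the fraction.
    """
    if delta <= 0.0:
        raise DesignError(f"delta: effect size must be > 0, got {delta}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha: must be in (0, 1), got {alpha}")
    if s is None:
        if d is None:
            raise ValueError("d: needed to derive s when s is not given")
        if s_source == "analytic":
            s = analytic_total_sd(d, m=m)
        elif s_source == "simulated":
            s = simulated_total_sd(d, m=m, reps=reps, seed=seed)
        else:
            raise ValueError(
                f"s_source: expected 'analytic' or 'simulated', got {s_source!r}"
            )
    t_crit = float(stats.norm.ppf(1.0 - alpha))
    n_exact = (t_crit * s / delta) ** 2
    if rounding == "ceil":
        return max(1, math.ceil(round(n_exact, 9)))
    if rounding == "trunc":
        return max(1, math.floor(round(n_exact, 9)))
    raise ValueError(f"rounding: expected 'ceil' or 'trunc', got {rounding!r}")


def fr_min_sample_size(
    se_target: float,
    design: Optional[FRDesign] = None,
    p_honest: Optional[float] = None,
    lam: float = 0.5,
) -> int:
    """Minimum n for a target Forced Response standard error.

    Inverts SE = sqrt(λ(1−λ)/n)/π₂, conservatively evaluated at the
    variance-maximising λ = 1/2 by default: n = ceil(λ(1−λ)/(SE²·π₂²)).
    """
    if se_target <= 0.0:
        raise DesignError(f"se_target: must be > 0, got {se_target}")
    if not (0.0 <= lam <= 1.0):
        raise DesignError(f"lam: must be in [0, 1], got {lam}")
    if p_honest is None:
        p_honest = 0.75 if design is None else design.p_honest
    if p_honest <= 0.0:
        raise DesignError("p_honest: must be > 0")
    n_exact = lam * (1.0 - lam) / (se_target**2 * p_honest**2)
    return max(1, math.ceil(round(n_exact, 9)))
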