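"""Answer-category distributions and exposure risk for SSC designs.

A respondent with all ``m`` innocuous answers affirmative *and* the
sensitive behaviour must report the top category ``m+1``, which is fully
revealing. Two mitigations redistribute that category's mass:

* ``merge_top_bottom`` — categories 0 and ``m+1`` share one answer box,
  so the top category's mass moves to 0;
* ``any_other`` — respondents who would report ``m+1`` pick any of the
  remaining options uniformly, spreading the mass over ``0..m``.

The honest PMF is the convolution of the ``m`` innocuous Bernoulli(p_i)
components with the Bernoulli(d) sensitive component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .designs import DesignError

__all__ = [
    "SCENARIOS",
    "AnswerDistribution",
    "answer_pmf",
    "exposure_probabilities",
    "exposure_table",
    "compare_distributions",
]

SCENARIOS = ("honest", "merge_top_bottom", "any_other")


@dataclass(frozen=True)
class AnswerDistribution:
    """PMF over reported answer categories under one response scenario.

    ``categories`` are the reportable totals; under ``merge_top_bottom``
    the top category disappears and its mass sits at category 0.
    """

    categories: Tuple[int, ...]
    pmf: Tuple[float, ...]
    scenario: str
    d: float
    m: int

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def full_support_pmf(self) -> np.ndarray:
        """PMF on the common support ``0..m+1`` (missing categories get 0)."""
        out = np.zeros(self.m + 2)
        out[list(self.categories)] = self.pmf
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"category": self.categories, "probability": self.pmf})


def _innocuous_pmf(probs: Sequence[float]) -> np.ndarray:
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def answer_pmf(
    m: int,
    d: float,
    scenario: str = "honest",
    probs: Optional[Sequence[float]] = None,
) -> AnswerDistribution:
    """Exact answer-category PMF for an ``m + 1`` SSC design.

    For the default equal 0.5 design with ``m = 4`` this reproduces the
    closed forms (e.g. honest P(0) = 1/16 − d/16, P(m+1) = d/16; merged
    P(0) = 1/16; any-other spreads d/16 into d/(16(m+1)) per category).

    Parameters
    ----------
    m
        Number of innocuous questions.
    d
        Sensitive-behaviour prevalence in [0, 1].
    scenario
        One of ``"honest"``, ``"merge_top_bottom"``, ``"any_other"``.
    probs
        Optional per-question innocuous probabilities (default all 0.5).
    """
    if m < 1:
        raise DesignError(f"m: must be >= 1, got {m}")
    if not (0.0 <= d <= 1.0):
        raise DesignError(f"d: prevalence must be in [0, 1], got {d}")
    if scenario not in SCENARIOS:
        raise DesignError(f"scenario: expected one of {SCENARIOS}, got {scenario!r}")
    if probs is None:
        probs = (0.5,) * m
    elif len(probs) != m:
        raise DesignError(f"probs: expected {m} probabilities, got {len(probs)}")

    honest = np.convolve(_innocuous_pmf(probs), [1.0 - d, d])  # length m+2
    if scenario == "honest":
        pmf = honest
        categories = tuple(range(m + 2))
    elif scenario == "merge_top_bottom":
        pmf = honest[:-1].copy()
        pmf[0] += honest[-1]
        categories = tuple(range(m + 1))
    else:  # any_other
        pmf = honest[:-1] + honest[-1] / (m + 1)
        categories = tuple(range(m + 1))
    return AnswerDistribution(
        categories=categories,
        pmf=tuple(float(x) for x in pmf),
        scenario=scenario,
        d=float(d),
        m=m,
    )


def exposure_probabilities(
    m: int,
    d: float,
    probs: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """Exposure risk, in percent, of an ``m + 1`` design.

    Returns ``(p_all_innocuous_yes, p_full_exposure)``: the chance a
    respondent's innocuous answers are all affirmative (100·∏p_i, i.e.
    100·0.5^m for equal designs), and the chance they must report the
    fully revealing top category (that times d).
    """
    if m < 1:
        raise DesignError(f"m: must be >= 1, got {m}")
    if not (0.0 <= d <= 1.0):
        raise DesignError(f"d: prevalence must be in [0, 1], got {d}")
    if probs is None:
        probs = (0.5,) * m
    p_all = 100.0 * float(np.prod(np.asarray(probs, dtype=float)))
    return p_all, p_all * d


def exposure_table(
    m_values: Iterable[int] = range(1, 9),
    d_values: Iterable[float] = (0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50),
) -> pd.DataFrame:
    """Exposure-risk grid across design sizes and prevalence rates.

    One row per ``m`` ("m+1" design); the ``innocuous`` column is the
    percentage of respondents answering every innocuous question
    affirmatively, and each prevalence column the percentage forced into
    the fully revealing answer.
    """
    rows = []
    d_values = list(d_values)
    for m in m_values:
        p_all, _ = exposure_probabilities(m, 0.0)
        row = {"design": f"{m} + 1", "innocuous": p_all}
        for d in d_values:
            row[f"d={d:g}"] = exposure_probabilities(m, d)[1]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_distributions(a: AnswerDistribution, b: AnswerDistribution) -> dict:
    """Kolmogorov-Smirnov and RMS divergence between two answer distributions.

    Both PMFs are aligned on the common support ``0..m+1`` (a merged
    top-and-bottom category contributes its whole mass at position 0);
    ``ks`` is the maximum absolute CDF difference over that support and
    ``rms`` the root-mean-square of per-category PMF differences.
    """
    if a.m != b.m:
        raise DesignError(f"m: cannot compare m={a.m} with m={b.m}")
    pa, pb = a.full_support_pmf(), b.full_support_pmf()
    ks = float(np.max(np.abs(np.cumsum(pa) - np.cumsum(pb))))
    rms = float(np.sqrt(np.mean((pa - pb) ** 2)))
    return {"ks": ks, "rms": rms}
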