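"""Forward simulation of survey respondents for both designs.

Each SSC respondent draws ``m`` independent Bernoulli(p_i) innocuous
answers and one Bernoulli(d) sensitive answer and reports the total;
exposure-mitigation scenarios then transform any fully revealing report.
Each FR respondent is forced 'yes' with probability π₁, forced 'no' with
π_no, and otherwise answers Bernoulli(d) honestly.

Randomness: every public function takes either an integer seed or a
``numpy.random.Generator``. Replicated studies derive one independent
child stream per replication from ``numpy.random.SeedSequence(seed)``,
so a study is reproducible from its single seed and replications are
statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .designs import (
    DesignError,
    FRDesign,
    FRResponseSet,
    SSCDesign,
    SSCResponseSet,
)
from .distributions import SCENARIOS
from .fr import estimate_fr
from .ssc import estimate_ssc_simple

__all__ = ["SimulationSpec", "simulate_ssc", "simulate_fr", "run_recovery_study"]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _rng(seed: Optional[SeedLike]) -> np.random.Generator:
    if seed is None:
        raise ValueError("seed: an explicit seed is required for reproducibility")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationSpec:
    """A reproducible simulation request for either model."""

    model: str  # "ssc" | "fr"
    design: Union[SSCDesign, FRDesign]
    d: float
    n: int
    seed: int
    scenario: str = "honest"
    replications: int = 1

    def __post_init__(self) -> None:
        if self.model not in ("ssc", "fr"):
            raise DesignError(f"model: expected 'ssc' or 'fr', got {self.model!r}")
        if not (0.0 <= self.d <= 1.0):
            raise DesignError(f"d: prevalence must be in [0, 1], got {self.d}")
        if self.n < 1:
            raise DesignError(f"n: must be >= 1, got {self.n}")
        if self.model == "fr" and self.scenario != "honest":
            raise DesignError("scenario: exposure scenarios apply to SSC only")
        if self.model == "ssc" and self.scenario not in SCENARIOS:
            raise DesignError(f"scenario: expected one of {SCENARIOS}, got {self.scenario!r}")


def simulate_ssc(
    d: float,
    n: int,
    m: int = 4,
    probs: Optional[Sequence[float]] = None,
    scenario: str = "honest",
    seed: Optional[SeedLike] = None,
    design: Optional[SSCDesign] = None,
) -> SSCResponseSet:
    """Simulate ``n`` SSC respondents at true prevalence ``d``.

    Under ``scenario="merge_top_bottom"`` a total of ``m+1`` is recorded
    as 0 (shared answer box); under ``"any_other"`` such respondents pick
    a category in ``0..m`` uniformly at random.
    """
    if design is not None:
        m, probs = design.m, design.probs
    if probs is None:
        probs = (0.5,) * m
    if len(probs) != m:
        raise DesignError(f"probs: expected {m} probabilities, got {len(probs)}")
    if not (0.0 <= d <= 1.0):
        raise DesignError(f"d: prevalence must be in [0, 1], got {d}")
    if scenario not in SCENARIOS:
        raise DesignError(f"scenario: expected one of {SCENARIOS}, got {scenario!r}")
    rng = _rng(seed)
    totals = np.zeros(n, dtype=np.int64)
    for p in probs:
        totals += rng.random(n) < p
    totals += rng.random(n) < d
    if scenario == "merge_top_bottom":
        totals[totals == m + 1] = 0
    elif scenario == "any_other":
        mask = totals == m + 1
        totals[mask] = rng.integers(0, m + 1, size=int(mask.sum()))
    return SSCResponseSet(totals, m=m)


def simulate_fr(
    d: float,
    n: int,
    design: FRDesign,
    seed: Optional[SeedLike] = None,
) -> FRResponseSet:
    """Simulate ``n`` Forced Response respondents at true prevalence ``d``."""
    if not (0.0 <= d <= 1.0):
        raise DesignError(f"d: prevalence must be in [0, 1], got {d}")
    rng = _rng(seed)
    u = rng.random(n)
    forced_yes = u < design.p_forced_yes
    forced_no = (~forced_yes) & (u < design.p_forced_yes + design.p_forced_no)
    honest_yes = (~forced_yes) & (~forced_no) & (rng.random(n) < d)
    return FRResponseSet(n_yes=int((forced_yes | honest_yes).sum()), n=n)


def run_spec(spec: SimulationSpec) -> Union[SSCResponseSet, FRResponseSet]:
    """Run a single replication of a :class:`SimulationSpec`."""
    if spec.model == "ssc":
        return simulate_ssc(
            d=spec.d, n=spec.n, design=spec.design, scenario=spec.scenario, seed=spec.seed
        )
    return simulate_fr(d=spec.d, n=spec.n, design=spec.design, seed=spec.seed)


def run_recovery_study(
    model: str,
    design: Union[SSCDesign, FRDesign],
    d_values: Iterable[float],
    n: int,
    replications: int,
    seed: int,
    alpha: float = 0.05,
    estimator: Optional[Callable] = None,
) -> pd.DataFrame:
    """Monte-Carlo bias / spread / CI-coverage table for an estimator.

    For every true prevalence in ``d_values``, simulates ``replications``
    datasets of ``n`` respondents, applies the estimator (defaults:
    simple SSC or FR estimator as appropriate) and summarises the raw
    estimates: mean, bias, Monte-Carlo SE of that mean, empirical SD,
    mean reported SE, and the proportion of raw CIs covering the truth.
    """
    if replications < 2:
        raise DesignError(f"replications: must be >= 2, got {replications}")
    if model not in ("ssc", "fr"):
        raise DesignError(f"model: expected 'ssc' or 'fr', got {model!r}")
    if estimator is None:
        if model == "ssc":
            estimator = lambda resp: estimate_ssc_simple(resp, m=design.m, alpha=alpha)
        else:
            estimator = lambda resp: estimate_fr(resp, design, alpha=alpha)

    d_values = list(d_values)
    streams = np.random.SeedSequence(seed).spawn(len(d_values))
    rows = []
    for d, stream in zip(d_values, streams):
        rngs = [np.random.default_rng(s) for s in stream.spawn(replications)]
        d_hats = np.empty(replications)
        ses = np.empty(replications)
        covered = np.zeros(replications, dtype=bool)
        for r, rng in enumerate(rngs):
            if model == "ssc":
                resp = simulate_ssc(d=d, n=n, design=design, seed=rng)
            else:
                resp = simulate_fr(d=d, n=n, design=design, seed=rng)
            est = estimator(resp)
            d_hats[r] = est.d_raw
            ses[r] = est.se
            lo, hi = est.ci_raw
            covered[r] = lo <= d <= hi
        sd = float(np.std(d_hats, ddof=1))
        rows.append(
            {
                "model": model,
                "d": d,
                "n": n,
                "replications": replications,
                "mean_d_hat": float(np.mean(d_hats)),
                "bias": float(np.mean(d_hats) - d),
                "mc_se_of_mean": sd / np.sqrt(replications),
                "sd_d_hat": sd,
                "mean_se": float(np.mean(ses)),
                "coverage": float(np.mean(covered)),
            }
        )
    return pd.DataFrame(rows)
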