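"""Survey designs and observed-data containers.

Two indirect-questioning designs are supported:

* **Single Sample Count (SSC)** — the sensitive item is embedded among
  ``m`` innocuous yes/no questions whose population affirmative
  probabilities are known (ideally 0.5 each); each respondent reports only
  the total number of affirmative answers, an integer in ``0..m+1``.
* **Forced Response (FR)** — a chance device (e.g. a pair of dice) forces
  a 'yes' with probability ``p_forced_yes``, a 'no' with probability
  ``p_forced_no``, and otherwise requires an honest answer to the
  sensitive question.

The classes here validate designs and hold observed responses; all
estimation lives in :mod:`sscount.ssc` and :mod:`sscount.fr`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Tuple, Union

import numpy as np

__all__ = [
    "DesignError",
    "SSCDesign",
    "FRDesign",
    "SSCResponseSet",
    "FRResponseSet",
    "PrevalenceEstimate",
    "validate_design",
    "design_to_dict",
    "design_from_dict",
    "DICE_FR_DESIGN",
    "MEPHEDRONE_BASELINE_PROBS",
]

_TOL = 1e-9


class DesignError(ValueError):
    """A survey design or response set violates one of its invariants."""


def _as_float(value) -> float:
    # accept "1/6"-style strings so YAML configs can state dice odds exactly
    if isinstance(value, str):
        return float(Fraction(value))
    return float(value)


@dataclass(frozen=True)
class SSCDesign:
    """An ``m + 1`` Single Sample Count questionnaire.

    Parameters
    ----------
    m
        Number of innocuous questions (>= 1).
    probs
        Affirmative probability of each innocuous question, each strictly
        inside (0, 1). Defaults to the equal 0.5 design.
    """

    m: int
    probs: Tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = int(self.m)
        object.__setattr__(self, "m", m)
        if self.probs is None:
            probs = (0.5,) * m
        else:
            probs = tuple(_as_float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        validate_design(self)

    @classmethod
    def equal(cls, m: int = 4, p: float = 0.5) -> "SSCDesign":
        """The equal-probability design (the default 4+1 questionnaire)."""
        return cls(m=m, probs=(p,) * m)

    @property
    def benchmark(self) -> float:
        """Expected innocuous total per respondent, ``sum(probs)`` (2 for 4+1)."""
        return float(sum(self.probs))

    @property
    def is_equal_half(self) -> bool:
        return all(p == 0.5 for p in self.probs)


@dataclass(frozen=True)
class FRDesign:
    """A Forced Response randomising device.

    The three probabilities must form a simplex; ``p_honest`` must be
    positive or the design carries no information about the sensitive
    behaviour.
    """

    p_forced_yes: float
    p_forced_no: float
    p_honest: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_forced_yes", _as_float(self.p_forced_yes))
        object.__setattr__(self, "p_forced_no", _as_float(self.p_forced_no))
        object.__setattr__(self, "p_honest", _as_float(self.p_honest))
        validate_design(self)


def validate_design(design: Union[SSCDesign, FRDesign]):
    """Check a design's invariants, returning it unchanged if they hold.

    Raises
    ------
    DesignError
        Naming the offending field.
    """
    if isinstance(design, SSCDesign):
        if design.m < 1:
            raise DesignError(f"m: must be >= 1, got {design.m}")
        if len(design.probs) != design.m:
            raise DesignError(
                f"probs: expected {design.m} probabilities, got {len(design.probs)}"
            )
        for i, p in enumerate(design.probs):
            if not (0.0 < p < 1.0):
                raise DesignError(f"probs[{i}]: must be strictly in (0, 1), got {p}")
        return design
    if isinstance(design, FRDesign):
        for name in ("p_forced_yes", "p_forced_no"):
            v = getattr(design, name)
            if not (0.0 <= v < 1.0):
                raise DesignError(f"{name}: must be in [0, 1), got {v}")
        if not (0.0 < design.p_honest <= 1.0):
            raise DesignError(
                f"p_honest: must be in (0, 1], got {design.p_honest}"
            )
        total = design.p_forced_yes + design.p_forced_no + design.p_honest
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise DesignError(
                f"p_forced_yes + p_forced_no + p_honest: must sum to 1, got {total}"
            )
        return design
    raise DesignError(f"unsupported design type {type(design).__name__}")


#: The two-dice device: total 2-4 forces 'yes' (6/36), 11-12 forces 'no'
#: (3/36), 5-10 (27/36) requires an honest answer.
DICE_FR_DESIGN = FRDesign(p_forced_yes=1 / 6, p_forced_no=1 / 12, p_honest=3 / 4)

#: Empirical affirmative probabilities of the four baseline questions
#: (birthday in first half of year, even house number, even last phone
#: digit, mother's birthday in second half of year), estimated from large
#: UK population registers.
MEPHEDRONE_BASELINE_PROBS: Tuple[float, ...] = (
    0.4990159,
    0.49646115,
    0.4973197,
    0.5009841,
)


def design_to_dict(design: Union[SSCDesign, FRDesign]) -> dict:
    """Serialise a design to a plain mapping (JSON/YAML friendly)."""
    if isinstance(design, SSCDesign):
        return {"model": "ssc", "m": design.m, "probs": list(design.probs)}
    if isinstance(design, FRDesign):
        return {
            "model": "fr",
            "pi_forced_yes": design.p_forced_yes,
            "pi_forced_no": design.p_forced_no,
            "pi_honest": design.p_honest,
        }
    raise DesignError(f"unsupported design type {type(design).__name__}")


def design_from_dict(data: Mapping) -> Union[SSCDesign, FRDesign]:
    """Inverse of :func:`design_to_dict`; also accepts ``probs: "equal"``."""
    model = str(data.get("model", "")).lower()
    if model == "ssc" or (not model and "m" in data):
        m = int(data["m"])
        probs = data.get("probs", "equal")
        if isinstance(probs, str):
            if probs != "equal":
                raise DesignError(f"probs: unknown shorthand {probs!r}")
            return SSCDesign.equal(m=m)
        return SSCDesign(m=m, probs=tuple(_as_float(p) for p in probs))
    if model == "fr" or (not model and "pi_honest" in data):
        return FRDesign(
            p_forced_yes=data.get("pi_forced_yes", 0.0),
            p_forced_no=data.get("pi_forced_no", 0.0),
            p_honest=data["pi_honest"],
        )
    raise DesignError("model: expected 'ssc' or 'fr'")


class SSCResponseSet:
    """Observed SSC data: one reported total per respondent.

    ``sum_yes`` is the total affirmative count λ across the sample; the
    estimators only consume ``(n, sum_yes)`` but the full vector is kept
    for the benchmark t-test and distribution checks.
    """

    __slots__ = ("totals", "m")

    def __init__(self, totals: Iterable[int], m: Optional[int] = None):
        arr = np.asarray(list(totals) if not isinstance(totals, np.ndarray) else totals)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=_TOL):
                raise DesignError("totals: reported totals must be integers")
            arr = rounded.astype(np.int64)
        arr = arr.astype(np.int64, copy=True)
        if arr.size and arr.min() < 0:
            raise DesignError(f"totals: negative total {int(arr.min())}")
        if m is not None:
            m = int(m)
            if arr.size and arr.max() > m + 1:
                raise DesignError(
                    f"totals: total {int(arr.max())} exceeds m+1 = {m + 1}"
                )
        arr.setflags(write=False)
        self.totals = arr
        self.m = m

    @classmethod
    def from_counts(cls, counts: Mapping[int, int], m: Optional[int] = None) -> "SSCResponseSet":
        """Build from aggregate ``{category: count}`` data."""
        totals = np.repeat(
            np.fromiter(counts.keys(), dtype=np.int64),
            np.fromiter(counts.values(), dtype=np.int64),
        )
        return cls(totals, m=m)

    @property
    def n(self) -> int:
        return int(self.totals.size)

    @property
    def sum_yes(self) -> int:
        """Total affirmative count λ over the whole sample."""
        return int(self.totals.sum())

    def category_counts(self, m: Optional[int] = None) -> np.ndarray:
        """Counts per answer category ``0..m+1``."""
        m = self.m if m is None else m
        if m is None:
            m = int(self.totals.max()) if self.n else 0
        return np.bincount(self.totals, minlength=m + 2)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return f"SSCResponseSet(n={self.n}, sum_yes={self.sum_yes}, m={self.m})"


class FRResponseSet:
    """Observed FR data: a yes count out of ``n`` respondents."""

    __slots__ = ("n_yes", "n")

    def __init__(self, n_yes: int, n: int):
        n_yes, n = int(n_yes), int(n)
        if n < 0:
            raise DesignError(f"n: must be >= 0, got {n}")
        if not (0 <= n_yes <= n):
            raise DesignError(f"n_yes: must be in [0, n={n}], got {n_yes}")
        self.n_yes = n_yes
        self.n = n

    @property
    def lambda_hat(self) -> float:
        """Observed 'yes' proportion."""
        if self.n == 0:
            raise DesignError("n: empty response set has no proportion")
        return self.n_yes / self.n

    def __repr__(self) -> str:
        return f"FRResponseSet(n_yes={self.n_yes}, n={self.n})"


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence point estimate with its normal-approximation interval.

    ``d_raw`` may legitimately fall outside [0, 1] when sampling noise
    exceeds the signal (a negative estimate means the observed count fell
    below the benchmark); ``d_truncated`` and ``ci_truncated`` are the
    presentation-friendly clipped versions. Downstream computation should
    always use the raw fields.
    """

    d_raw: float
    se: float
    ci_raw: Tuple[float, float]
    method: str
    n: int
    alpha: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci_raw
        if not (lo <= self.d_raw <= hi):
            raise ValueError("ci_raw must bracket d_raw")

    @property
    def d_truncated(self) -> float:
        return _clip01(self.d_raw)

    @property
    def ci_truncated(self) -> Tuple[float, float]:
        lo, hi = self.ci_raw
        return (_clip01(lo), _clip01(hi))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "alpha": self.alpha,
            "d_raw": self.d_raw,
            "d_truncated": self.d_truncated,
            "se": self.se,
            "ci_raw": list(self.ci_raw),
            "ci_truncated": list(self.ci_truncated),
            "diagnostics": dict(self.diagnostics),
        }
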