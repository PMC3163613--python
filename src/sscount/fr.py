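"""Forced Response prevalence estimation.

With forced-yes probability π₁ and honest-answer probability π₂, the
expected observed 'yes' proportion is λ = π₁ + π₂·d, inverted as

    d̂ = (λ̂ − π₁) / π₂,   Var(d̂) = λ̂(1 − λ̂) / (n·π₂²).

The forced-no probability completes the simplex but does not enter the
estimator (a forced 'no' and an honest 'no' are indistinguishable and
both excluded from λ̂).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .designs import DesignError, FRDesign, FRResponseSet, PrevalenceEstimate

__all__ = ["estimate_fr"]


def estimate_fr(
    responses: FRResponseSet,
    design: FRDesign,
    alpha: float = 0.05,
) -> PrevalenceEstimate:
    """Prevalence estimate with Wald interval for a Forced Response survey.

    Examples
    --------
    >>> est = estimate_fr(FRResponseSet(n_yes=74, n=318),
    ...                   FRDesign(1/6, 1/12, 3/4))
    >>> round(100 * est.d_raw, 2)
    8.81
    """
    if responses.n == 0:
        raise DesignError("n: response set is empty")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha: must be in (0, 1), got {alpha}")
    if design.p_honest <= 0.0:
        raise DesignError("p_honest: estimator undefined when nobody answers honestly")

    lam = responses.lambda_hat
    d_raw = (lam - design.p_forced_yes) / design.p_honest
    se = float(np.sqrt(lam * (1.0 - lam) / responses.n) / design.p_honest)
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = z * se
    diagnostics = {
        "lambda_hat": lam,
        "negative_estimate": d_raw < 0.0,
        "z": z,
    }
    return PrevalenceEstimate(
        d_raw=float(d_raw),
        se=se,
        ci_raw=(float(d_raw - half), float(d_raw + half)),
        method="forced_response",
        n=responses.n,
        alpha=alpha,
        diagnostics=diagnostics,
    )
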