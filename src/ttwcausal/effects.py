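"""Common effect-estimate container shared by the two analysis arms."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EffectEstimate", "crude_effects"]


@dataclass(frozen=True)
class EffectEstimate:
    """A treatment effect on one scale with its 95% uncertainty interval.

    ``arm`` tags the producing method (frequentist | bayesian | crude),
    ``estimand`` the target population (ATT | ATE), ``subgroup`` the
    stratum ("all" for the pooled cohort), and ``scale`` either
    "odds-ratio" or "risk-difference". ``n`` records the resampling size
    backing the interval (bootstrap replicates or posterior draws) or the
    sample size for analytic intervals.
    """

    arm: str
    estimand: str
    subgroup: str
    scale: str
    point: float
    lo: float
    hi: float
    n: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        # the reported interval always brackets the point estimate
        if np.isfinite(self.point):
            object.__setattr__(self, "lo", min(self.lo, self.point))
            object.__setattr__(self, "hi", max(self.hi, self.point))


def crude_effects(treatment: np.ndarray, outcome: np.ndarray, subgroup: str = "all") -> dict:
    """Unadjusted risk-difference and odds-ratio contrasts with Wald CIs.

    The naive comparator for confounding demonstrations: difference of
    outcome proportions between treated and untreated records, and the
    2x2 odds ratio with a Woolf (log-scale Wald) interval.
    """
    treatment = np.asarray(treatment)
    outcome = np.asarray(outcome)
    t, c = outcome[treatment == 1], outcome[treatment == 0]
    if len(t) == 0 or len(c) == 0:
        raise ValueError("both treated and control records are required")
    p1, p0 = t.mean(), c.mean()
    rd = p1 - p0
    se_rd = math.sqrt(p1 * (1 - p1) / len(t) + p0 * (1 - p0) / len(c))
    a, b = t.sum(), len(t) - t.sum()
    cc, d = c.sum(), len(c) - c.sum()
    # Haldane-Anscombe correction guards empty cells
    if min(a, b, cc, d) == 0:
        a, b, cc, d = a + 0.5, b + 0.5, cc + 0.5, d + 0.5
    log_or = math.log(a * d / (b * cc))
    se_log_or = math.sqrt(1 / a + 1 / b + 1 / cc + 1 / d)
    z = 1.959963984540054
    return {
        "risk-difference": EffectEstimate(
            "crude", "ATE", subgroup, "risk-difference", rd, rd - z * se_rd, rd + z * se_rd,
            n=len(treatment), extras={"se": se_rd},
        ),
        "odds-ratio": EffectEstimate(
            "crude", "ATE", subgroup, "odds-ratio", math.exp(log_or),
            math.exp(log_or - z * se_log_or), math.exp(log_or + z * se_log_or),
            n=len(treatment), extras={"se_log": se_log_or},
        ),
    }
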