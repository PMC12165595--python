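"""Exact binomial interval for the cohort correctness claim.

With all 900 spectra classified correctly the point estimate is 100%,
but the informative quantity is the exact (Clopper-Pearson) lower 95%
confidence bound on the probability of correct identification, which
for x = n successes has the closed form (alpha/2)^(1/n) -- 99.6% at
n = 900. The bound assumes independent observations; repeated spectra
from the same organ are not independent, so any report rendering it
must carry that caveat (see pipeline.CI_CAVEAT).
"""

from __future__ import annotations

import dataclasses

from scipy.stats import beta

__all__ = ["BinomialOutcome", "clopper_pearson_lower"]


@dataclasses.dataclass(frozen=True)
class BinomialOutcome:
    """x successes out of n trials at two-sided error level alpha."""

    x: int
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def clopper_pearson_lower(o: BinomialOutcome) -> float:
    """Exact lower bound of the two-sided (1 - alpha) binomial interval.

    The Beta(x, n - x + 1) quantile at alpha/2; equal to
    ``(alpha/2)**(1/n)`` when x = n and 0 when x = 0.
    """
    if o.x == 0:
        return 0.0
    if o.x == o.n:
        return float((o.alpha / 2.0) ** (1.0 / o.n))
    return float(beta.ppf(o.alpha / 2.0, o.x, o.n - o.x + 1))
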