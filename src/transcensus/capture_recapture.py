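"""Two-occasion closed-population abundance estimation.

Two sequencing libraries sampled from the same transcript population play
the role of two capture occasions: n1 and n2 transcripts are "captured"
by each library and m are captured by both (the common contig fraction).
The Lincoln-Petersen estimator N-hat = n1*n2/m then estimates the total
transcript population, and observed/N-hat is the completeness of the
combined catalogue. Chapman's bias-corrected variant is available for
small samples or m = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "CaptureRecaptureEstimate",
    "estimate_abundance",
    "completeness_fraction",
]


@dataclass(frozen=True)
class CaptureRecaptureEstimate:
    n1: int
    n2: int
    m: int
    method: str
    n_hat: float
    se: float
    ci_level: float
    ci_low: float
    ci_high: float

    @property
    def n_hat_rounded(self) -> int:
        """Abundance rounded half-up to an integer (presentation value)."""
        return math.floor(self.n_hat + 0.5)

    @property
    def observed(self) -> int:
        """Distinct items seen on either occasion."""
        return self.n1 + self.n2 - self.m


def estimate_abundance(
    n1: int,
    n2: int,
    m: int,
    method: str = "lincoln_petersen",
    ci_level: float = 0.95,
) -> CaptureRecaptureEstimate:
    """Estimate abundance from two capture occasions.

    Parameters
    ----------
    n1, n2
        Items captured on occasion 1 and 2.
    m
        Items captured on both occasions; must satisfy m <= min(n1, n2),
        and m >= 1 for lincoln_petersen (use chapman when m may be 0).
    method
        "lincoln_petersen": N = n1*n2/m with
        SE = sqrt(n1*n2*(n1-m)*(n2-m)/m^3).
        "chapman": N = (n1+1)(n2+1)/(m+1) - 1 with the standard Chapman
        variance (n1+1)(n2+1)(n1-m)(n2-m)/((m+1)^2 (m+2)).
    ci_level
        Normal-approximation confidence level; the lower bound is truncated
        at the number of distinct observed items n1 + n2 - m.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must both be >= 1")
    if m < 0 or m > min(n1, n2):
        raise ValueError(f"m={m} must satisfy 0 <= m <= min(n1, n2) = {min(n1, n2)}")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")

    if method == "lincoln_petersen":
        if m == 0:
            raise ValueError(
                "m = 0: Lincoln-Petersen is undefined; use method='chapman'"
            )
        n_hat = n1 * n2 / m
        var = n1 * n2 * (n1 - m) * (n2 - m) / m**3
    elif method == "chapman":
        n_hat = (n1 + 1) * (n2 + 1) / (m + 1) - 1
        var = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    else:
        raise ValueError(f"unknown method {method!r}")

    se = math.sqrt(var)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    observed = n1 + n2 - m
    ci_low = max(n_hat - z * se, float(observed))
    ci_high = n_hat + z * se
    return CaptureRecaptureEstimate(
        n1=n1, n2=n2, m=m, method=method,
        n_hat=n_hat, se=se,
        ci_level=ci_level, ci_low=ci_low, ci_high=ci_high,
    )


def completeness_fraction(observed: int, estimate: CaptureRecaptureEstimate | float) -> float:
    """Observed distinct transcripts over the estimated total.

    ``estimate`` may be a CaptureRecaptureEstimate or any positive total
    (e.g. a saturation-curve asymptote — the same ratio serves both).
    """
    if observed < 1:
        raise ValueError("observed must be >= 1")
    total = estimate.n_hat if isinstance(estimate, CaptureRecaptureEstimate) else float(estimate)
    if total <= 0:
        raise ValueError("estimated total must be positive")
    return observed / total
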