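"""Significance tests for comparing the hinge and shear sets.

The proportion comparisons (axes outside the protein, missing effective
hinge axes, twisting movements) use the standard pooled two-proportion
one-sided z-test: with sample proportions p1 = s1/n1 and p2 = s2/n2 and
pooled proportion p = (s1+s2)/(n1+n2),

    z = (p1 - p2) / sqrt(p (1-p) (1/n1 + 1/n2)),
    p_one_sided = P(Z >= z) = 1 - Phi(z),

testing whether group 1's proportion exceeds group 2's. A Welch-style
two-sample z comparison of means is provided as a convenience for
summary statistics given only as mean/SD/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from scipy.stats import norm

__all__ = ["ProportionComparison", "two_proportion_z", "welch_two_sample_z"]


@dataclass(frozen=True)
class ProportionComparison:
    """Result of a pooled one-sided two-proportion z-test."""

    successes_1: int
    n_1: int
    successes_2: int
    n_2: int
    z: float
    p_one_sided: float

    @property
    def proportion_1(self) -> float:
        return self.successes_1 / self.n_1

    @property
    def proportion_2(self) -> float:
        return self.successes_2 / self.n_2

    @property
    def p_one_sided_percent(self) -> float:
        return 100.0 * self.p_one_sided

    def report_line(self, label: str = "") -> str:
        return (
            f"{label}\t{self.successes_1}\t{self.n_1}\t{self.successes_2}"
            f"\t{self.n_2}\t{self.z:.4f}\t{self.p_one_sided_percent:.4g}"
        )


def two_proportion_z(
    successes_1: int, n_1: int, successes_2: int, n_2: int
) -> ProportionComparison:
    """Pooled one-sided two-proportion z-test (H1: p1 > p2)."""
    if n_1 <= 0 or n_2 <= 0:
        raise ValueError("sample sizes must be positive")
    for s, n in ((successes_1, n_1), (successes_2, n_2)):
        if not 0 <= s <= n:
            raise ValueError("successes must lie in [0, n]")
    p1 = successes_1 / n_1
    p2 = successes_2 / n_2
    pooled = (successes_1 + successes_2) / (n_1 + n_2)
    var = pooled * (1.0 - pooled) * (1.0 / n_1 + 1.0 / n_2)
    if var <= 0.0:
        raise ValueError(
            "pooled variance is zero (all or no successes overall); z undefined"
        )
    z = (p1 - p2) / sqrt(var)
    return ProportionComparison(
        successes_1=successes_1,
        n_1=n_1,
        successes_2=successes_2,
        n_2=n_2,
        z=float(z),
        p_one_sided=float(norm.sf(z)),
    )


def welch_two_sample_z(
    mean_1: float, sd_1: float, n_1: int, mean_2: float, sd_2: float, n_2: int
) -> tuple[float, float]:
    """Unpooled z comparison of two means from summary statistics.

    Returns (z, one-sided p for H1: mean_1 > mean_2). A convenience for
    mean/SD summaries; not used in any acceptance claim.
    """
    if n_1 <= 1 or n_2 <= 1:
        raise ValueError("sample sizes must exceed 1")
    se = sqrt(sd_1**2 / n_1 + sd_2**2 / n_2)
    if se == 0:
        raise ValueError("zero standard error; z undefined")
    z = (mean_1 - mean_2) / se
    return float(z), float(norm.sf(z))
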