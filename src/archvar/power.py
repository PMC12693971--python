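"""Rare-variant association power under the additive 1-df chi-square model.

For a biallelic variant with minor allele frequency f tested against a
standardized quantitative trait in N individuals, the score/Wald
statistic under an additive per-allele effect of beta SD is
asymptotically noncentral chi-square with 1 df and noncentrality

    lambda = 2 f (1 - f) N beta^2

(2f(1-f)N being the variance of the genotype dosage summed over the
sample).  Power at two-sided level alpha is the upper-tail mass of that
noncentral distribution beyond the central chi-square (1-alpha)
quantile.  The exact noncentral tail is used; a normal approximation is
available for cross-checks.  ``detectable_beta`` inverts power -> beta.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats


def bonferroni(alpha_family: float, m: int) -> tuple[float, str]:
    """Per-test significance level alpha_family / m.

    Returns the full-precision value used in computation alongside a
    4-decimal display form.
    """
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValueError("family-wise alpha must lie in (0, 1)")
    alpha = alpha_family / m
    return alpha, f"{alpha:.4f}"


def _validate(f: float, n: int, alpha: float) -> None:
    if not 0 < f <= 0.5:
        raise ValueError("minor allele frequency f must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("sample count N must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")


def noncentrality(f: float, n: int, beta: float) -> float:
    """lambda = 2 f (1-f) N beta^2."""
    return 2.0 * f * (1.0 - f) * n * beta * beta


def power_additive(
    f: float, n: int, beta: float, alpha: float, approx: str = "exact"
) -> float:
    """Power of the two-sided 1-df test at per-test level alpha.

    ``approx="exact"`` uses the noncentral chi-square tail;
    ``approx="normal"`` the two-sided normal-shift approximation
    Phi(sqrt(lambda) - z) + Phi(-sqrt(lambda) - z) (identical in exact
    arithmetic for 1 df; kept as an independent formulation).
    """
    _validate(f, n, alpha)
    lam = noncentrality(f, n, beta)
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    if approx == "exact":
        return float(stats.ncx2.sf(crit, df=1, nc=lam))
    if approx == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        root = lam ** 0.5
        return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))
    raise ValueError(f"unknown approx {approx!r}")


def detectable_beta(
    f: float,
    n: int,
    alpha: float,
    target_power: float = 0.8,
    rtol: float = 1e-9,
    max_growth: int = 64,
) -> float:
    """Smallest beta > 0 with power_additive(...) = target_power.

    Power is strictly increasing in |beta|, so the root is unique; the
    bracket [0, hi] is grown geometrically from hi = 1 until it
    straddles the target, then solved to relative tolerance ``rtol``.
    """
    _validate(f, n, alpha)
    if not alpha < target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    hi = 1.0
    for _ in range(max_growth):
        if power_additive(f, n, hi, alpha) >= target_power:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket detectable beta")
    return float(
        optimize.brentq(
            lambda b: power_additive(f, n, b, alpha) - target_power,
            0.0, hi, rtol=rtol, xtol=1e-15,
        )
    )


@dataclass(frozen=True)
class PowerModel:
    """(f, N, alpha, beta) quadruple with derived lambda and power."""

    f: float
    n: int
    alpha: float
    beta: float

    @property
    def noncentrality(self) -> float:
        return noncentrality(self.f, self.n, self.beta)

    @property
    def power(self) -> float:
        return power_additive(self.f, self.n, self.beta, self.alpha)

    @classmethod
    def at_power(
        cls, f: float, n: int, alpha: float, target_power: float = 0.8
    ) -> "PowerModel":
        return cls(f=f, n=n, alpha=alpha,
                   beta=detectable_beta(f, n, alpha, target_power))
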