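"""Sample-size and power calculation for negative-binomial count comparisons.

For detecting a fold-change Delta between two groups at sequencing depth
(average coverage) mu and between-group coefficient of variation sigma, the
per-group sample size achieving power 1 - beta at two-sided level alpha is

    n = 2 * (z_{1-alpha/2} + z_beta)^2 * (1/mu + sigma^2) / (ln Delta)^2

(Hart et al.'s formula for RNA-seq experiments). 1/mu is the Poisson
counting-noise term, sigma^2 the overdispersion term; deeper sequencing
only ever buys down the first. The denominator is the squared natural log
of the fold-change; two alternative readings of the fold-change term are
exposed via ``denominator`` for comparison but are not the default because
they do not correspond to the source formulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

_DENOMINATORS = ("sq_log", "log_sq", "sq_log_sq")


@dataclass
class PowerSpec:
    """alpha: two-sided false-positive rate; power: 1 - beta; mu: average
    coverage (reads per feature); sigma: CV of counts across groups;
    delta: fold-change to detect."""

    alpha: float = 0.05
    power: float = 0.9
    mu: float = 10.0
    sigma: float = 0.23
    delta: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if self.mu <= 0 or self.sigma <= 0 or self.delta <= 0:
            raise ValueError("mu, sigma and delta must be positive")
        if self.delta == 1.0:
            raise ValueError("delta = 1 means no effect: sample size diverges")


def _denominator(delta: float, form: str) -> float:
    if form == "sq_log":        # (ln Delta)^2 — the default
        return math.log(delta) ** 2
    if form == "log_sq":        # ln(Delta^2)
        return math.log(delta ** 2)
    if form == "sq_log_sq":     # (ln Delta^2)^2
        return math.log(delta ** 2) ** 2
    raise ValueError(f"denominator must be one of {_DENOMINATORS}")


def sample_size(spec: PowerSpec,
                denominator: str = "sq_log") -> tuple[float, int]:
    """Per-group sample size: (exact real value, ceiling integer)."""
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    n_exact = (2.0 * (z_a + z_b) ** 2 * (1.0 / spec.mu + spec.sigma ** 2)
               / _denominator(spec.delta, denominator))
    return float(n_exact), int(math.ceil(n_exact))


def power_given_n(n: float, alpha: float = 0.05, mu: float = 10.0,
                  sigma: float = 0.23, delta: float = 2.0,
                  denominator: str = "sq_log") -> float:
    """Achieved power at per-group size n (the formula solved for z_beta)."""
    if n < 2:
        raise ValueError("need n >= 2 per group")
    if delta == 1.0:
        raise ValueError("delta = 1 means no effect")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = math.sqrt(n * _denominator(delta, denominator)
                    / (2.0 * (1.0 / mu + sigma ** 2))) - z_a
    if z_b <= -8.0:
        warnings.warn("parameters imply essentially zero power", stacklevel=2)
        return 0.0
    return float(stats.norm.cdf(z_b))


def sample_size_range(powers=(0.7, 0.8, 0.9), alpha: float = 0.05,
                      mu: float = 10.0, sigma: float = 0.23,
                      delta: float = 2.0) -> dict[float, int]:
    """Required per-group n (ceiling) for each requested power level."""
    return {
        p: sample_size(PowerSpec(alpha=alpha, power=p, mu=mu, sigma=sigma,
                                 delta=delta))[1]
        for p in powers
    }
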