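"""Trial-enrichment sample-size calculation.

Two-arm randomized trial with a binary progression endpoint: the control
arm progresses with probability ``p_control`` and the treatment arm with
``p_control * (1 - rrr)`` (relative risk reduction).  The required sample
size uses the standard pooled-variance two-proportion z-test formula

    n/arm = (z_{1-a/2} * sqrt(2*pbar*qbar)
             + z_{1-b} * sqrt(p1*q1 + p2*q2))^2 / (p1 - p2)^2

with per-arm ceiling before doubling.  Enriching enrolment with predicted
progressors raises the control-arm event rate and shrinks the required N;
``enrichment_gain`` reports both sizes and their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
from scipy.stats import norm

__all__ = ["PowerCalcConfig", "required_sample_size", "enrichment_gain",
           "simulated_power"]


@dataclass
class PowerCalcConfig:
    p_control: float = 0.5
    rrr: float = 0.10
    alpha: float = 0.05   # two-sided
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.p_control < 1:
            raise ValueError("p_control must be in (0,1)")
        if not 0 < self.rrr < 1:
            raise ValueError("rrr must be in (0,1); rrr=0 gives infinite n")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0,1)")

    @property
    def p_treat(self) -> float:
        return self.p_control * (1 - self.rrr)


def required_sample_size(cfg: PowerCalcConfig) -> int:
    """Total N over both arms (1:1 allocation), per-arm ceiling."""
    p1, p2 = cfg.p_control, cfg.p_treat
    pbar = (p1 + p2) / 2
    z_a = norm.ppf(1 - cfg.alpha / 2)
    z_b = norm.ppf(cfg.power)
    num = (z_a * sqrt(2 * pbar * (1 - pbar))
           + z_b * sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    n_per_arm = num / (p1 - p2) ** 2
    return 2 * ceil(n_per_arm)


def enrichment_gain(cfg: PowerCalcConfig, enriched_p_control: float
                    ) -> tuple[int, int, float]:
    """(N_unenriched, N_enriched, ratio) for raising the control-arm
    progression probability to ``enriched_p_control`` at the same relative
    risk reduction."""
    if enriched_p_control <= cfg.p_control:
        raise ValueError("enriched prevalence must exceed the baseline")
    n0 = required_sample_size(cfg)
    enriched = PowerCalcConfig(p_control=enriched_p_control, rrr=cfg.rrr,
                               alpha=cfg.alpha, power=cfg.power)
    n1 = required_sample_size(enriched)
    return n0, n1, n1 / n0


def simulated_power(cfg: PowerCalcConfig, total_n: int, n_trials: int = 100_000,
                    seed: int = 0) -> float:
    """Monte-Carlo power of the pooled two-proportion z-test at a given
    total N (vectorized simulation oracle for the closed form)."""
    rng = np.random.default_rng(seed)
    n = total_n // 2
    x1 = rng.binomial(n, cfg.p_control, n_trials)
    x2 = rng.binomial(n, cfg.p_treat, n_trials)
    p1, p2 = x1 / n, x2 / n
    pbar = (x1 + x2) / (2 * n)
    se = np.sqrt(2 * pbar * (1 - pbar) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    crit = norm.ppf(1 - cfg.alpha / 2)
    return float((np.abs(z) > crit).mean())
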