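"""Screening-design calculus and binomial power for sensitivity comparisons.

Two-stage screening arithmetic
------------------------------
A screening programme in an asymptomatic population tolerates at most a
certain number of screen-indicated surgeries per cancer detected, which fixes
a target positive predictive value (PPV).  With disease prevalence ``pi`` and
target PPV ``ppv`` (and assuming high sensitivity), the screening cascade
must enrich prevalence by ``ppv / pi``-fold.  If a second-stage triage test
(transvaginal ultrasound) contributes a further ``k``-fold reduction of
first-stage false positives, the blood test itself must enrich by
``ppv / (pi * k)``-fold, i.e. operate at false-positive rate
``pi * k / ppv`` — with the study's numbers (prevalence 1/2500, PPV 20%,
10-fold triage) a 2% FPR, hence the 98% specificity at which all sensitivity
comparisons are made.

Power
-----
One-sided power to rule out a null sensitivity ``p0`` when the true
sensitivity is ``p1``, from ``n`` validated cases, via the normal
approximation without continuity correction (null variance sets the critical
value, alternative variance the power):

    power = Phi( (n (p1 - p0) - z_{1-a} sqrt(n p0 (1-p0))) / sqrt(n p1 (1-p1)) )

An exact binomial version (smallest critical count with null tail <= alpha)
is provided as cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import beta, binom, norm

__all__ = [
    "ScreeningDesign",
    "PowerSpec",
    "PowerResult",
    "screening_design",
    "sensitivity_power",
    "retrospective_power",
    "exact_binomial_ci",
]


@dataclass(frozen=True)
class ScreeningDesign:
    prevalence: float
    target_ppv: float
    second_stage_factor: float
    required_total_enrichment: float
    required_first_stage_enrichment: float
    required_fpr: float
    implied_specificity: float


def screening_design(
    prevalence: float, target_ppv: float, second_stage_factor: float = 10.0
) -> ScreeningDesign:
    """PPV -> enrichment -> first-stage FPR -> implied blood-test specificity.

    Assumes near-perfect sensitivity when converting enrichment to a
    false-positive rate, as the verbal screening argument does.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0.0 < target_ppv < 1.0:
        raise ValueError("target_ppv must lie in (0, 1)")
    if second_stage_factor < 1.0:
        raise ValueError("second_stage_factor must be >= 1")
    total = target_ppv / prevalence
    first = total / second_stage_factor
    if first < 1.0:
        warnings.warn(
            "required enrichment below 1: the target PPV is reached without "
            "any first-stage test discrimination",
            stacklevel=2,
        )
    fpr = 1.0 / first
    return ScreeningDesign(
        prevalence=prevalence,
        target_ppv=target_ppv,
        second_stage_factor=second_stage_factor,
        required_total_enrichment=total,
        required_first_stage_enrichment=first,
        required_fpr=fpr,
        implied_specificity=1.0 - fpr,
    )


@dataclass(frozen=True)
class PowerSpec:
    n: int
    p0: float
    p1: float
    alpha: float = 0.05
    method: str = "normal_approximation"  # or "exact_binomial"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("p0", "p1", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.method not in ("normal_approximation", "exact_binomial"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class PowerResult:
    power: float
    critical_value: float
    spec: PowerSpec


def sensitivity_power(spec: PowerSpec) -> PowerResult:
    """One-sided power to detect sensitivity p1 against the null p0."""
    n, p0, p1, a = spec.n, spec.p0, spec.p1, spec.alpha
    if spec.method == "normal_approximation":
        z = norm.ppf(1.0 - a)
        crit = n * p0 + z * (n * p0 * (1.0 - p0)) ** 0.5
        num = n * (p1 - p0) - z * (n * p0 * (1.0 - p0)) ** 0.5
        den = (n * p1 * (1.0 - p1)) ** 0.5
        power = float(norm.cdf(num / den))
        return PowerResult(power=power, critical_value=float(crit), spec=spec)
    # exact binomial: smallest integer c with P(X >= c | n, p0) <= alpha
    candidates = np.arange(0, n + 2)
    tail = binom.sf(candidates - 1, n, p0)  # P(X >= c)
    c = int(candidates[tail <= a][0])
    power = float(binom.sf(c - 1, n, p1))
    return PowerResult(power=power, critical_value=float(c), spec=spec)


def retrospective_power(
    n: int, p0: float, observed_p1: float, alpha: float = 0.05,
    method: str = "normal_approximation",
) -> PowerResult:
    """Power the study had, in retrospect, at the observed sensitivity."""
    return sensitivity_power(
        PowerSpec(n=n, p0=p0, p1=observed_p1, alpha=alpha, method=method)
    )


def exact_binomial_ci(
    n_positive: int, n_total: int, level: float = 0.95
) -> Tuple[float, float]:
    """Clopper-Pearson (exact binomial) confidence interval for a proportion."""
    if not 0 <= n_positive <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_positive <= n_total, n_total >= 1")
    a = 1.0 - level
    lo = 0.0 if n_positive == 0 else float(
        beta.ppf(a / 2, n_positive, n_total - n_positive + 1)
    )
    hi = 1.0 if n_positive == n_total else float(
        beta.ppf(1 - a / 2, n_positive + 1, n_total - n_positive)
    )
    return lo, hi
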