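"""Synthetic multi-site serum-biomarker cohort generation.

The real discovery cohort behind this package — pooled EDRN sera assayed for
CA125, HE4, HE4 antigen-autoantibody complexes, osteopontin and a panel of
autoantibodies — is not publicly deposited, so every downstream stage
(cutoffs, panel classifiers, permutation inference) is exercised on
simulated cohorts that reproduce the statistical structure the analysis
assumes:

* log-normal marginal concentration distributions (the analysis works on
  log-scale means, and serum concentrations are positive and right-skewed);
* per-group location shifts on the log scale, calibrated so a marker hits a
  target sensitivity at a target specificity;
* optional pairwise correlation between markers via a Gaussian copula on
  the log scale;
* optional *complementarity*: a marker whose elevation is concentrated in
  the cases that a partner marker (e.g. CA125) misses.

Group labels follow the study design: ``healthy`` and ``benign`` controls,
``early`` (stage I-II) and ``late`` (stage III-IV) cases, accrued at two
sites (``mdacc``, ``fhcc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GROUP_LABELS",
    "CASE_GROUPS",
    "CONTROL_GROUPS",
    "EDRN_GROUP_COUNTS",
    "ConfigurationError",
    "GroupSpec",
    "MarkerSpec",
    "generate_cohort",
    "calibrate_shift",
    "edrn_groups",
]

#: Canonical group labels, in reporting order.
GROUP_LABELS: Tuple[str, ...] = ("healthy", "benign", "early", "late")
CASE_GROUPS: Tuple[str, ...] = ("early", "late")
CONTROL_GROUPS: Tuple[str, ...] = ("healthy", "benign")

#: Group x site composition of the pooled discovery serum set:
#: 64 early-stage and 186 late-stage cases, 200 benign pelvic masses and
#: 502 healthy controls accrued at MD Anderson (mdacc) and Fred Hutchinson
#: (fhcc).
EDRN_GROUP_COUNTS: Mapping[str, Mapping[str, int]] = {
    "early": {"mdacc": 21, "fhcc": 43},
    "late": {"mdacc": 107, "fhcc": 79},
    "benign": {"mdacc": 56, "fhcc": 144},
    "healthy": {"mdacc": 131, "fhcc": 371},
}


class ConfigurationError(ValueError):
    """A cohort/marker specification is internally inconsistent."""


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sample counts, broken down by accrual site."""

    group_label: str
    site_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for site, n in self.site_counts.items():
            if int(n) != n or n < 0:
                raise ConfigurationError(
                    f"group {self.group_label!r}: count for site {site!r} "
                    f"must be a non-negative integer, got {n!r}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.site_counts.values()))


@dataclass(frozen=True)
class MarkerSpec:
    """Distributional assumptions for one marker, on the natural-log scale.

    Parameters
    ----------
    name:
        Marker column name (e.g. ``"CA125"``).
    log_mean_by_group, log_sd_by_group:
        Mean and standard deviation of log-concentration per group.  Groups
        not listed fall back to the ``reference_group`` entry.
    correlation_partner:
        Optional ``(partner_name, rho)``; the marker's latent Gaussian is
        correlated with the partner's via a pairwise Gaussian copula.  The
        partner must appear earlier in the marker list.
    complement_target:
        Optional partner marker name: the group shift of this marker is
        applied only to the half of each elevated group whose value of the
        target marker lies below that group's median — samples the target
        tends to miss.  The other half reverts to the reference-group
        marginal.  This reproduces "elevated preferentially in
        CA125-negative cases" without joint-distribution bookkeeping.
    reference_group:
        The group whose marginal defines "not elevated" (default
        ``"healthy"``).
    """

    name: str
    log_mean_by_group: Mapping[str, float]
    log_sd_by_group: Mapping[str, float]
    correlation_partner: Optional[Tuple[str, float]] = None
    complement_target: Optional[str] = None
    reference_group: str = "healthy"

    def __post_init__(self) -> None:
        for g, sd in self.log_sd_by_group.items():
            if not sd > 0:
                raise ConfigurationError(
                    f"marker {self.name!r}: log_sd for group {g!r} must be "
                    f"positive, got {sd!r}"
                )
        if self.correlation_partner is not None:
            partner, rho = self.correlation_partner
            if not -1.0 <= rho <= 1.0:
                raise ValueError(
                    f"marker {self.name!r}: correlation rho must lie in "
                    f"[-1, 1], got {rho!r}"
                )

    def log_mean(self, group: str) -> float:
        if group in self.log_mean_by_group:
            return float(self.log_mean_by_group[group])
        return float(self.log_mean_by_group[self.reference_group])

    def log_sd(self, group: str) -> float:
        if group in self.log_sd_by_group:
            return float(self.log_sd_by_group[group])
        return float(self.log_sd_by_group[self.reference_group])


def edrn_groups() -> list[GroupSpec]:
    """GroupSpecs matching the pooled discovery set (952 samples)."""
    return [
        GroupSpec(g, dict(EDRN_GROUP_COUNTS[g]))
        for g in ("early", "late", "benign", "healthy")
    ]


def calibrate_shift(
    target_sensitivity: float,
    target_specificity: float,
    log_sd: float = 1.0,
) -> float:
    """Log-scale case shift delta achieving a target sensitivity.

    Under equal-sd Gaussian log-concentrations, the cutoff placed at the
    ``target_specificity`` quantile of the control distribution yields
    case sensitivity ``target_sensitivity`` when the case mean is shifted by

        delta = log_sd * (z_spec + z_sens)

    with ``z_q`` the standard-normal quantile at ``q``.
    """
    for name, v in (
        ("target_sensitivity", target_sensitivity),
        ("target_specificity", target_specificity),
    ):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v!r}")
    if not log_sd > 0:
        raise ValueError(f"log_sd must be positive, got {log_sd!r}")
    return float(
        log_sd * (norm.ppf(target_specificity) + norm.ppf(target_sensitivity))
    )


def _validate(groups: Sequence[GroupSpec], markers: Sequence[MarkerSpec]) -> None:
    if not groups or not markers:
        raise ConfigurationError("need at least one group and one marker")
    labels = {g.group_label for g in groups}
    if len(labels) != len(groups):
        raise ConfigurationError("duplicate group labels")
    seen: set[str] = set()
    for m in markers:
        unknown = (set(m.log_mean_by_group) | set(m.log_sd_by_group)) - labels
        if unknown:
            raise ConfigurationError(
                f"marker {m.name!r} references unknown group(s) {sorted(unknown)}"
            )
        if m.reference_group not in m.log_mean_by_group:
            raise ConfigurationError(
                f"marker {m.name!r}: reference group {m.reference_group!r} "
                "has no log_mean entry"
            )
        for dep_desc, dep in (
            ("correlation partner", m.correlation_partner and m.correlation_partner[0]),
            ("complement target", m.complement_target),
        ):
            if dep is not None and dep not in seen:
                raise ConfigurationError(
                    f"marker {m.name!r}: {dep_desc} {dep!r} must be declared "
                    "earlier in the marker list"
                )
        seen.add(m.name)


def generate_cohort(
    groups: Sequence[GroupSpec],
    markers: Sequence[MarkerSpec],
    seed: int,
) -> pd.DataFrame:
    """Simulate a cohort table: one row per sample, one column per marker.

    Returns a DataFrame with columns ``sample_id, group, site,
    <marker...>``.  Regeneration with identical arguments and seed is
    bit-identical.
    """
    _validate(groups, markers)

    group_col: list[str] = []
    site_col: list[str] = []
    for g in groups:
        for site, n in g.site_counts.items():
            group_col.extend([g.group_label] * int(n))
            site_col.extend([str(site)] * int(n))
    n_total = len(group_col)
    if n_total == 0:
        raise ConfigurationError("all group counts are zero")

    group_arr = np.asarray(group_col)
    rng = np.random.default_rng(seed)
    # One block of independent latent normals, drawn up-front so that the
    # realisation of marker k does not depend on the parameters of markers
    # j != k (only on their latent draws, via copula/gating).
    latent = rng.standard_normal((n_total, len(markers)))

    z_by_marker: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    for j, m in enumerate(markers):
        z = latent[:, j]
        if m.correlation_partner is not None:
            partner, rho = m.correlation_partner
            z = rho * z_by_marker[partner] + np.sqrt(1.0 - rho**2) * z
        z_by_marker[m.name] = z

        mu = np.array([m.log_mean(g) for g in group_col])
        sd = np.array([m.log_sd(g) for g in group_col])
        if m.complement_target is not None:
            target_vals = values[m.complement_target]
            mu_ref = m.log_mean(m.reference_group)
            sd_ref = m.log_sd(m.reference_group)
            for g in {gr.group_label for gr in groups}:
                mask = group_arr == g
                if not mask.any() or m.log_mean(g) <= mu_ref:
                    continue
                med = np.median(target_vals[mask])
                # the target-high half reverts to the reference marginal
                revert = mask & (target_vals >= med)
                mu[revert] = mu_ref
                sd[revert] = sd_ref
        values[m.name] = np.exp(mu + sd * z)

    table = pd.DataFrame(
        {
            "sample_id": [f"s{i:05d}" for i in range(n_total)],
            "group": group_col,
            "site": site_col,
            **values,
        }
    )
    return table
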