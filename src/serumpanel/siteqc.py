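"""Accrual-site comparability checks.

When a cohort pools sera from two accrual sites, per-group differences in
marker level between sites would confound any case/control contrast.  The
check here is deliberately simple: within each clinical group, a Welch
(unequal-variance) two-sample t-test compares mean log-concentration
between sites.  It is a QC screen, not an adjustment — no multiple-testing
correction and no batch correction is applied.

The natural log is used; the base cancels in the t statistic, so the choice
is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = ["SiteTestResult", "site_mean_test", "site_comparison_table"]


@dataclass(frozen=True)
class SiteTestResult:
    marker: str
    group: str
    site_a: str
    site_b: str
    n_a: int
    n_b: int
    mean_log_a: float
    mean_log_b: float
    t_statistic: float
    p_value: float


def _site_values(
    cohort: pd.DataFrame, marker: str, group: str, sites: Optional[Tuple[str, str]]
):
    if marker not in cohort.columns:
        raise KeyError(f"marker {marker!r} not in cohort")
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"no samples in group {group!r}")
    if sites is None:
        present = sorted(sub["site"].unique())
        if len(present) != 2:
            raise ValueError(
                f"group {group!r} has {len(present)} site(s); pass `sites` "
                "explicitly to choose two"
            )
        sites = (present[0], present[1])
    out = []
    for site in sites:
        vals = sub.loc[sub["site"] == site, marker].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(
                f"site {site!r} has fewer than 2 samples in group {group!r}"
            )
        if np.any(vals <= 0):
            raise ValueError(
                f"non-positive concentration for marker {marker!r} at site "
                f"{site!r}; log undefined"
            )
        out.append(np.log(vals))
    return sites, out[0], out[1]


def site_mean_test(
    cohort: pd.DataFrame,
    marker: str,
    group: str,
    sites: Optional[Tuple[str, str]] = None,
) -> SiteTestResult:
    """Welch t-test of log-concentration means between two sites, one group."""
    (site_a, site_b), log_a, log_b = _site_values(cohort, marker, group, sites)
    t, p = ttest_ind(log_a, log_b, equal_var=False)
    return SiteTestResult(
        marker=marker,
        group=group,
        site_a=site_a,
        site_b=site_b,
        n_a=log_a.size,
        n_b=log_b.size,
        mean_log_a=float(log_a.mean()),
        mean_log_b=float(log_b.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


def site_comparison_table(
    cohort: pd.DataFrame,
    markers: Optional[Sequence[str]] = None,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One Welch-test row per (marker, group) with two usable sites."""
    if markers is None:
        markers = [
            c for c in cohort.columns
            if c not in ("sample_id", "group", "site", "split")
        ]
    if groups is None:
        groups = list(pd.unique(cohort["group"]))
    rows = []
    for marker in markers:
        for group in groups:
            try:
                res = site_mean_test(cohort, marker, group)
            except ValueError:
                continue  # group absent, single-site, or too small
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
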