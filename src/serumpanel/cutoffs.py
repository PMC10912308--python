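"""Marker positivity rules, dichotomization and sensitivity tables.

Three ways to declare a sample "positive" for a marker, all with strict
``value > threshold`` semantics (a value exactly at the threshold is
negative, matching clinical usage such as ">35 U/ml" for CA125):

* an empirical fixed-specificity cutoff estimated from control values
  (the study convention: 98% specificity among healthy controls, 95%
  among benign controls);
* the seropositivity convention for autoantibody assays: control mean
  plus two standard deviations;
* an externally given clinical threshold.

On top of the rules: dichotomization of a cohort, per-group sensitivity
tables (benign / early / late / all cases), complementarity counts
(candidate-marker positivity among reference-negative cases) and the
OR-rule panel combination (positive if any member marker is positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CASE_GROUPS

__all__ = [
    "CutoffRule",
    "DichotomizedPanel",
    "FixedSpecificityCutoff",
    "MeanPlusTwoSDCutoff",
    "specificity_cutoff",
    "mean_plus_2sd_cutoff",
    "clinical_rule",
    "dichotomize",
    "sensitivity_by_group",
    "complement_detection",
    "or_rule_panel",
    "threshold_at_specificity",
]

REPORT_GROUPS = ("benign", "early", "late", "all_cases")


@dataclass(frozen=True)
class CutoffRule:
    """A positivity rule for one marker: positive iff value > threshold."""

    marker: str
    threshold: float
    method: str  # empirical_specificity | mean_plus_2sd | clinical
    direction: str = "greater"
    target_specificity: Optional[float] = None
    achieved_specificity: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold!r}")
        if self.direction != "greater":
            raise ValueError("only direction='greater' is supported")

    def is_positive(self, values) -> np.ndarray:
        """0/1 calls for an array of marker values."""
        return (np.asarray(values, dtype=float) > self.threshold).astype(int)


def threshold_at_specificity(
    control_values, target_specificity: float
) -> tuple[float, float]:
    """Smallest observed control value whose strict exceedance fraction
    keeps specificity at or above the target.

    Returns ``(threshold, achieved_specificity)``.  The threshold is always
    one of the observed control values, so the achieved specificity is exact
    and auditable on the defining set; it is ``>= target`` by construction.
    """
    v = np.asarray(control_values, dtype=float)
    if v.size == 0:
        raise ValueError("control values must be non-empty")
    if not np.all(np.isfinite(v)):
        raise ValueError("control values must all be finite")
    if not 0.0 < target_specificity < 1.0:
        raise ValueError(
            f"target_specificity must lie in (0, 1), got {target_specificity!r}"
        )
    v_sorted = np.sort(v)
    n = v.size
    max_fpr = 1.0 - target_specificity
    # candidate c = v_sorted[i]; #(values > c) = n - searchsorted(right)
    # scan ascending, first candidate meeting the constraint is the smallest
    exceed = n - np.searchsorted(v_sorted, v_sorted, side="right")
    ok = exceed / n <= max_fpr
    i = int(np.argmax(ok))  # guaranteed: the maximum has exceedance 0
    threshold = float(v_sorted[i])
    achieved = 1.0 - exceed[i] / n
    return threshold, float(achieved)


class FixedSpecificityCutoff(BaseEstimator):
    """Empirical fixed-specificity cutoff, as a fit/predict estimator.

    ``fit(control_values)`` chooses the smallest observed control value
    such that the fraction of controls strictly above it does not exceed
    ``1 - target_specificity``; ``predict(values)`` returns 0/1 calls.

    Fitted attributes: ``threshold_``, ``achieved_specificity_``, ``rule_``.
    """

    def __init__(self, target_specificity: float = 0.98, marker: str = ""):
        self.target_specificity = target_specificity
        self.marker = marker

    def fit(self, X, y=None) -> "FixedSpecificityCutoff":
        x = np.asarray(X, dtype=float).ravel()
        self.threshold_, self.achieved_specificity_ = threshold_at_specificity(
            x, self.target_specificity
        )
        self.n_controls_ = x.size
        self.rule_ = CutoffRule(
            marker=self.marker,
            threshold=self.threshold_,
            method="empirical_specificity",
            target_specificity=float(self.target_specificity),
            achieved_specificity=self.achieved_specificity_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.rule_.is_positive(np.asarray(X, dtype=float).ravel())


class MeanPlusTwoSDCutoff(BaseEstimator):
    """Seropositivity cutoff at control mean + 2 sample standard deviations."""

    def __init__(self, marker: str = ""):
        self.marker = marker

    def fit(self, X, y=None) -> "MeanPlusTwoSDCutoff":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 2:
            raise ValueError(
                "mean + 2 SD cutoff needs at least 2 control values "
                "(sample sd undefined)"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("control values must all be finite")
        self.threshold_ = float(x.mean() + 2.0 * x.std(ddof=1))
        self.rule_ = CutoffRule(
            marker=self.marker, threshold=self.threshold_, method="mean_plus_2sd"
        )
        return self

    def predict(self, X) -> np.ndarray:
        return self.rule_.is_positive(np.asarray(X, dtype=float).ravel())


def specificity_cutoff(
    control_values, target_specificity: float, marker: str = ""
) -> CutoffRule:
    """Fixed-specificity rule from control values (see FixedSpecificityCutoff)."""
    return FixedSpecificityCutoff(target_specificity, marker).fit(control_values).rule_


def mean_plus_2sd_cutoff(control_values, marker: str = "") -> CutoffRule:
    """Control mean + 2 SD seropositivity rule (sample sd, n-1 denominator)."""
    return MeanPlusTwoSDCutoff(marker).fit(control_values).rule_


def clinical_rule(marker: str, threshold: float) -> CutoffRule:
    """Externally fixed clinical threshold (e.g. CA125 > 35 U/ml, HE4 > 70 pmol/L)."""
    return CutoffRule(marker=marker, threshold=float(threshold), method="clinical")


@dataclass
class DichotomizedPanel:
    """0/1 positivity calls per sample with the rules that produced them."""

    calls: pd.DataFrame  # columns: sample_id + one 0/1 column per rule
    rules: dict  # call-column name -> CutoffRule

    @property
    def columns(self) -> list[str]:
        return [c for c in self.calls.columns if c != "sample_id"]


def dichotomize(cohort: pd.DataFrame, rules: Sequence[CutoffRule]) -> DichotomizedPanel:
    """Apply positivity rules to a cohort; one 0/1 column per rule.

    Two rules on the same marker get method-suffixed column names.  Row
    order follows the cohort.
    """
    calls = pd.DataFrame({"sample_id": cohort["sample_id"].to_numpy()})
    provenance: dict[str, CutoffRule] = {}
    marker_counts: dict[str, int] = {}
    for rule in rules:
        if rule.marker not in cohort.columns:
            raise KeyError(
                f"cutoff rule refers to marker {rule.marker!r}, "
                "which is not a cohort column"
            )
        marker_counts[rule.marker] = marker_counts.get(rule.marker, 0) + 1
    seen: dict[str, int] = {}
    for rule in rules:
        name = rule.marker
        if marker_counts[rule.marker] > 1:
            name = f"{rule.marker}_{rule.method}"
            if name in provenance:  # same marker, same method, twice
                seen[name] = seen.get(name, 1) + 1
                name = f"{name}_{seen[name]}"
        calls[name] = rule.is_positive(cohort[rule.marker].to_numpy())
        provenance[name] = rule
    return DichotomizedPanel(calls=calls, rules=provenance)


def _aligned(panel: DichotomizedPanel, cohort: pd.DataFrame) -> pd.DataFrame:
    if not np.array_equal(
        panel.calls["sample_id"].to_numpy(), cohort["sample_id"].to_numpy()
    ):
        raise ValueError("panel and cohort do not align on sample_id")
    out = panel.calls.copy()
    out["group"] = cohort["group"].to_numpy()
    return out


def sensitivity_by_group(
    panel: DichotomizedPanel,
    cohort: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    calls_override: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Positivity counts and sensitivity per call column and case group.

    Rows: one per (column, group) for benign, early, late and all_cases
    (= early + late).  Healthy controls never enter the case rows.
    Sensitivity is NaN when the group is empty.
    """
    merged = _aligned(panel, cohort)
    if columns is None:
        columns = panel.columns
    rows = []
    for col in columns:
        if col not in merged.columns:
            raise KeyError(f"call column {col!r} not present in panel")
        for grp in REPORT_GROUPS:
            if grp == "all_cases":
                sel = merged["group"].isin(CASE_GROUPS)
            else:
                sel = merged["group"] == grp
            n_total = int(sel.sum())
            n_pos = int(merged.loc[sel, col].sum())
            rows.append(
                {
                    "name": col,
                    "group": grp,
                    "n_positive": n_pos,
                    "n_total": n_total,
                    "sensitivity": (n_pos / n_total) if n_total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


class ComplementResult(NamedTuple):
    n_reference_negative: int
    n_candidate_positive: int
    fraction: float  # NaN when no reference-negative samples


def complement_detection(
    panel: DichotomizedPanel,
    cohort: pd.DataFrame,
    reference: str,
    candidate: str,
    group: str = "early",
) -> ComplementResult:
    """Candidate-marker positivity among group cases missed by the reference.

    E.g. the fraction of early-stage cases with normal CA125 that are
    nonetheless positive for OPN.
    """
    merged = _aligned(panel, cohort)
    for col in (reference, candidate):
        if col not in merged.columns:
            raise KeyError(f"call column {col!r} not present in panel")
    known = set(cohort["group"].unique()) | set(REPORT_GROUPS)
    if group not in known:
        raise ValueError(f"unknown group {group!r}")
    if group == "all_cases":
        sel = merged["group"].isin(CASE_GROUPS)
    else:
        sel = merged["group"] == group
    neg = merged[sel & (merged[reference] == 0)]
    n_ref_neg = len(neg)
    n_cand_pos = int(neg[candidate].sum()) if n_ref_neg else 0
    frac = (n_cand_pos / n_ref_neg) if n_ref_neg else float("nan")
    return ComplementResult(n_ref_neg, n_cand_pos, frac)


class OrRuleResult(NamedTuple):
    calls: pd.Series  # combined 0/1 calls, indexed like the cohort rows
    report: pd.DataFrame  # sensitivity_by_group rows for the combination
    specificity: float  # 1 - positive fraction among the control group


def or_rule_panel(
    panel: DichotomizedPanel,
    columns: Sequence[str],
    cohort: pd.DataFrame,
    control_group: str = "healthy",
    name: str = "or_rule",
) -> OrRuleResult:
    """OR-rule combination: positive if any member marker is positive."""
    if not columns:
        raise ValueError("or_rule_panel needs at least one call column")
    merged = _aligned(panel, cohort)
    for col in columns:
        if col not in merged.columns:
            raise KeyError(f"call column {col!r} not present in panel")
    combined = merged[list(columns)].max(axis=1).astype(int)
    controls = combined[merged["group"] == control_group]
    if len(controls) == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    specificity = 1.0 - float(controls.mean())
    aug = DichotomizedPanel(
        calls=pd.DataFrame(
            {"sample_id": merged["sample_id"].to_numpy(), name: combined.to_numpy()}
        ),
        rules={name: None},
    )
    report = sensitivity_by_group(aug, cohort, columns=[name])
    calls = pd.Series(combined.to_numpy(), index=cohort.index, name=name)
    return OrRuleResult(calls, report, specificity)
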