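"""Re-split/re-train permutation test for sensitivity comparisons.

The test treats the *entire* evaluation procedure as the statistic: for each
permutation the case/control labels are shuffled over the combined cohort,
the shuffled cohort is randomly re-split 50:50, forests are re-trained on the
permuted training half, and the sensitivity statistic is recomputed on the
permuted validation half.  The p-value is the (add-one) upper tail of the
observed statistic within the null draws:

    p = (1 + #{null >= observed}) / (1 + B)

which is never exactly zero and is exact under exchangeability.  The
statistic is either the panel-minus-baseline difference in validation
sensitivity at fixed specificity (default) or the panel's raw sensitivity;
the test is one-sided for an improvement.

Any statistic with the ``(cohort, split) -> float`` signature can be
injected in place of the forest pipeline, which keeps exhaustive
small-instance oracles and calibration studies cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    ForestSpec,
    SingleClassError,
    sensitivity_at_specificity,
    split_cohort,
    train_forest,
    with_split,
)
from .cohort import CASE_GROUPS

__all__ = ["PermutationSpec", "PermutationResult", "observed_statistic", "permutation_test"]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class PermutationSpec:
    """Configuration of one permutation test run."""

    panel: tuple
    baseline: Optional[tuple] = None
    statistic: str = "sensitivity_difference"  # or "sensitivity"
    specificity: float = 0.98
    fraction: float = 0.5
    b: int = 500
    seed: int = 0
    case_groups: tuple = CASE_GROUPS
    control_group: str = "healthy"
    group: Optional[str] = None  # restrict sensitivity to one case group
    n_trees: int = 2000
    threshold_on: str = "validation"

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("number of permutations B must be >= 1")
        if self.statistic not in ("sensitivity_difference", "sensitivity"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.statistic == "sensitivity_difference" and self.baseline is None:
            raise ValueError("sensitivity_difference requires a baseline panel")
        if not 0.0 < self.specificity < 1.0:
            raise ValueError("specificity must lie in (0, 1)")


@dataclass
class PermutationResult:
    observed_statistic: float
    null_draws: np.ndarray
    p_value: float
    spec: PermutationSpec
    n_redrawn: int = 0

    def summary(self) -> dict:
        q = np.quantile(self.null_draws, [0.0, 0.25, 0.5, 0.75, 0.95, 1.0])
        return {
            "observed_statistic": self.observed_statistic,
            "p_value": self.p_value,
            "b": int(self.spec.b),
            "seed": int(self.spec.seed),
            "statistic": self.spec.statistic,
            "specificity": self.spec.specificity,
            "n_redrawn": self.n_redrawn,
            "null_quantiles": {
                "min": q[0], "q25": q[1], "median": q[2],
                "q75": q[3], "q95": q[4], "max": q[5],
            },
        }


def _panel_sensitivity(
    cohort: pd.DataFrame,
    split: pd.Series,
    features: Sequence[str],
    spec: PermutationSpec,
) -> float:
    model = train_forest(
        cohort,
        split,
        ForestSpec(
            n_trees=spec.n_trees, seed=spec.seed, feature_columns=tuple(features)
        ),
        spec.case_groups,
        (spec.control_group,),
    )
    sub = with_split(cohort, split)
    val = sub[
        sub["group"].isin(tuple(spec.case_groups) + (spec.control_group,))
        & (sub["split"] == "validation")
    ]
    scores = model.vote_scores(val)
    is_control = (val["group"] == spec.control_group).to_numpy()
    if spec.group is None:
        is_case = val["group"].isin(spec.case_groups).to_numpy()
    else:
        is_case = (val["group"] == spec.group).to_numpy()
    # threshold on the evaluated (or training) controls, cases from the
    # requested group only
    if spec.threshold_on == "train":
        train = sub[
            (sub["group"] == spec.control_group) & (sub["split"] == "train")
        ]
        control_scores = model.vote_scores(train)
    else:
        control_scores = scores[is_control]
    from .cutoffs import threshold_at_specificity

    thr, _ = threshold_at_specificity(control_scores, spec.specificity)
    case_scores = scores[is_case]
    if case_scores.size == 0:
        raise SingleClassError("no validation cases for the requested group")
    return float((case_scores > thr).mean())


def observed_statistic(
    cohort: pd.DataFrame, split: pd.Series, spec: PermutationSpec
) -> float:
    """Panel validation sensitivity (minus the baseline's, by default)."""
    value = _panel_sensitivity(cohort, split, spec.panel, spec)
    if spec.statistic == "sensitivity_difference":
        value -= _panel_sensitivity(cohort, split, spec.baseline, spec)
    return value


def permutation_test(
    cohort: pd.DataFrame,
    spec: PermutationSpec,
    statistic_fn: Optional[Callable[[pd.DataFrame, pd.Series], float]] = None,
) -> PermutationResult:
    """Re-permute, re-split, re-train, re-evaluate; return the add-one p.

    Labels are permuted over the rows belonging to the case groups plus the
    designated control group; other groups are excluded from the run (the
    comparisons are pairwise: cases vs healthy, or cases vs benign).  The
    permutation shuffles the full group-label vector, preserving group sizes
    while destroying any label/marker association.  Per-permutation seeds
    derive deterministically from the master seed.  Permutations whose
    stratified re-split leaves a single class in training are redrawn (with
    a logged count).
    """
    if statistic_fn is None:
        statistic_fn = lambda c, s: observed_statistic(c, s, spec)  # noqa: E731

    keep = cohort["group"].isin(tuple(spec.case_groups) + (spec.control_group,))
    sub = cohort[keep].reset_index(drop=True)
    if sub["group"].nunique() < 2:
        raise SingleClassError("cohort must contain both cases and controls")

    master = np.random.default_rng(spec.seed)
    seeds = master.integers(0, 2**31 - 1, size=spec.b + 1)

    obs_split = split_cohort(sub, spec.fraction, seed=int(seeds[0]), strata=("group",))
    observed = float(statistic_fn(sub, obs_split))

    labels = sub["group"].to_numpy()
    null = np.empty(spec.b)
    n_redrawn = 0
    for b in range(spec.b):
        rng_b = np.random.default_rng(int(seeds[b + 1]))
        for _attempt in range(_MAX_REDRAWS):
            perm = sub.copy()
            perm["group"] = rng_b.permutation(labels)
            split_b = split_cohort(
                perm,
                spec.fraction,
                seed=int(rng_b.integers(0, 2**31 - 1)),
                strata=("group",),
            )
            try:
                null[b] = statistic_fn(perm, split_b)
                break
            except SingleClassError:
                n_redrawn += 1
        else:  # pragma: no cover - pathological configurations only
            raise RuntimeError(
                "could not draw a non-degenerate permutation after "
                f"{_MAX_REDRAWS} attempts"
            )
    if n_redrawn:
        logger.info("permutation test: %d degenerate permutations redrawn", n_redrawn)

    p = (1.0 + float((null >= observed).sum())) / (1.0 + spec.b)
    return PermutationResult(
        observed_statistic=observed,
        null_draws=null,
        p_value=p,
        spec=spec,
        n_redrawn=n_redrawn,
    )
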