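"""Train/validation splitting, random-forest panel scoring and evaluation.

The study design this reproduces: the pooled cohort is split 50:50 (stratified
by group) into a training and an independent validation set; a random forest
with 2,000 trees is trained on the training set to separate cases from a
designated control group; sensitivity at a fixed high specificity (98% against
healthy controls, 95% against benign masses) is then estimated by applying the
model to the validation set, with the score threshold chosen on the evaluated
controls by the same smallest-value-meeting-the-constraint rule used for raw
marker cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import CASE_GROUPS
from .cutoffs import threshold_at_specificity

__all__ = [
    "SingleClassError",
    "ForestSpec",
    "PanelForest",
    "split_cohort",
    "with_split",
    "train_forest",
    "score_cohort",
    "sensitivity_at_specificity",
    "SensSpecResult",
    "roc_curve",
    "ROCCurve",
    "evaluate_panels",
]


class SingleClassError(ValueError):
    """Training (or evaluation) data contain only one class."""


def split_cohort(
    cohort: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    strata: Sequence[str] = ("group",),
) -> pd.Series:
    """Random stratified train/validation assignment.

    Within every stratum (by default the group label), ``round(fraction*n)``
    samples go to training and the rest to validation, so per-stratum counts
    are within one sample of ``fraction * n``.  Deterministic under ``seed``.

    Returns a Series mapping ``sample_id`` to ``"train"``/``"validation"``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction!r}")
    for col in strata:
        if col not in cohort.columns:
            raise KeyError(f"stratum column {col!r} not in cohort")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("cohort sample_id values must be unique")

    rng = np.random.default_rng(seed)
    assignment = pd.Series(
        index=pd.Index(cohort["sample_id"], name="sample_id"),
        dtype=object,
        name="split",
    )
    keys = cohort[list(strata)].apply(tuple, axis=1)
    for key in sorted(keys.unique()):
        ids = cohort.loc[keys == key, "sample_id"].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(fraction * len(ids) + 0.5))
        assignment.loc[ids[perm[:n_train]]] = "train"
        assignment.loc[ids[perm[n_train:]]] = "validation"
    return assignment


def with_split(cohort: pd.DataFrame, split: pd.Series) -> pd.DataFrame:
    """Return a copy of the cohort with a ``split`` column attached."""
    out = cohort.copy()
    out["split"] = out["sample_id"].map(split)
    if out["split"].isna().any():
        raise ValueError("split assignment does not cover every cohort sample")
    return out


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest configuration: bagged trees, majority-vote probability."""

    n_trees: int = 2000
    seed: int = 0
    feature_columns: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class PanelForest(BaseEstimator, ClassifierMixin):
    """Random-forest panel scorer (sklearn-compatible).

    ``fit(X, y)`` trains a forest of ``n_trees`` fully grown trees on the
    marker columns; ``vote_scores(X)`` returns the fraction of trees voting
    "case" — a score in [0, 1] used for sensitivity-at-specificity and ROC
    reporting.  Deterministic under ``seed``.
    """

    def __init__(
        self,
        feature_columns: Optional[Sequence[str]] = None,
        n_trees: int = 2000,
        seed: int = 0,
    ):
        self.feature_columns = feature_columns
        self.n_trees = n_trees
        self.seed = seed

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = list(self.feature_columns or X.columns)
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise KeyError(f"feature column(s) {missing} not in data")
            return X[cols].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y) -> "PanelForest":
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size < 2:
            raise SingleClassError(
                "training data contain a single class; need both cases and controls"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=int(self.n_trees), random_state=int(self.seed), n_jobs=1
        )
        self.forest_.fit(self._matrix(X), y)
        self.classes_ = self.forest_.classes_
        return self

    def vote_scores(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive (case) class."""
        mat = self._matrix(X)
        votes = np.zeros(mat.shape[0])
        for tree in self.forest_.estimators_:
            votes += (tree.predict(mat) == 1)
        return votes / len(self.forest_.estimators_)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.vote_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.vote_scores(X) > 0.5).astype(int)


def _rows(
    cohort: pd.DataFrame,
    split: pd.Series,
    which: str,
    case_groups: Sequence[str],
    control_groups: Sequence[str],
) -> pd.DataFrame:
    sub = with_split(cohort, split)
    keep = sub["group"].isin(tuple(case_groups) + tuple(control_groups))
    return sub[keep & (sub["split"] == which)]


def train_forest(
    cohort: pd.DataFrame,
    split: pd.Series,
    spec: ForestSpec,
    case_groups: Sequence[str] = CASE_GROUPS,
    control_groups: Sequence[str] = ("healthy",),
) -> PanelForest:
    """Fit a PanelForest on the training rows of the cohort."""
    train = _rows(cohort, split, "train", case_groups, control_groups)
    features = list(spec.feature_columns or [])
    if not features:
        raise ValueError("ForestSpec.feature_columns must name at least one marker")
    y = train["group"].isin(case_groups).to_numpy().astype(int)
    model = PanelForest(
        feature_columns=features, n_trees=spec.n_trees, seed=spec.seed
    )
    model.fit(train, y)
    return model


def score_cohort(model: PanelForest, cohort: pd.DataFrame) -> pd.Series:
    """Vote-fraction scores for every cohort row, indexed by sample_id."""
    return pd.Series(
        model.vote_scores(cohort),
        index=pd.Index(cohort["sample_id"], name="sample_id"),
        name="score",
    )


class SensSpecResult(NamedTuple):
    sensitivity: float
    threshold: float
    n_positive: int
    n_cases: int
    achieved_specificity: float


def sensitivity_at_specificity(
    scores, labels, specificity: float
) -> SensSpecResult:
    """Case sensitivity at a fixed specificity on the evaluated controls.

    The score threshold is the smallest control score whose strict
    exceedance fraction keeps specificity at or above the target (the same
    rule as the raw-marker cutoff); a case is positive iff its score is
    strictly above the threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not y.any() or y.all():
        raise SingleClassError("need at least one case and one control score")
    thr, achieved = threshold_at_specificity(s[~y], specificity)
    case_scores = s[y]
    n_pos = int((case_scores > thr).sum())
    return SensSpecResult(
        sensitivity=n_pos / case_scores.size,
        threshold=thr,
        n_positive=n_pos,
        n_cases=int(case_scores.size),
        achieved_specificity=achieved,
    )


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve: monotone (fpr, tpr) path from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve over all distinct score thresholds, with AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise SingleClassError("need both classes for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:  # pragma: no cover - sklearn guarantees
        fpr = np.append(fpr, 1.0)
        tpr = np.append(tpr, 1.0)
        thr = np.append(thr, -np.inf)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(roc_auc_score(y, s)))


def _normalize_panels(panels) -> dict[str, list[str]]:
    if isinstance(panels, dict):
        out = {str(k): list(v) for k, v in panels.items()}
    else:
        out = {"+".join(p): list(p) for p in panels}
    if not out:
        raise ValueError("need at least one panel")
    for name, feats in out.items():
        if not feats:
            raise ValueError(f"panel {name!r} has no features")
    return out


def evaluate_panels(
    cohort: pd.DataFrame,
    split: pd.Series,
    panels,
    case_groups: Sequence[str] = CASE_GROUPS,
    control_groups: Sequence[str] = ("healthy",),
    specificity: float = 0.98,
    baseline: Optional[str] = None,
    n_trees: int = 2000,
    seed: int = 0,
    threshold_on: str = "validation",
) -> pd.DataFrame:
    """Validation sensitivity of each panel at fixed specificity, with deltas.

    Each panel is a feature set; a forest is trained per panel on the
    training rows and applied to the validation rows.  Sensitivity is
    reported overall (all cases) and per case group, together with the
    change relative to the baseline panel (default: the first), mirroring
    the "panel vs CA125 alone" comparison tables.

    ``threshold_on`` selects which controls fix the score threshold:
    ``"validation"`` (default, the evaluated set) or ``"train"``.
    """
    panel_map = _normalize_panels(panels)
    for name, feats in panel_map.items():
        missing = [f for f in feats if f not in cohort.columns]
        if missing:
            raise KeyError(f"panel {name!r}: feature(s) {missing} not in cohort")
    if baseline is None:
        baseline = next(iter(panel_map))
    if baseline not in panel_map:
        raise KeyError(f"baseline panel {baseline!r} not among the panels")
    if threshold_on not in ("validation", "train"):
        raise ValueError("threshold_on must be 'validation' or 'train'")

    val = _rows(cohort, split, "validation", case_groups, control_groups)
    thr_rows = (
        val
        if threshold_on == "validation"
        else _rows(cohort, split, "train", case_groups, control_groups)
    )
    is_case_val = val["group"].isin(case_groups).to_numpy()
    records = []
    sens_lookup: dict[tuple[str, str], float] = {}
    for name, feats in panel_map.items():
        model = train_forest(
            cohort,
            split,
            ForestSpec(n_trees=n_trees, seed=seed, feature_columns=tuple(feats)),
            case_groups,
            control_groups,
        )
        val_scores = model.vote_scores(val)
        thr_controls = model.vote_scores(
            thr_rows[~thr_rows["group"].isin(case_groups)]
        )
        thr, achieved = threshold_at_specificity(thr_controls, specificity)
        group_sets = [("all_cases", is_case_val)] + [
            (g, (val["group"] == g).to_numpy()) for g in case_groups
        ]
        for gname, mask in group_sets:
            n_total = int(mask.sum())
            n_pos = int((val_scores[mask] > thr).sum())
            sens = (n_pos / n_total) if n_total else float("nan")
            sens_lookup[(name, gname)] = sens
            records.append(
                {
                    "panel": name,
                    "features": ",".join(feats),
                    "group": gname,
                    "n_positive": n_pos,
                    "n_total": n_total,
                    "sensitivity": sens,
                    "threshold": thr,
                    "achieved_specificity": achieved,
                }
            )
    report = pd.DataFrame(records)
    report["delta_vs_baseline"] = [
        r["sensitivity"] - sens_lookup[(baseline, r["group"])]
        for r in records
    ]
    report.attrs["baseline"] = baseline
    report.attrs["specificity"] = specificity
    return report
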