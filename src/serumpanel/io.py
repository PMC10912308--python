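"""Cohort CSV input/output, rule serialization and packaged fixtures.

The single interchange format is a plain CSV with header
``sample_id,group,site,<marker...>[,split]`` — serum immunoassay panels are
small tabular data, so no binary or domain-specific container is used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import (
    GROUP_LABELS,
    GroupSpec,
    MarkerSpec,
    calibrate_shift,
    edrn_groups,
    generate_cohort,
)
from .cutoffs import CutoffRule

__all__ = [
    "read_cohort",
    "write_cohort",
    "rules_to_yaml",
    "rules_from_yaml",
    "report_to_csv",
    "make_fixture",
    "fixture_expected_sensitivity",
    "FIXTURE_PROFILES",
]

REQUIRED_COLUMNS = ("sample_id", "group", "site")
SPLIT_TOKENS = ("train", "validation", "unassigned")


class CohortFormatError(ValueError):
    """A cohort CSV violates the interchange contract."""


def read_cohort(
    path,
    groups: Sequence[str] = GROUP_LABELS,
    sites: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Unknown group tokens (and site tokens, when a site set is given) are
    rejected with the offending file line numbers; duplicate sample ids and
    non-numeric concentrations are rejected with their location.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")

    dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
    if len(dups):
        raise CohortFormatError(
            f"{path}: duplicate sample_id value(s): {', '.join(map(str, dups))}"
        )

    def _bad_lines(mask) -> str:
        # +2: one for the header line, one for 1-based numbering
        return ", ".join(str(i + 2) for i in df.index[mask][:10])

    bad = ~df["group"].isin(list(groups))
    if bad.any():
        raise CohortFormatError(
            f"{path}: unknown group token(s) "
            f"{sorted(df.loc[bad, 'group'].unique())} at line(s) {_bad_lines(bad)}"
        )
    if sites is not None:
        bad = ~df["site"].isin(list(sites))
        if bad.any():
            raise CohortFormatError(
                f"{path}: unknown site token(s) "
                f"{sorted(df.loc[bad, 'site'].unique())} at line(s) {_bad_lines(bad)}"
            )
    if "split" in df.columns:
        bad = ~df["split"].isin(SPLIT_TOKENS)
        if bad.any():
            raise CohortFormatError(
                f"{path}: invalid split token(s) at line(s) {_bad_lines(bad)}"
            )

    marker_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c != "split"
    ]
    for col in marker_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            bad = bad | df[col].isna()
            raise CohortFormatError(
                f"{path}: non-numeric or missing concentration in column "
                f"{col!r} at line(s) {_bad_lines(bad)}"
            )
        df[col] = converted.astype(float)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as the interchange CSV (lossless round-trip)."""
    cohort.to_csv(path, index=False)


def rules_to_yaml(rules: Sequence[CutoffRule], path=None) -> str:
    """Serialize cutoff rules to YAML; optionally write to ``path``."""
    payload = [
        {
            "marker": r.marker,
            "threshold": float(r.threshold),
            "direction": r.direction,
            "method": r.method,
            "target_specificity": r.target_specificity,
            "achieved_specificity": r.achieved_specificity,
        }
        for r in rules
    ]
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def rules_from_yaml(source) -> list[CutoffRule]:
    """Load cutoff rules from a YAML string or file path."""
    text = source
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    payload = yaml.safe_load(text)
    return [
        CutoffRule(
            marker=d["marker"],
            threshold=float(d["threshold"]),
            method=d["method"],
            direction=d.get("direction", "greater"),
            target_specificity=d.get("target_specificity"),
            achieved_specificity=d.get("achieved_specificity"),
        )
        for d in payload
    ]


def report_to_csv(report: pd.DataFrame, path) -> None:
    """Write a sensitivity report with percentages to one decimal place."""
    out = report.copy()
    out["sensitivity_percent"] = (100.0 * out["sensitivity"]).round(1)
    cols = ["name", "group", "n_positive", "n_total", "sensitivity_percent"]
    extra = [c for c in out.columns if c not in cols + ["sensitivity"]]
    out[cols + extra].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixture profiles
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = ("edrn_like", "null", "complementary", "tiny")

_BASE_RATE = 0.02  # unshifted tail above the true 98%-specificity cutoff
_LOG_MU0 = float(np.log(10.0))  # reference log-concentration, arbitrary units

#: Marginal sensitivity targets at 98% specificity for the study-like
#: fixture, per (early, late, benign).  CA125-like values follow the
#: single-marker table of the study; the three complementary markers are
#: elevated preferentially in CA125-low cases.
_EDRN_TARGETS: Mapping[str, tuple] = {
    "CA125": (0.625, 0.935, 0.22),
    "HE4": (0.406, 0.860, 0.02),
    "HE4_AgAAb": (0.188, 0.086, 0.03),
    "OPN": (0.125, 0.226, 0.04),
}
_GATED = ("HE4", "HE4_AgAAb", "OPN")


def _gated_shift(marginal_target: float) -> tuple[float, float]:
    """(within-gate sensitivity, implied marginal) for a median-gated marker.

    Only the half of each case group below the partner's median receives the
    shift, so the achievable marginal is at most ~0.5; the within-gate
    sensitivity is capped at 0.995 and the implied marginal recorded.
    """
    s = float(np.clip(2.0 * marginal_target - _BASE_RATE, _BASE_RATE, 0.995))
    if s <= _BASE_RATE:
        return _BASE_RATE, _BASE_RATE
    return s, 0.5 * s + 0.5 * _BASE_RATE


def _edrn_markers() -> tuple[list[MarkerSpec], dict]:
    markers: list[MarkerSpec] = []
    expected: dict[str, dict[str, float]] = {}
    for name, (t_early, t_late, t_benign) in _EDRN_TARGETS.items():
        gated = name in _GATED
        mus = {"healthy": _LOG_MU0}
        exp = {"healthy": _BASE_RATE}
        for group, t in (("early", t_early), ("late", t_late), ("benign", t_benign)):
            if gated:
                s, marginal = _gated_shift(t)
                delta = 0.0 if s <= _BASE_RATE else calibrate_shift(s, 0.98, 1.0)
            else:
                marginal = t
                delta = 0.0 if t <= _BASE_RATE else calibrate_shift(t, 0.98, 1.0)
            mus[group] = _LOG_MU0 + delta
            exp[group] = marginal
        markers.append(
            MarkerSpec(
                name=name,
                log_mean_by_group=mus,
                log_sd_by_group={"healthy": 1.0},
                complement_target="CA125" if gated else None,
            )
        )
        expected[name] = exp
    return markers, expected


def fixture_expected_sensitivity(profile: str = "edrn_like") -> dict:
    """Analytically implied per-group marginal sensitivities at 98% specificity."""
    if profile != "edrn_like":
        raise ValueError(f"expected sensitivities are defined for 'edrn_like' only")
    _, expected = _edrn_markers()
    return expected


def make_fixture(profile: str, seed: int = 0) -> pd.DataFrame:
    """Generate one of the packaged synthetic cohort profiles.

    * ``edrn_like`` — the printed 64/186/200/502 group-by-site composition
      with a CA125-like marker and three CA125-complementary markers
      calibrated to study-like sensitivities at 98% specificity;
    * ``null`` — no group effects at all (for permutation calibration);
    * ``complementary`` — marker B informative only among marker-A-low
      cases (for panel-gain tests);
    * ``tiny`` — 8 samples, both classes, for exhaustive permutation
      oracles.
    """
    if profile == "edrn_like":
        markers, _ = _edrn_markers()
        return generate_cohort(edrn_groups(), markers, seed)
    if profile == "null":
        groups = [
            GroupSpec("healthy", {"mdacc": 40, "fhcc": 60}),
            GroupSpec("benign", {"mdacc": 10, "fhcc": 10}),
            GroupSpec("early", {"mdacc": 10, "fhcc": 10}),
            GroupSpec("late", {"mdacc": 10, "fhcc": 10}),
        ]
        markers = [
            MarkerSpec(m, {"healthy": _LOG_MU0}, {"healthy": 1.0})
            for m in ("m1", "m2")
        ]
        return generate_cohort(groups, markers, seed)
    if profile == "complementary":
        groups = [
            GroupSpec("healthy", {"mdacc": 100, "fhcc": 100}),
            GroupSpec("early", {"mdacc": 25, "fhcc": 25}),
            GroupSpec("late", {"mdacc": 25, "fhcc": 25}),
        ]
        delta_b = calibrate_shift(0.90, 0.98, 1.0)
        markers = [
            MarkerSpec(
                "A",
                {
                    "healthy": _LOG_MU0,
                    "early": _LOG_MU0 + calibrate_shift(0.55, 0.98, 1.0),
                    "late": _LOG_MU0 + calibrate_shift(0.75, 0.98, 1.0),
                },
                {"healthy": 1.0},
            ),
            MarkerSpec(
                "B",
                {
                    "healthy": _LOG_MU0,
                    "early": _LOG_MU0 + delta_b,
                    "late": _LOG_MU0 + delta_b,
                },
                {"healthy": 1.0},
                complement_target="A",
            ),
        ]
        return generate_cohort(groups, markers, seed)
    if profile == "tiny":
        groups = [
            GroupSpec("healthy", {"mdacc": 2, "fhcc": 2}),
            GroupSpec("early", {"mdacc": 2, "fhcc": 2}),
        ]
        markers = [
            MarkerSpec(
                "m1",
                {"healthy": _LOG_MU0, "early": _LOG_MU0 + 2.0},
                {"healthy": 1.0},
            )
        ]
        return generate_cohort(groups, markers, seed)
    raise ValueError(
        f"unknown fixture profile {profile!r}; choose from {FIXTURE_PROFILES}"
    )
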