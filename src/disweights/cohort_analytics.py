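"""Subgroup homogeneity and cross-study comparison of weight sets.

Subgroup analysis refits the paired-comparison probit separately within
each level of a respondent attribute (same reference state throughout)
and summarises agreement between levels by the Spearman rank correlation
of the per-level coefficient vectors over the states estimated in every
level.  High correlations indicate that health-state preferences are
homogeneous across the attribute.

Two disability-weight sets are compared over their matched states by the
Spearman correlation and the Wilcoxon signed-rank test of the point
estimates, medians/IQRs, and a classification of how many set-A point
estimates fall outside set-B's 95% uncertainty interval (below the lower
bound / above the upper bound), overall and per disease category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DisabilityWeightEstimate, IntegrityError, RESPONDENT_ATTRIBUTES,
)
from .probit_engine import build_design, fit_probit

__all__ = [
    "SubgroupCorrelationMatrix",
    "ComparisonReport",
    "subgroup_correlations",
    "compare_weight_sets",
]

logger = logging.getLogger(__name__)

# Levels with fewer respondents than this are excluded from per-level fits
# (affects e.g. a sub-percent gender category, whose handful of respondents
# cannot support a 200-state probit).
DEFAULT_MIN_CELL = 30


@dataclass
class SubgroupCorrelationMatrix:
    attribute: str
    levels: list[str]
    rho: pd.DataFrame                      # symmetric, unit diagonal
    n_per_level: dict[str, int]            # responses per retained level
    n_states_used: int
    excluded_levels: list[str] = field(default_factory=list)

    def min_pairwise(self) -> float:
        off = self.rho.to_numpy()[~np.eye(len(self.levels), dtype=bool)]
        return float(off.min())


def subgroup_correlations(
    responses: pd.DataFrame,
    respondents: pd.DataFrame,
    attribute: str,
    min_cell: int = DEFAULT_MIN_CELL,
    reference_state: Optional[str] = None,
) -> SubgroupCorrelationMatrix:
    """Spearman correlations of per-level probit coefficient vectors.

    ``min_cell`` is the minimum number of respondents a level needs to be
    fitted; smaller levels are excluded with a warning.  Fewer than two
    usable levels is an error.  Coefficients are compared over the
    intersection of states estimated (connected to the shared reference)
    in every retained level.
    """
    if attribute not in RESPONDENT_ATTRIBUTES:
        raise ValueError(f"unknown respondent attribute {attribute!r}")
    joined = responses.merge(
        respondents[["respondent_id", attribute]], on="respondent_id", how="left")
    if joined[attribute].isna().any():
        missing = joined.loc[joined[attribute].isna(), "respondent_id"]
        raise IntegrityError(
            f"responses from respondents absent in the attribute table: "
            f"{sorted(set(missing))[:10]}")

    if reference_state is None:
        reference_state = pd.concat(
            [responses["first_state"], responses["second_state"]]
        ).value_counts().idxmax()

    levels, excluded = [], []
    for level in RESPONDENT_ATTRIBUTES[attribute]:
        sub = joined.loc[joined[attribute] == level]
        n_resp = sub["respondent_id"].nunique()
        if n_resp == 0:
            continue
        if n_resp < min_cell:
            excluded.append(level)
            logger.warning(
                "level %r of %r has %d respondents (< %d); excluded",
                level, attribute, n_resp, min_cell)
            continue
        levels.append(level)
    if len(levels) < 2:
        raise ValueError(
            f"need >= 2 usable levels of {attribute!r}; got {levels}")

    coeffs: dict[str, pd.Series] = {}
    n_per_level: dict[str, int] = {}
    for level in levels:
        sub = joined.loc[joined[attribute] == level]
        design = build_design(sub, reference_state=reference_state)
        fit = fit_probit(design)
        coeffs[level] = fit.coefficients
        n_per_level[level] = int(len(sub))

    common = sorted(set.intersection(*(set(c.index) for c in coeffs.values())))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} states estimated in every level; "
            "cannot correlate")
    rho = pd.DataFrame(np.eye(len(levels)), index=levels, columns=levels)
    for a_pos, a in enumerate(levels):
        for b in levels[a_pos + 1:]:
            r = stats.spearmanr(
                coeffs[a].loc[common], coeffs[b].loc[common]).statistic
            rho.loc[a, b] = rho.loc[b, a] = r
    return SubgroupCorrelationMatrix(
        attribute=attribute, levels=levels, rho=rho,
        n_per_level=n_per_level, n_states_used=len(common),
        excluded_levels=excluded,
    )


@dataclass
class ComparisonReport:
    n_matched: int
    spearman_rho: float
    spearman_p: float
    wilcoxon_p: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    n_outside: int
    n_below: int
    n_above: int
    per_category: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_matched": self.n_matched,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "wilcoxon_p": self.wilcoxon_p,
            "median_a": self.median_a,
            "iqr_a_low": self.iqr_a[0], "iqr_a_high": self.iqr_a[1],
            "median_b": self.median_b,
            "iqr_b_low": self.iqr_b[0], "iqr_b_high": self.iqr_b[1],
            "n_outside": self.n_outside,
            "n_below": self.n_below, "n_above": self.n_above,
        }])


def _as_frame(estimates: Sequence[DisabilityWeightEstimate], label: str) -> pd.DataFrame:
    ids = [e.state_id for e in estimates]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate state ids in set {label}: {dupes[:10]}")
    return pd.DataFrame({
        "state_id": ids,
        "dw": [e.dw for e in estimates],
        "ui_low": [e.ui_low for e in estimates],
        "ui_high": [e.ui_high for e in estimates],
    }).set_index("state_id")


def compare_weight_sets(
    set_a: Sequence[DisabilityWeightEstimate],
    set_b: Sequence[DisabilityWeightEstimate],
    categories: Optional[Mapping[str, str]] = None,
) -> ComparisonReport:
    """Compare two weight sets over their matched states.

    The Wilcoxon signed-rank test is two-sided with zero differences
    dropped; the exact null distribution is used for n <= 25 without ties,
    the continuity-corrected normal approximation otherwise.  The
    outside-UI classification counts set-A point estimates strictly below
    set-B's lower bound or strictly above its upper bound.
    """
    a = _as_frame(set_a, "a")
    b = _as_frame(set_b, "b")
    matched = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if len(matched) == 0:
        raise ValueError("no matched states between the two sets")
    if len(matched) < 3:
        raise ValueError(f"need >= 3 matched states; got {len(matched)}")

    sp = stats.spearmanr(matched["dw_a"], matched["dw_b"])
    diff = matched["dw_a"] - matched["dw_b"]
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        wilcoxon_p = 1.0
    else:
        has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
        method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
        wilcoxon_p = float(stats.wilcoxon(
            nonzero, alternative="two-sided", method=method,
            correction=(method == "approx")).pvalue)

    below = matched["dw_a"] < matched["ui_low_b"]
    above = matched["dw_a"] > matched["ui_high_b"]

    per_category = None
    if categories is not None:
        cat = pd.Series({s: categories.get(s, "uncategorized")
                         for s in matched.index})
        per_category = pd.DataFrame({
            "n_matched": cat.groupby(cat).size(),
            "n_below": below.groupby(cat).sum(),
            "n_above": above.groupby(cat).sum(),
        })
        per_category["n_outside"] = per_category["n_below"] + per_category["n_above"]

    q_a = matched["dw_a"].quantile([0.25, 0.5, 0.75])
    q_b = matched["dw_b"].quantile([0.25, 0.5, 0.75])
    return ComparisonReport(
        n_matched=int(len(matched)),
        spearman_rho=float(sp.statistic),
        spearman_p=float(sp.pvalue),
        wilcoxon_p=wilcoxon_p,
        median_a=float(q_a.loc[0.5]), iqr_a=(float(q_a.loc[0.25]), float(q_a.loc[0.75])),
        median_b=float(q_b.loc[0.5]), iqr_b=(float(q_b.loc[0.25]), float(q_b.loc[0.75])),
        n_outside=int((below | above).sum()),
        n_below=int(below.sum()),
        n_above=int(above.sum()),
        per_category=per_category,
    )
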