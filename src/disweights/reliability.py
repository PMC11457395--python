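"""Test-retest reliability of the deliberately repeated comparison.

The survey repeats one early pair later in the task sequence, either in
the same presentation order or reversed.  Consistency is counted on the
chosen *health state*: for same-order repeats a consistent respondent
picks the same state (same position) twice; for reverse-order repeats
picking the same state means switching the selected position.

Agreement beyond chance is summarised by Cohen's kappa against the 0.5
chance level of a binary forced choice, so kappa = 2 * p_observed - 1.
For reverse-order repeats kappa is computed on *positional* agreement —
choosing the same state counts as positional disagreement — which makes a
strongly state-consistent cohort yield a strongly negative reverse-order
kappa.  All probabilities are computed from raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .data_model import IntegrityError, RESPONDENT_ATTRIBUTES

__all__ = [
    "InsufficientDataError",
    "ReliabilityReport",
    "consistency_probability",
    "cohen_kappa",
    "kappa_band",
    "test_retest_report",
    "report_frame",
]

CHANCE_AGREEMENT = 0.5  # binary forced choice

KAPPA_BANDS = (
    (0.20, "slight or no agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.00, "almost perfect agreement"),
)


class InsufficientDataError(ValueError):
    """A requested statistic has no observations to compute from."""


@dataclass
class ReliabilityReport:
    n_same_order: int
    n_reverse_order: int
    p_consistent_same: Optional[float]
    p_same_state_reverse: Optional[float]
    kappa_same: Optional[float]
    kappa_reverse: Optional[float]
    strata: Optional[dict[str, "ReliabilityReport"]] = None

    @property
    def agreement_same(self) -> Optional[str]:
        return None if self.kappa_same is None else kappa_band(self.kappa_same)


def cohen_kappa(p_observed: float, p_expected: float = CHANCE_AGREEMENT) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e), in [-1, 1]."""
    if not (0.0 <= p_observed <= 1.0 and 0.0 <= p_expected <= 1.0):
        raise ValueError("p_observed and p_expected must lie in [0, 1]")
    if p_expected == 1.0:
        raise ZeroDivisionError("kappa undefined when chance agreement is 1")
    return (p_observed - p_expected) / (1.0 - p_expected)


def kappa_band(kappa: float) -> str:
    """Verbal agreement band for a kappa value."""
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return KAPPA_BANDS[-1][1]


def consistency_probability(
    repeat_pairs: Iterable[tuple[str, str, str]], order: str,
) -> float:
    """Fraction of repeats in which the same health state was chosen twice.

    ``repeat_pairs`` yields (original_choice_state, repeat_choice_state,
    repeat_order) triples; only those with the requested order ("same" or
    "reverse") are counted.  Raises :class:`InsufficientDataError` on an
    empty stratum rather than returning a number.
    """
    if order not in ("same", "reverse"):
        raise ValueError("order must be 'same' or 'reverse'")
    total = consistent = 0
    for original, repeat, rep_order in repeat_pairs:
        if rep_order != order:
            continue
        total += 1
        consistent += original == repeat
    if total == 0:
        raise InsufficientDataError(f"no {order}-order repeats to evaluate")
    return consistent / total


def _chosen_state(df: pd.DataFrame) -> pd.Series:
    return df["first_state"].where(df["choice"] == "first", df["second_state"])


def _match_repeats(responses: pd.DataFrame, source_task: int) -> pd.DataFrame:
    """Join each repeat response to its original, validating pair identity."""
    repeats = responses.loc[responses["is_repeat"]].copy()
    originals = responses.loc[responses["task_index"] == source_task,
                              ["respondent_id", "first_state", "second_state",
                               "choice"]].copy()
    originals.columns = ["respondent_id", "orig_first", "orig_second", "orig_choice"]
    merged = repeats.merge(originals, on="respondent_id", how="left")
    unmatched = merged["orig_first"].isna()
    pair_ok = (
        ((merged["first_state"] == merged["orig_first"])
         & (merged["second_state"] == merged["orig_second"]))
        | ((merged["first_state"] == merged["orig_second"])
           & (merged["second_state"] == merged["orig_first"]))
    )
    bad = merged.loc[unmatched | ~pair_ok, "respondent_id"]
    if len(bad):
        raise IntegrityError(
            f"repeat responses do not match their originals for respondents "
            f"{sorted(set(bad))[:10]}")
    merged["orig_chosen"] = merged["orig_first"].where(
        merged["orig_choice"] == "first", merged["orig_second"])
    merged["rep_chosen"] = _chosen_state(merged)
    return merged


def _report_from_matched(matched: pd.DataFrame) -> ReliabilityReport:
    same = matched.loc[matched["repeat_order"] == "same"]
    rev = matched.loc[matched["repeat_order"] == "reverse"]
    p_same = k_same = p_rev = k_rev = None
    if len(same):
        p_same = float((same["rep_chosen"] == same["orig_chosen"]).mean())
        k_same = cohen_kappa(p_same)
    if len(rev):
        p_rev = float((rev["rep_chosen"] == rev["orig_chosen"]).mean())
        # positional agreement: same chosen state in reverse order means
        # the selected position switched
        k_rev = cohen_kappa(1.0 - p_rev)
    return ReliabilityReport(
        n_same_order=int(len(same)), n_reverse_order=int(len(rev)),
        p_consistent_same=p_same, p_same_state_reverse=p_rev,
        kappa_same=k_same, kappa_reverse=k_rev,
    )


def test_retest_report(
    responses: pd.DataFrame,
    respondents: Optional[pd.DataFrame] = None,
    strata_attribute: Optional[str] = None,
    source_task: int = 2,
) -> ReliabilityReport:
    """Overall (and optionally stratified) test-retest report.

    ``source_task`` is the task index whose pair was deliberately repeated.
    Stratification requires the respondents table and one of its attribute
    columns; strata with no repeat observations are omitted.
    """
    matched = _match_repeats(responses, source_task)
    report = _report_from_matched(matched)
    if strata_attribute is not None:
        if respondents is None:
            raise ValueError("stratified report requires the respondents table")
        if strata_attribute not in RESPONDENT_ATTRIBUTES:
            raise ValueError(
                f"unknown attribute {strata_attribute!r}; "
                f"expected one of {sorted(RESPONDENT_ATTRIBUTES)}")
        joined = matched.merge(
            respondents[["respondent_id", strata_attribute]], on="respondent_id")
        report.strata = {}
        for level in RESPONDENT_ATTRIBUTES[strata_attribute]:
            sub = joined.loc[joined[strata_attribute] == level]
            if len(sub):
                report.strata[level] = _report_from_matched(sub)
    return report


def report_frame(report: ReliabilityReport) -> pd.DataFrame:
    """Serialize a (possibly stratified) report as one row per stratum."""
    def row(label: str, r: ReliabilityReport) -> dict:
        return {
            "stratum": label,
            "n_same_order": r.n_same_order,
            "n_reverse_order": r.n_reverse_order,
            "p_consistent_same": r.p_consistent_same,
            "p_same_state_reverse": r.p_same_state_reverse,
            "kappa_same": r.kappa_same,
            "kappa_reverse": r.kappa_reverse,
        }

    rows = [row("overall", report)]
    for label, sub in (report.strata or {}).items():
        rows.append(row(label, sub))
    return pd.DataFrame(rows)
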