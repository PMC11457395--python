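"""Core domain types and CSV interchange for the disability-weight pipeline.

The pipeline values health states by paired comparison: respondents judge
which of two hypothetical persons is healthier, a Thurstonian probit model
turns those forced choices into latent severities, and a loess anchor maps
the latent scale onto 0-to-1 disability weights.  This module defines the
records that flow between stages (health states, respondents, individual
paired-comparison responses, anchored weight estimates), the CSV schemas
used to persist them, and the packaged transcription of the published Dutch
disability-weight table used as fixture, anchor source and simulation
ground truth.

CSV conventions: comma-separated, UTF-8, mandatory header row, "." decimal
separator; optional numeric fields are encoded as the empty string.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CatalogError",
    "IntegrityError",
    "HealthState",
    "Respondent",
    "PairedResponse",
    "DisabilityWeightEstimate",
    "ORIGINS",
    "AGE_GROUPS",
    "GENDERS",
    "EDUCATION_LEVELS",
    "CHRONIC_GROUPS",
    "REGIONS",
    "read_catalog",
    "write_catalog",
    "read_estimates",
    "write_estimates",
    "read_responses",
    "write_responses",
    "read_respondents",
    "write_respondents",
    "load_table2_fixture",
    "table2_catalog",
    "filter_by_threshold",
    "catalog_by_id",
]


class CatalogError(ValueError):
    """Malformed or inconsistent catalog/estimate input."""


class IntegrityError(ValueError):
    """Cross-file referential integrity violation (unknown ids, unmatched rows)."""


# Closed enumerations for respondent attributes (survey design categories).
ORIGINS = ("prior_study", "new", "experimental")
AGE_GROUPS = ("18-34", "35-54", "55-75")
GENDERS = ("male", "female", "other")
EDUCATION_LEVELS = ("low", "middle", "high")
CHRONIC_GROUPS = ("zero", "one", "two_plus")
REGIONS = ("north", "east", "south", "west")

RESPONDENT_ATTRIBUTES = {
    "age_group": AGE_GROUPS,
    "gender": GENDERS,
    "education": EDUCATION_LEVELS,
    "chronic_group": CHRONIC_GROUPS,
    "region": REGIONS,
}


def _check_unit_open(value: float, what: str) -> None:
    if not (0.0 < value < 1.0):
        raise CatalogError(f"{what} must lie strictly inside (0, 1); got {value!r}")


@dataclass(frozen=True)
class HealthState:
    """One valued health state.

    ``reference_dw`` is the external anchor value (a published 0-to-1
    disability weight) used by the loess anchoring stage; ``true_dw`` is
    simulation-only ground truth and is never consumed by estimation.
    """

    state_id: str
    name: str
    category: str
    origin: str = "prior_study"
    reference_dw: Optional[float] = None
    true_dw: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.state_id:
            raise CatalogError("state_id must be non-empty")
        if self.origin not in ORIGINS:
            raise CatalogError(
                f"origin must be one of {ORIGINS}; got {self.origin!r}"
            )
        if self.reference_dw is not None:
            _check_unit_open(self.reference_dw, f"reference_dw of {self.state_id!r}")
        if self.true_dw is not None:
            _check_unit_open(self.true_dw, f"true_dw of {self.state_id!r}")


@dataclass(frozen=True)
class Respondent:
    respondent_id: str
    age_group: str
    gender: str
    education: str
    chronic_group: str
    region: str

    def __post_init__(self) -> None:
        for attr, allowed in RESPONDENT_ATTRIBUTES.items():
            value = getattr(self, attr)
            if value not in allowed:
                raise CatalogError(
                    f"{attr} must be one of {allowed}; got {value!r}"
                )


@dataclass(frozen=True)
class PairedResponse:
    """One forced-choice judgment: which of two states is the healthier one.

    ``is_repeat`` marks the deliberate test-retest repetition of an earlier
    pair later in the task sequence; ``repeat_order`` records whether the
    repeated pair was shown in the same or reversed presentation order.
    """

    respondent_id: str
    task_index: int
    first_state: str
    second_state: str
    choice: str  # "first" | "second"
    is_repeat: bool = False
    repeat_order: Optional[str] = None  # "same" | "reverse"

    def __post_init__(self) -> None:
        if self.first_state == self.second_state:
            raise CatalogError(
                f"paired comparison requires two distinct states; got "
                f"{self.first_state!r} twice (respondent {self.respondent_id})"
            )
        if self.choice not in ("first", "second"):
            raise CatalogError(f"choice must be 'first' or 'second'; got {self.choice!r}")
        if self.is_repeat and self.repeat_order not in ("same", "reverse"):
            raise CatalogError("repeat responses must carry repeat_order same/reverse")
        if not self.is_repeat and self.repeat_order is not None:
            raise CatalogError("repeat_order only valid on repeat responses")


@dataclass(frozen=True)
class DisabilityWeightEstimate:
    """Anchored point estimate with a bootstrap 95% uncertainty interval.

    Percentile construction does not guarantee that the point estimate lies
    inside the interval, so only bound ordering and containment in (0, 1)
    are enforced.
    """

    state_id: str
    dw: float
    ui_low: float
    ui_high: float

    def __post_init__(self) -> None:
        _check_unit_open(self.dw, f"dw of {self.state_id!r}")
        _check_unit_open(self.ui_low, f"ui_low of {self.state_id!r}")
        _check_unit_open(self.ui_high, f"ui_high of {self.state_id!r}")
        if self.ui_low > self.ui_high:
            raise CatalogError(
                f"uncertainty bounds out of order for {self.state_id!r}: "
                f"{self.ui_low} > {self.ui_high}"
            )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["state_id", "name", "category", "origin", "reference_dw", "true_dw"]
ESTIMATE_COLUMNS = ["state_id", "dw", "ui_low", "ui_high"]
RESPONSE_COLUMNS = [
    "respondent_id", "task_index", "first_state", "second_state",
    "choice", "is_repeat", "repeat_order",
]
RESPONDENT_COLUMNS = [
    "respondent_id", "age_group", "gender", "education", "chronic_group", "region",
]


def _parse_optional_float(raw: str, line_no: int, fieldname: str) -> Optional[float]:
    if raw is None or raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise CatalogError(
            f"line {line_no}: field {fieldname!r} is not a number: {raw!r}"
        ) from None


def _open_reader(path):
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    return fh, reader


def _require_header(reader: csv.DictReader, required: Sequence[str], path) -> None:
    got = reader.fieldnames or []
    missing = [c for c in required if c not in got]
    if missing:
        raise CatalogError(f"{path}: header is missing columns {missing}; got {got}")


def read_catalog(path) -> list[HealthState]:
    """Read a health-state catalog CSV into validated :class:`HealthState` rows.

    Raises :class:`CatalogError` naming the offending line and field for
    malformed rows, and listing the id for duplicated ``state_id`` values.
    """
    fh, reader = _open_reader(path)
    with fh:
        _require_header(reader, ["state_id", "name", "category", "origin"], path)
        states: list[HealthState] = []
        seen: set[str] = set()
        for line_no, row in enumerate(reader, start=2):
            sid = (row.get("state_id") or "").strip()
            if not sid:
                raise CatalogError(f"line {line_no}: field 'state_id' is empty")
            if sid in seen:
                raise CatalogError(f"duplicate state_id {sid!r} (line {line_no})")
            seen.add(sid)
            try:
                states.append(HealthState(
                    state_id=sid,
                    name=row.get("name") or "",
                    category=row.get("category") or "",
                    origin=(row.get("origin") or "prior_study").strip(),
                    reference_dw=_parse_optional_float(
                        row.get("reference_dw", ""), line_no, "reference_dw"),
                    true_dw=_parse_optional_float(
                        row.get("true_dw", ""), line_no, "true_dw"),
                ))
            except CatalogError as exc:
                raise CatalogError(f"line {line_no}: {exc}") from None
    return states


def write_catalog(states: Iterable[HealthState], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOG_COLUMNS)
        for s in states:
            writer.writerow([
                s.state_id, s.name, s.category, s.origin,
                "" if s.reference_dw is None else repr(s.reference_dw),
                "" if s.true_dw is None else repr(s.true_dw),
            ])


def read_estimates(path) -> list[DisabilityWeightEstimate]:
    fh, reader = _open_reader(path)
    with fh:
        _require_header(reader, ESTIMATE_COLUMNS, path)
        out = []
        seen: set[str] = set()
        for line_no, row in enumerate(reader, start=2):
            sid = (row.get("state_id") or "").strip()
            if sid in seen:
                raise CatalogError(f"duplicate state_id {sid!r} (line {line_no})")
            seen.add(sid)
            try:
                out.append(DisabilityWeightEstimate(
                    state_id=sid,
                    dw=float(row["dw"]),
                    ui_low=float(row["ui_low"]),
                    ui_high=float(row["ui_high"]),
                ))
            except (ValueError, KeyError) as exc:
                raise CatalogError(f"line {line_no}: {exc}") from None
    return out


def write_estimates(estimates: Iterable[DisabilityWeightEstimate], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ESTIMATE_COLUMNS)
        for e in estimates:
            writer.writerow([e.state_id, repr(e.dw), repr(e.ui_low), repr(e.ui_high)])


def read_responses(path) -> pd.DataFrame:
    """Read paired-comparison responses into a validated DataFrame."""
    df = pd.read_csv(path, dtype={"respondent_id": str}, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: responses header missing columns {missing}")
    df["task_index"] = df["task_index"].astype(int)
    df["is_repeat"] = df["is_repeat"].map(
        {"True": True, "False": False, True: True, False: False, "true": True,
         "false": False, 1: True, 0: False})
    if df["is_repeat"].isna().any():
        raise CatalogError(f"{path}: is_repeat must be boolean")
    df.loc[df["repeat_order"] == "", "repeat_order"] = None
    validate_responses(df)
    return df


def validate_responses(df: pd.DataFrame) -> None:
    if (df["first_state"] == df["second_state"]).any():
        bad = df.loc[df["first_state"] == df["second_state"], "respondent_id"]
        raise CatalogError(
            f"responses compare a state with itself for respondents "
            f"{sorted(set(bad))[:5]}")
    if not df["choice"].isin(["first", "second"]).all():
        raise CatalogError("choice column must be 'first' or 'second'")
    rep = df.loc[df["is_repeat"]]
    if not rep["repeat_order"].isin(["same", "reverse"]).all():
        raise CatalogError("repeat responses must carry repeat_order same/reverse")


def write_responses(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["repeat_order"] = out["repeat_order"].fillna("")
    out.to_csv(path, index=False, columns=RESPONSE_COLUMNS)


def read_respondents(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONDENT_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: respondents header missing columns {missing}")
    if df["respondent_id"].duplicated().any():
        dupes = df.loc[df["respondent_id"].duplicated(), "respondent_id"].tolist()
        raise CatalogError(f"duplicate respondent ids: {dupes[:5]}")
    for attr, allowed in RESPONDENT_ATTRIBUTES.items():
        bad = ~df[attr].isin(allowed)
        if bad.any():
            raise CatalogError(
                f"{attr} contains values outside {allowed}: "
                f"{sorted(set(df.loc[bad, attr]))[:5]}")
    return df


def write_respondents(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=RESPONDENT_COLUMNS)


# ---------------------------------------------------------------------------
# Packaged fixture: the published Dutch disability-weight table
# ---------------------------------------------------------------------------

def _fixture_frame() -> pd.DataFrame:
    with resources.files("disweights.data").joinpath("table2.csv").open(
            "r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_table2_fixture() -> list[DisabilityWeightEstimate]:
    """Return the packaged published disability-weight table.

    This is a transcription of the printed results table of the Dutch
    disability-weights measurement study: every row carries the anchored
    point estimate and its 95% uncertainty interval.  The printed table
    lists 203 states (the study valued 210, of which seven were
    experimental and excluded from the published weight set).
    """
    df = _fixture_frame()
    return [
        DisabilityWeightEstimate(r.state_id, r.dw, r.ui_low, r.ui_high)
        for r in df.itertuples()
    ]


def table2_catalog(as_truth: bool = True) -> list[HealthState]:
    """Build a health-state catalog from the packaged weight table.

    With ``as_truth`` the published point estimates are installed both as
    simulation ground truth (``true_dw``) and anchor values
    (``reference_dw``), which is how the synthetic survey emulates the
    study over a realistic severity distribution.  The per-state
    prior-study/new origin split is not printed in the table, so all rows
    carry origin ``prior_study``.
    """
    df = _fixture_frame()
    return [
        HealthState(
            state_id=r.state_id,
            name=r.name,
            category=r.category,
            origin="prior_study",
            reference_dw=r.dw if as_truth else None,
            true_dw=r.dw if as_truth else None,
        )
        for r in df.itertuples()
    ]


def filter_by_threshold(
    estimates: Sequence[DisabilityWeightEstimate], threshold: float
) -> tuple[int, list[DisabilityWeightEstimate]]:
    """Return (count, subset) of estimates with dw strictly below ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise CatalogError(f"threshold must lie in (0, 1); got {threshold!r}")
    subset = [e for e in estimates if e.dw < threshold]
    return len(subset), subset


def catalog_by_id(states: Iterable[HealthState]) -> dict[str, HealthState]:
    return {s.state_id: s for s in states}
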