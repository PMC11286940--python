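"""Data model, CSV input/output, stratification and record filtering.

Every downstream statistic operates on tables that have passed through
:func:`filter_stomachs`.  The filtering rules mirror standard
stomach-content practice: bait and chum items are discarded, prey that
cannot be placed at family level or finer is omitted, and stomachs left
with no identifiable natural prey are excluded.  Every dropped row is
accounted for in an exclusion log so that retained + excluded rows
always partition the input exactly.

The study calendar runs April 1 -> March 31: seasons are spring
(April-June), summer (July-September), fall (October-December) and
winter (January-March), and "day of year" is counted from April 1
(day 1) through the following March 31 (day 365 or 366).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer", "fall", "winter")
SIZE_CLASSES = ("sub_adult", "adult")
SOURCE_GROUPS = ("coastal_nekton", "oceanic_nekton", "oceanic_plankton")

#: taxonomic ranks fine enough to enter statistics
FAMILY_OR_FINER = frozenset({"species", "genus", "family"})

#: order-level groups kept as honorary family-level units
HONORARY_FAMILY_TAXA = frozenset({"stomatopoda"})

#: substrings marking non-prey stomach contents (dropped, stomach kept)
NON_PREY_MARKERS = ("sargassum", "parasite")

STOMACH_COLUMNS = [
    "stomach_id", "capture_date", "fork_length_cm", "sex",
    "bait_used", "chum_used",
]
PREY_COLUMNS = [
    "stomach_id", "taxon_name", "taxon_rank", "family", "count",
    "wet_weight_g", "life_stage", "is_bait", "is_chum", "source_group",
]

FORK_LENGTH_BOUNDS = (30.0, 250.0)


class ValidationError(ValueError):
    """Raised when an input table violates the schema, naming the row."""


@dataclass(frozen=True)
class StomachRecord:
    stomach_id: str
    capture_date: _dt.date
    fork_length_cm: float
    sex: str = "unknown"
    bait_used: bool = False
    chum_used: bool = False


@dataclass(frozen=True)
class PreyRecord:
    stomach_id: str
    taxon_name: str
    taxon_rank: str
    family: str = ""
    count: int = 1
    wet_weight_g: float = 0.0
    life_stage: str = "unknown"
    is_bait: bool = False
    is_chum: bool = False
    source_group: str = "unassigned"


@dataclass(frozen=True)
class Stratum:
    season: str
    size_class: str

    def __post_init__(self):
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")

    def __str__(self) -> str:
        return f"{self.size_class}/{self.season}"


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def assign_season(capture_date: _dt.date | str) -> str:
    """Map a calendar date to its season.

    April-June -> spring, July-September -> summer, October-December ->
    fall, January-March -> winter.
    """
    d = _coerce_date(capture_date)
    m = d.month
    if m in (4, 5, 6):
        return "spring"
    if m in (7, 8, 9):
        return "summer"
    if m in (10, 11, 12):
        return "fall"
    return "winter"


def assign_size_class(fork_length_cm: float) -> str:
    """Sub-adult below 100 cm fork length, adult at or above 100 cm."""
    if not np.isfinite(fork_length_cm) or fork_length_cm <= 0:
        raise ValidationError(f"non-positive fork length {fork_length_cm!r}")
    return "sub_adult" if fork_length_cm < 100.0 else "adult"


def cycle_start(capture_date: _dt.date | str) -> _dt.date:
    """April 1 opening the study cycle that contains ``capture_date``."""
    d = _coerce_date(capture_date)
    year = d.year if d.month >= 4 else d.year - 1
    return _dt.date(year, 4, 1)


def day_of_year(capture_date: _dt.date | str) -> int:
    """Days since the cycle's April 1, counting April 1 itself as day 1.

    A cycle spanning a leap February has 366 days; otherwise 365.
    Multi-year inputs are handled by mapping each date within its own
    April->March cycle.
    """
    d = _coerce_date(capture_date)
    return (d - cycle_start(d)).days + 1


def _coerce_date(value: _dt.date | str) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"unparseable date {value!r}") from exc


def stratify(stomachs: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``season``, ``size_class`` and ``day_of_year``."""
    out = stomachs.copy()
    out["season"] = out["capture_date"].map(assign_season)
    out["size_class"] = out["fork_length_cm"].map(assign_size_class)
    out["day_of_year"] = out["capture_date"].map(day_of_year)
    return out


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    try:
        return _BOOL_MAP[str(x).strip().lower()]
    except KeyError:
        raise ValidationError(f"unparseable boolean {x!r}") from None


def read_stomach_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stomach_id": str})
    _require_columns(df, STOMACH_COLUMNS, "stomach table")
    df["capture_date"] = df["capture_date"].map(_coerce_date)
    df["fork_length_cm"] = df["fork_length_cm"].astype(float)
    for col in ("bait_used", "chum_used"):
        df[col] = df[col].map(_parse_bool)
    df["sex"] = df["sex"].fillna("unknown").astype(str)
    return validate_stomachs(df)


def read_prey_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"stomach_id": str, "taxon_name": str}, keep_default_na=False
    )
    _require_columns(df, PREY_COLUMNS, "prey table")
    df["count"] = df["count"].astype(int)
    df["wet_weight_g"] = df["wet_weight_g"].astype(float)
    for col in ("is_bait", "is_chum"):
        df[col] = df[col].map(_parse_bool)
    return validate_prey(df)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as UTF-8 CSV with ISO-8601 dates."""
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def _require_columns(df: pd.DataFrame, cols: Iterable[str], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{label} is missing columns {missing}")


def validate_stomachs(df: pd.DataFrame) -> pd.DataFrame:
    lo, hi = FORK_LENGTH_BOUNDS
    bad = df[(df["fork_length_cm"] <= lo) | (df["fork_length_cm"] >= hi)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"stomach {row['stomach_id']}: fork length {row['fork_length_cm']} "
            f"outside ({lo}, {hi}) cm"
        )
    if df["stomach_id"].duplicated().any():
        dup = df.loc[df["stomach_id"].duplicated(), "stomach_id"].iloc[0]
        raise ValidationError(f"duplicate stomach_id {dup!r}")
    return df


def validate_prey(df: pd.DataFrame) -> pd.DataFrame:
    if (df["count"] < 0).any():
        row = df[df["count"] < 0].iloc[0]
        raise ValidationError(
            f"prey row (stomach {row['stomach_id']}, {row['taxon_name']}): "
            f"negative count"
        )
    if (df["wet_weight_g"] < 0).any():
        row = df[df["wet_weight_g"] < 0].iloc[0]
        raise ValidationError(
            f"prey row (stomach {row['stomach_id']}, {row['taxon_name']}): "
            f"negative weight"
        )
    return df


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    stomachs: pd.DataFrame
    prey: pd.DataFrame
    exclusion_log: pd.DataFrame

    @property
    def n_retained_stomachs(self) -> int:
        return len(self.stomachs)


def _is_non_prey(name: str) -> bool:
    low = str(name).lower()
    return any(marker in low for marker in NON_PREY_MARKERS)


def filter_stomachs(
    stomachs: pd.DataFrame,
    prey: pd.DataFrame,
    *,
    honorary_taxa: frozenset[str] = HONORARY_FAMILY_TAXA,
) -> FilterResult:
    """Apply the pre-statistics filtering rules.

    Row-level rules, applied in order to each prey row:

    1. bait or chum items are discarded (``bait`` / ``chum``);
    2. non-prey contents (Sargassum, parasites) are discarded
       (``non_prey``) but do not disqualify the stomach;
    3. rows with zero count are discarded (``zero_count``);
    4. rows identified more coarsely than family are discarded
       (``coarse_taxon``), except honorary family-level groups such as
       the order Stomatopoda.

    Stomach-level rule: stomachs with no surviving prey rows are
    excluded — with reason ``empty`` if they had no prey rows at all,
    otherwise ``no identifiable prey``.

    The exclusion log has one row per dropped prey row plus one row per
    excluded stomach, so input rows partition exactly into retained
    rows and logged exclusions.  The operation is idempotent.
    """
    prey = prey.reset_index(drop=True)
    stomachs = stomachs.reset_index(drop=True)
    log_rows: list[dict] = []
    keep = np.ones(len(prey), dtype=bool)

    for i, row in prey.iterrows():
        reason = None
        if row["is_bait"]:
            reason = "bait"
        elif row["is_chum"]:
            reason = "chum"
        elif _is_non_prey(row["taxon_name"]):
            reason = "non_prey"
        elif int(row["count"]) < 1:
            reason = "zero_count"
        elif (
            row["taxon_rank"] not in FAMILY_OR_FINER
            and str(row["taxon_name"]).lower() not in honorary_taxa
        ):
            reason = "coarse_taxon"
        if reason is not None:
            keep[i] = False
            log_rows.append(
                {
                    "kind": "prey_row",
                    "stomach_id": row["stomach_id"],
                    "taxon_name": row["taxon_name"],
                    "reason": reason,
                }
            )

    retained_prey = prey[keep].reset_index(drop=True)
    had_any = set(prey["stomach_id"])
    has_valid = set(retained_prey["stomach_id"])
    stomach_keep = stomachs["stomach_id"].isin(has_valid)
    for _, row in stomachs[~stomach_keep].iterrows():
        sid = row["stomach_id"]
        log_rows.append(
            {
                "kind": "stomach",
                "stomach_id": sid,
                "taxon_name": "",
                "reason": "empty" if sid not in had_any else "no identifiable prey",
            }
        )

    retained_stomachs = stomachs[stomach_keep].reset_index(drop=True)
    # prey rows referencing an excluded or unknown stomach never reach stats
    known = set(retained_stomachs["stomach_id"])
    orphan = ~retained_prey["stomach_id"].isin(known)
    for _, row in retained_prey[orphan].iterrows():
        log_rows.append(
            {
                "kind": "prey_row",
                "stomach_id": row["stomach_id"],
                "taxon_name": row["taxon_name"],
                "reason": "orphan_row",
            }
        )
    retained_prey = retained_prey[~orphan].reset_index(drop=True)

    log = pd.DataFrame(log_rows, columns=["kind", "stomach_id", "taxon_name", "reason"])
    return FilterResult(retained_stomachs, retained_prey, log)


def normalize_taxon(name: str) -> str:
    """Case-insensitive canonical form of a taxon name."""
    return " ".join(str(name).strip().split()).lower()


def apply_family_lookup(prey: pd.DataFrame, lookup: pd.DataFrame) -> pd.DataFrame:
    """Fill empty ``family`` fields from a taxonomy lookup table.

    ``lookup`` needs columns ``taxon_name`` and ``family``; matching is
    case-insensitive on the normalized taxon name.
    """
    table = {
        normalize_taxon(r["taxon_name"]): r["family"] for _, r in lookup.iterrows()
    }
    out = prey.copy()
    blank = out["family"].astype(str).str.strip() == ""
    out.loc[blank, "family"] = [
        table.get(normalize_taxon(t), "") for t in out.loc[blank, "taxon_name"]
    ]
    return out
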