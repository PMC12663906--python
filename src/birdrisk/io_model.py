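"""Domain records and CSV I/O for airfield bird-monitoring tables.

Four monitoring streams feed the risk pipeline, plus one reference table:

* transect bird count surveys — exact counts per species over the whole
  airfield, the source of species density (birds per 10 ha);
* runway inspection counts — frequent short censuses of the runway area in
  which abundance is recorded per species in fixed count classes
  (``1-2`` … ``>1000``) and bird-control personnel assign a qualitative
  local bird status (normal / alert / critical);
* bird strike records — one record per collision event, regardless of the
  number of birds hit;
* aircraft-movement ledgers — takeoffs plus landings per airbase and year,
  the exposure denominator of strike rates;
* species profiles — body mass per species, the severity term of SSI.

All tables are interchanged as comma-separated UTF-8 CSV with a single
header row and ISO-8601 dates.  Readers validate every row against the
record invariants and report offending row numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "COUNT_CLASSES",
    "FLIGHT_PHASES",
    "LOCAL_PHASES",
    "OBSERVER_STATUSES",
    "STATUSES",
    "UNKNOWN_SPECIES",
    "SpeciesProfile",
    "CountSurvey",
    "InspectionRecord",
    "StrikeRecord",
    "MovementEntry",
    "AirbaseProfile",
    "DatasetSummary",
    "FilterReport",
    "SchemaError",
    "RowValidationError",
    "normalize_count_class",
    "read_table",
    "write_table",
    "filter_strikes",
    "summarize_dataset",
    "summarize_reported",
    "reconstruct_species_known",
]

#: Fixed, ordered set of runway-inspection count classes.
COUNT_CLASSES: tuple[str, ...] = (
    "1-2", "3-5", "6-10", "11-25", "26-50",
    "51-100", "101-250", "251-500", "501-1000", ">1000",
)

#: All recognised flight phases.  The first five are the "local" phases
#: (strikes on or immediately around the airfield); anything else is
#: recorded as "other" and excluded from local-strike analyses.
FLIGHT_PHASES: tuple[str, ...] = (
    "final_approach", "landing", "touch_and_go", "takeoff", "climb", "other",
)
LOCAL_PHASES: frozenset[str] = frozenset(FLIGHT_PHASES[:5])

#: Sentinel species id for strikes whose remains could not be identified.
#: Reserved: never a valid species_id in a species profile table.
UNKNOWN_SPECIES = "UNKNOWN"

#: Local bird statuses, ordered from least to most severe.
STATUSES: tuple[str, ...] = ("normal", "alert", "critical")
OBSERVER_STATUSES: tuple[str, ...] = STATUSES + ("unknown",)


class SchemaError(ValueError):
    """A CSV file does not match the expected column layout."""


class RowValidationError(ValueError):
    """One or more CSV rows violate a record invariant.

    ``rows`` holds 1-based data-row numbers (header excluded) with the
    per-row reason.
    """

    def __init__(self, message: str, rows: Sequence[tuple[int, str]]):
        self.rows = list(rows)
        detail = "; ".join(f"row {r}: {why}" for r, why in self.rows[:10])
        more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        super().__init__(f"{message}: {detail}{more}")


@dataclass(frozen=True)
class SpeciesProfile:
    species_id: str
    common_name: str
    body_mass_kg: float

    def __post_init__(self):
        if self.body_mass_kg <= 0:
            raise ValueError(f"body_mass_kg must be > 0, got {self.body_mass_kg}")
        if self.species_id == UNKNOWN_SPECIES:
            raise ValueError(f"{UNKNOWN_SPECIES!r} is a reserved sentinel, not a species id")


@dataclass(frozen=True)
class CountSurvey:
    """One species' tally on one full-airfield transect count."""

    date: date
    airbase: str
    species_id: str
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class InspectionRecord:
    """One runway inspection: class-binned counts plus the observer's status.

    ``observations`` maps species_id to a count-class label; it is empty when
    no birds were seen.
    """

    timestamp: datetime
    airbase: str
    observations: Mapping[str, str] = field(default_factory=dict)
    observer_status: str = "unknown"

    def __post_init__(self):
        for sp, cls in self.observations.items():
            if cls not in COUNT_CLASSES:
                raise ValueError(f"unknown count class {cls!r} for species {sp!r}")
        if self.observer_status not in OBSERVER_STATUSES:
            raise ValueError(f"unknown observer status {self.observer_status!r}")


@dataclass(frozen=True)
class StrikeRecord:
    """One bird strike event (multiple birds hit still count once)."""

    date: date
    airbase: str
    species_id: str
    flight_phase: str

    def __post_init__(self):
        if self.flight_phase not in FLIGHT_PHASES:
            raise ValueError(f"unknown flight phase {self.flight_phase!r}")


@dataclass(frozen=True)
class MovementEntry:
    """Aircraft movements (takeoffs + landings) for one airbase-year."""

    airbase: str
    year: int
    movements: int

    def __post_init__(self):
        if self.movements < 0:
            raise ValueError(f"movements must be >= 0, got {self.movements}")


@dataclass(frozen=True)
class AirbaseProfile:
    airbase: str
    area_ha: float
    survey_start: date
    survey_end: date

    def __post_init__(self):
        if self.area_ha <= 0:
            raise ValueError(f"area_ha must be > 0, got {self.area_ha}")


@dataclass
class DatasetSummary:
    """Per-airbase and total dataset extent.

    ``per_airbase`` is indexed by airbase with columns ``n_strikes``,
    ``pct_species_known``, ``n_count_surveys``, ``n_inspections``.  The total
    percentage is the strike-weighted mean of the per-airbase percentages.
    """

    per_airbase: pd.DataFrame
    total_strikes: int
    total_pct_species_known: float
    total_count_surveys: int
    total_inspections: int

    def to_frame(self) -> pd.DataFrame:
        total = pd.DataFrame(
            {
                "n_strikes": [self.total_strikes],
                "pct_species_known": [self.total_pct_species_known],
                "n_count_surveys": [self.total_count_surveys],
                "n_inspections": [self.total_inspections],
            },
            index=pd.Index(["Total"], name="airbase"),
        )
        return pd.concat([self.per_airbase, total])


@dataclass
class FilterReport:
    """Partition of dropped strike records by reason."""

    n_kept: int = 0
    dropped_by_phase: int = 0
    dropped_unknown_species: int = 0

    @property
    def n_dropped(self) -> int:
        return self.dropped_by_phase + self.dropped_unknown_species


# en/em dashes as they appear in field notes; canonical labels use "-"
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})


def normalize_count_class(label: str) -> str:
    """Return the canonical form of a count-class label.

    Raises ``ValueError`` for labels outside the fixed class set (e.g. a raw
    number like ``"7"``).
    """
    canon = label.strip().translate(_DASHES).replace(" ", "")
    if canon not in COUNT_CLASSES:
        raise ValueError(f"not a count class label: {label!r}")
    return canon


# ---------------------------------------------------------------------------
# CSV schemas

_SCHEMAS: dict[str, tuple[str, ...]] = {
    "species": ("species_id", "common_name", "body_mass_kg"),
    "surveys": ("date", "airbase", "species_id", "count"),
    "inspections": ("timestamp", "airbase", "species_id", "count_class", "observer_status"),
    "strikes": ("date", "airbase", "species_id", "flight_phase"),
    "movements": ("airbase", "year", "movements"),
    "airbases": ("airbase", "area_ha", "survey_start", "survey_end"),
}


def _load_frame(path, kind: str) -> pd.DataFrame:
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {kind} table is missing columns {missing}")
    return df


def read_table(path, kind: str):
    """Read and validate one of the six CSV tables.

    Returns a list of typed records (``InspectionRecord`` rows are grouped by
    (timestamp, airbase)).  Invalid rows raise ``RowValidationError`` listing
    the 1-based data-row numbers; a missing column raises ``SchemaError``.
    """
    df = _load_frame(path, kind)
    bad: list[tuple[int, str]] = []
    if kind == "inspections":
        records = _parse_inspections(df, bad)
    else:
        parser = {
            "species": _parse_species_row,
            "surveys": _parse_survey_row,
            "strikes": _parse_strike_row,
            "movements": _parse_movement_row,
            "airbases": _parse_airbase_row,
        }[kind]
        records = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                records.append(parser(row))
            except (ValueError, TypeError) as exc:
                bad.append((i, str(exc)))
        if kind == "species" and not bad:
            seen: dict[str, int] = {}
            for i, r in enumerate(records, start=1):
                if r.species_id in seen:
                    bad.append((i, f"duplicate species_id {r.species_id!r}"))
                seen.setdefault(r.species_id, i)
        if kind == "surveys" and not bad:
            keys: dict[tuple, int] = {}
            for i, r in enumerate(records, start=1):
                k = (r.date, r.airbase, r.species_id)
                if k in keys:
                    bad.append((i, f"duplicate survey key {k}"))
                keys.setdefault(k, i)
    if bad:
        raise RowValidationError(f"invalid rows in {kind} table", bad)
    return records


def _parse_species_row(row) -> SpeciesProfile:
    return SpeciesProfile(row.species_id, row.common_name, float(row.body_mass_kg))


def _parse_survey_row(row) -> CountSurvey:
    count = int(row.count)
    return CountSurvey(date.fromisoformat(row.date), row.airbase, row.species_id, count)


def _parse_strike_row(row) -> StrikeRecord:
    return StrikeRecord(
        date.fromisoformat(row.date), row.airbase, row.species_id, row.flight_phase
    )


def _parse_movement_row(row) -> MovementEntry:
    return MovementEntry(row.airbase, int(row.year), int(row.movements))


def _parse_airbase_row(row) -> AirbaseProfile:
    return AirbaseProfile(
        row.airbase,
        float(row.area_ha),
        date.fromisoformat(row.survey_start),
        date.fromisoformat(row.survey_end),
    )


def _parse_inspections(df: pd.DataFrame, bad: list) -> list[InspectionRecord]:
    # long format: one row per species sighting; a bird-free inspection is a
    # single row with empty species_id and count_class
    groups: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        key = (row.timestamp, row.airbase)
        g = groups.setdefault(key, {"obs": {}, "status": None, "row": i})
        status = row.observer_status or "unknown"
        if status not in OBSERVER_STATUSES:
            bad.append((i, f"unknown observer status {status!r}"))
            continue
        if g["status"] is None:
            g["status"] = status
        elif g["status"] != status:
            bad.append((i, f"conflicting observer status within inspection {key}"))
            continue
        if row.species_id == "":
            continue
        try:
            cls = normalize_count_class(row.count_class)
        except ValueError as exc:
            bad.append((i, str(exc)))
            continue
        if row.species_id in g["obs"]:
            bad.append((i, f"duplicate species {row.species_id!r} in inspection {key}"))
            continue
        g["obs"][row.species_id] = cls
    records = []
    for (ts, base), g in groups.items():
        try:
            records.append(
                InspectionRecord(
                    datetime.fromisoformat(ts), base, g["obs"], g["status"] or "unknown"
                )
            )
        except ValueError as exc:
            bad.append((g["row"], str(exc)))
    return records


def write_table(records: Iterable, path, kind: str) -> None:
    """Write typed records back to CSV (inverse of :func:`read_table`)."""
    cols = _SCHEMAS[kind]
    rows: list[tuple] = []
    if kind == "species":
        rows = [(r.species_id, r.common_name, repr(r.body_mass_kg)) for r in records]
    elif kind == "surveys":
        rows = [(r.date.isoformat(), r.airbase, r.species_id, r.count) for r in records]
    elif kind == "strikes":
        rows = [(r.date.isoformat(), r.airbase, r.species_id, r.flight_phase) for r in records]
    elif kind == "movements":
        rows = [(r.airbase, r.year, r.movements) for r in records]
    elif kind == "airbases":
        rows = [
            (r.airbase, repr(r.area_ha), r.survey_start.isoformat(), r.survey_end.isoformat())
            for r in records
        ]
    elif kind == "inspections":
        for r in records:
            ts = r.timestamp.isoformat()
            if not r.observations:
                rows.append((ts, r.airbase, "", "", r.observer_status))
            for sp, cls in r.observations.items():
                rows.append((ts, r.airbase, sp, cls, r.observer_status))
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Strike filtering

def filter_strikes(
    records: Sequence[StrikeRecord],
    phases: frozenset[str] | set[str] = LOCAL_PHASES,
    require_species: bool = True,
) -> tuple[list[StrikeRecord], FilterReport]:
    """Keep local strikes with (optionally) species-level identification.

    A record is dropped either because its flight phase is outside ``phases``
    (en-route and other non-local strikes) or, failing that check first,
    because the species is the UNKNOWN sentinel.  The report partitions every
    dropped record into exactly one of those two reasons.
    """
    if not phases:
        raise ValueError("phases must be non-empty")
    kept: list[StrikeRecord] = []
    report = FilterReport()
    for r in records:
        if r.flight_phase not in phases:
            report.dropped_by_phase += 1
        elif require_species and r.species_id == UNKNOWN_SPECIES:
            report.dropped_unknown_species += 1
        else:
            kept.append(r)
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Dataset summaries

def summarize_dataset(
    strikes: Sequence[StrikeRecord],
    surveys: Sequence[CountSurvey],
    inspections: Sequence[InspectionRecord],
    airbases: Sequence[AirbaseProfile],
) -> DatasetSummary:
    """Tabulate dataset extent per airbase and in total.

    Counts strikes (with the fraction identified to species level), distinct
    transect count occasions (date × airbase) and inspections.  The total
    species-known percentage is the strike-weighted mean of the per-airbase
    percentages.  Any airbase referenced by a record but absent from the
    profile table is an error.
    """
    known_bases = {a.airbase for a in airbases}
    seen = (
        {s.airbase for s in strikes}
        | {s.airbase for s in surveys}
        | {i.airbase for i in inspections}
    )
    orphans = sorted(seen - known_bases)
    if orphans:
        raise ValueError(f"records reference airbases with no profile: {orphans}")

    idx = pd.Index(sorted(known_bases), name="airbase")
    n_strikes = pd.Series(0, index=idx, dtype=int)
    n_known = pd.Series(0, index=idx, dtype=int)
    for s in strikes:
        n_strikes[s.airbase] += 1
        if s.species_id != UNKNOWN_SPECIES:
            n_known[s.airbase] += 1
    occasions = {b: set() for b in idx}
    for s in surveys:
        occasions[s.airbase].add(s.date)
    n_surveys = pd.Series({b: len(d) for b, d in occasions.items()}, dtype=int).reindex(idx)
    n_insp = pd.Series(0, index=idx, dtype=int)
    for i in inspections:
        n_insp[i.airbase] += 1

    pct = (n_known / n_strikes * 100.0).where(n_strikes > 0)
    per = pd.DataFrame(
        {
            "n_strikes": n_strikes,
            "pct_species_known": pct,
            "n_count_surveys": n_surveys,
            "n_inspections": n_insp,
        }
    )
    tot_strikes = int(n_strikes.sum())
    tot_pct = float(n_known.sum() / tot_strikes * 100.0) if tot_strikes else math.nan
    return DatasetSummary(
        per_airbase=per,
        total_strikes=tot_strikes,
        total_pct_species_known=tot_pct,
        total_count_surveys=int(n_surveys.sum()),
        total_inspections=int(n_insp.sum()),
    )


def reconstruct_species_known(n_strikes: int, pct_species_known: float) -> int:
    """Recover the species-identified strike count from a printed percentage.

    Rounds half away from zero, which is how such tables are conventionally
    rounded when printed.
    """
    return int(math.floor(n_strikes * pct_species_known / 100.0 + 0.5))


def summarize_reported(per_airbase: pd.DataFrame) -> DatasetSummary:
    """Aggregate a printed per-airbase summary table into totals.

    ``per_airbase`` needs columns ``n_strikes``, ``pct_species_known``,
    ``n_count_surveys`` and ``n_inspections`` (airbase as index or column).
    Totals are sums, except the percentage which is the strike-weighted mean;
    the species-known strike total is reconstructed per airbase (rounded)
    and then summed.
    """
    df = per_airbase.copy()
    if "airbase" in df.columns:
        df = df.set_index("airbase")
    known = df.apply(
        lambda r: reconstruct_species_known(int(r["n_strikes"]), float(r["pct_species_known"])),
        axis=1,
    )
    tot_strikes = int(df["n_strikes"].sum())
    weighted_pct = float((df["n_strikes"] * df["pct_species_known"]).sum() / tot_strikes)
    summary = DatasetSummary(
        per_airbase=df[
            ["n_strikes", "pct_species_known", "n_count_surveys", "n_inspections"]
        ],
        total_strikes=tot_strikes,
        total_pct_species_known=weighted_pct,
        total_count_surveys=int(df["n_count_surveys"].sum()),
        total_inspections=int(df["n_inspections"].sum()),
    )
    summary.per_airbase = summary.per_airbase.assign(n_species_known=known)
    return summary
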