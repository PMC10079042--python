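"""Record-level birth data: reading, validation, exclusion filters, and
epoch-level aggregation.

The analyses in this package compare two service epochs (before and after a
universal presentation-screening policy) on outcomes measured per birth.
Everything downstream consumes the 2x2 ``CohortSummary`` produced here, so
this module owns the clinical definitions: what counts as a term birth, which
pregnancies are excluded, what "undiagnosed breech" means, and which
denominators each outcome uses.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Gestational age (completed days) at which a birth counts as term: 37+0 weeks.
TERM_DAYS = 259

SITES = frozenset({"routine_us", "pocus", "other"})
PRESENTATIONS = frozenset({"cephalic", "breech", "other"})
ONSETS = frozenset(
    {"spontaneous_labour", "prelabour_rom", "induction", "planned_cesarean"}
)
MODES = frozenset(
    {
        "elective_cesarean",
        "emergency_cesarean",
        "vaginal_breech_spontaneous",
        "vaginal_breech_extraction",
        "vaginal_breech_forceps",
        "vaginal_vertex_spontaneous",
        "vaginal_vertex_operative",
    }
)
ETHNICITIES = frozenset(
    {"caucasian", "black", "asian", "mixed", "other", "not_stated"}
)

#: Labour-onset states in which a breech discovered without an antenatal
#: diagnosis counts as "undiagnosed": presenting in labour, with ruptured
#: membranes, or immediately before induction.
LABOUR_ONSETS = frozenset({"spontaneous_labour", "prelabour_rom", "induction"})

#: Outcomes measured on the neonate.  Pregnancies delivered by planned
#: cesarean for breech stay in the denominator for these outcomes only.
NEONATAL_OUTCOMES = frozenset(
    {"apgar_lt7", "nnu_admission", "hie", "perinatal_death"}
)

KNOWN_OUTCOMES = frozenset(
    {
        "undiagnosed_breech",
        "apgar_lt7",
        "nnu_admission",
        "hie",
        "perinatal_death",
        "emergency_cesarean",
        "elective_cesarean",
        "vaginal_breech",
    }
)


class SchemaError(ValueError):
    """The input file is missing required columns."""


class RowValidationError(ValueError):
    """One or more rows failed record-level validation.

    ``errors`` holds ``(row_number, message)`` pairs, 1-based counting the
    header as row 1.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        listing = "; ".join(f"row {i}: {msg}" for i, msg in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{len(errors)} invalid row(s): {listing}{more}")


@dataclass(frozen=True, slots=True)
class BirthRecord:
    """One delivery with presentation, diagnosis status, and outcomes."""

    record_id: str
    site: str
    birth_date: dt.date
    gestational_age_days: int
    plurality: int
    presentation_at_birth: str
    antenatally_diagnosed_breech: bool
    onset: str
    planned_cesarean_for_breech: bool
    mode_of_birth: str
    apgar5: int | None
    nnu_admission: bool
    hie: bool
    perinatal_death: bool
    congenital_anomaly: bool
    maternal_age_years: float = math.nan
    bmi: float = math.nan
    parous: bool = False
    ethnicity: str = "not_stated"
    imd_quintile: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if self.site not in SITES:
            problems.append(f"site {self.site!r} not in {sorted(SITES)}")
        if self.gestational_age_days < 0:
            problems.append("gestational_age_days must be >= 0")
        if self.plurality < 1:
            problems.append("plurality must be >= 1")
        if self.presentation_at_birth not in PRESENTATIONS:
            problems.append(
                f"presentation_at_birth {self.presentation_at_birth!r} invalid"
            )
        if self.onset not in ONSETS:
            problems.append(f"onset {self.onset!r} invalid")
        if self.mode_of_birth not in MODES:
            problems.append(f"mode_of_birth {self.mode_of_birth!r} invalid")
        if self.apgar5 is not None and not 0 <= self.apgar5 <= 10:
            problems.append(f"apgar5 {self.apgar5} outside [0, 10]")
        if self.planned_cesarean_for_breech and self.presentation_at_birth != "breech":
            problems.append(
                "planned_cesarean_for_breech requires breech presentation"
            )
        if self.ethnicity not in ETHNICITIES:
            problems.append(f"ethnicity {self.ethnicity!r} invalid")
        if self.imd_quintile is not None and not 1 <= self.imd_quintile <= 5:
            problems.append(f"imd_quintile {self.imd_quintile} outside [1, 5]")
        return problems


@dataclass(frozen=True)
class EpochSpec:
    """Assigns records to epochs by birth date.

    Records with ``birth_date`` strictly before ``cut_date`` belong to the
    "before" epoch; all others (half-open interval ``[cut_date, inf)``) to
    "after".
    """

    cut_date: dt.date
    label_before: str = "before"
    label_after: str = "after"

    def is_after(self, date: dt.date) -> bool:
        return date >= self.cut_date

    def label(self, date: dt.date) -> str:
        return self.label_after if self.is_after(date) else self.label_before


@dataclass(frozen=True)
class CohortSummary:
    """2x2 (epoch x event) counts with denominators for a named outcome."""

    outcome_name: str
    epoch_labels: tuple[str, str]
    events: tuple[int, int]
    totals: tuple[int, int]
    zero_corrected: bool = False

    def __post_init__(self) -> None:
        a, c = self.events
        n1, n2 = self.totals
        if n1 <= 0 or n2 <= 0:
            raise ValueError("totals must be positive")
        if not (0 <= a <= n1 and 0 <= c <= n2):
            raise ValueError("events must lie in [0, total] for each epoch")

    @property
    def risks(self) -> tuple[float, float]:
        return (self.events[0] / self.totals[0], self.events[1] / self.totals[1])

    @property
    def percentages(self) -> tuple[float, float]:
        p1, p2 = self.risks
        return (100.0 * p1, 100.0 * p2)

    def swapped(self) -> "CohortSummary":
        """Same summary with the epoch order reversed."""
        return replace(
            self,
            epoch_labels=self.epoch_labels[::-1],
            events=self.events[::-1],
            totals=self.totals[::-1],
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome_name,
            "epochs": list(self.epoch_labels),
            "events": list(self.events),
            "totals": list(self.totals),
            "percentages": [round(p, 6) for p in self.percentages],
            "zero_corrected": self.zero_corrected,
        }


# ---------------------------------------------------------------------------
# CSV I/O

_REQUIRED_COLUMNS = [
    "record_id",
    "site",
    "birth_date",
    "gestational_age_days",
    "plurality",
    "presentation_at_birth",
    "antenatally_diagnosed_breech",
    "onset",
    "planned_cesarean_for_breech",
    "mode_of_birth",
    "apgar5",
    "nnu_admission",
    "hie",
    "perinatal_death",
    "congenital_anomaly",
]

_OPTIONAL_COLUMNS = [
    "maternal_age_years",
    "bmi",
    "parous",
    "ethnicity",
    "imd_quintile",
]

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _parse_bool(text: str, column: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{column}: cannot parse boolean from {text!r}")


def _parse_opt_int(text: str, column: str) -> int | None:
    t = text.strip()
    if t == "" or t.lower() in {"na", "nan", "none"}:
        return None
    try:
        return int(t)
    except ValueError as exc:
        raise ValueError(f"{column}: cannot parse integer from {text!r}") from exc


def _parse_opt_float(text: str) -> float:
    t = text.strip()
    if t == "" or t.lower() in {"na", "nan", "none"}:
        return math.nan
    return float(t)


def read_birth_records(
    path,
    column_map: Mapping[str, str] | None = None,
) -> list[BirthRecord]:
    """Read and validate a delimited birth-record file.

    Parameters
    ----------
    path
        CSV file with a header row; dates ISO-8601; booleans true/false.
    column_map
        Optional mapping from the canonical column names used here to the
        names actually present in the file.

    Raises
    ------
    SchemaError
        If a required column is absent.
    RowValidationError
        If any row fails parsing or record invariants; the error lists each
        offending row number and field.
    """
    column_map = dict(column_map or {})

    def col(name: str) -> str:
        return column_map.get(name, name)

    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if col(c) not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        has_optional = {c: col(c) in header for c in _OPTIONAL_COLUMNS}

        records: list[BirthRecord] = []
        errors: list[tuple[int, str]] = []
        for row_no, row in enumerate(reader, start=2):
            try:
                record = BirthRecord(
                    record_id=row[col("record_id")].strip(),
                    site=row[col("site")].strip(),
                    birth_date=dt.date.fromisoformat(row[col("birth_date")].strip()),
                    gestational_age_days=int(row[col("gestational_age_days")]),
                    plurality=int(row[col("plurality")]),
                    presentation_at_birth=row[col("presentation_at_birth")].strip(),
                    antenatally_diagnosed_breech=_parse_bool(
                        row[col("antenatally_diagnosed_breech")],
                        "antenatally_diagnosed_breech",
                    ),
                    onset=row[col("onset")].strip(),
                    planned_cesarean_for_breech=_parse_bool(
                        row[col("planned_cesarean_for_breech")],
                        "planned_cesarean_for_breech",
                    ),
                    mode_of_birth=row[col("mode_of_birth")].strip(),
                    apgar5=_parse_opt_int(row[col("apgar5")], "apgar5"),
                    nnu_admission=_parse_bool(
                        row[col("nnu_admission")], "nnu_admission"
                    ),
                    hie=_parse_bool(row[col("hie")], "hie"),
                    perinatal_death=_parse_bool(
                        row[col("perinatal_death")], "perinatal_death"
                    ),
                    congenital_anomaly=_parse_bool(
                        row[col("congenital_anomaly")], "congenital_anomaly"
                    ),
                    maternal_age_years=(
                        _parse_opt_float(row[col("maternal_age_years")])
                        if has_optional["maternal_age_years"]
                        else math.nan
                    ),
                    bmi=(
                        _parse_opt_float(row[col("bmi")])
                        if has_optional["bmi"]
                        else math.nan
                    ),
                    parous=(
                        _parse_bool(row[col("parous")], "parous")
                        if has_optional["parous"]
                        else False
                    ),
                    ethnicity=(
                        row[col("ethnicity")].strip()
                        if has_optional["ethnicity"]
                        else "not_stated"
                    ),
                    imd_quintile=(
                        _parse_opt_int(row[col("imd_quintile")], "imd_quintile")
                        if has_optional["imd_quintile"]
                        else None
                    ),
                )
            except (ValueError, KeyError) as exc:
                errors.append((row_no, str(exc)))
                continue
            problems = record.validate()
            if problems:
                errors.append((row_no, "; ".join(problems)))
            else:
                records.append(record)

    if errors:
        raise RowValidationError(errors)
    return records


def write_birth_records(records: Iterable[BirthRecord], path) -> None:
    """Write records as CSV such that ``read_birth_records`` round-trips."""
    columns = [f.name for f in fields(BirthRecord)]
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for r in records:
            row = []
            for name in columns:
                value = getattr(r, name)
                if isinstance(value, bool):
                    row.append("true" if value else "false")
                elif value is None:
                    row.append("")
                elif isinstance(value, float) and math.isnan(value):
                    row.append("")
                elif isinstance(value, dt.date):
                    row.append(value.isoformat())
                else:
                    row.append(value)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Filters

def apply_exclusions(
    records: Sequence[BirthRecord],
) -> tuple[list[BirthRecord], Counter]:
    """Remove multiple pregnancies, preterm births, and congenital anomalies.

    Returns the kept records and a tally of exclusions by reason.  A record
    matching several reasons is tallied once, by the first matching reason in
    the order: multiple pregnancy, preterm, congenital anomaly.  The tally
    always satisfies ``len(kept) + sum(tally.values()) == len(records)``.
    """
    kept: list[BirthRecord] = []
    tally: Counter = Counter()
    for r in records:
        if r.plurality > 1:
            tally["multiple_pregnancy"] += 1
        elif r.gestational_age_days < TERM_DAYS:
            tally["preterm"] += 1
        elif r.congenital_anomaly:
            tally["congenital_anomaly"] += 1
        else:
            kept.append(r)
    return kept, tally


def apply_planned_cs_rule(
    records: Sequence[BirthRecord], outcome_name: str
) -> list[BirthRecord]:
    """Drop planned cesareans for breech, except for neonatal outcomes.

    Pregnancies delivered by planned cesarean for a diagnosed breech never
    labour, so they cannot contribute to labour-related outcomes; they are
    removed from every denominator except the four neonatal outcomes, where
    the baby's outcome is still informative.
    """
    if outcome_name not in KNOWN_OUTCOMES:
        raise KeyError(
            f"unknown outcome {outcome_name!r}; known: {sorted(KNOWN_OUTCOMES)}"
        )
    if outcome_name in NEONATAL_OUTCOMES:
        return list(records)
    return [r for r in records if not r.planned_cesarean_for_breech]


def classify_undiagnosed_breech(record: BirthRecord) -> bool:
    """True if a term breech was first discovered in labour, at membrane
    rupture, or immediately before induction — i.e. missed antenatally."""
    if record.presentation_at_birth != "breech":
        raise ValueError(
            f"record {record.record_id}: classify_undiagnosed_breech requires "
            "a breech birth"
        )
    return (not record.antenatally_diagnosed_breech) and record.onset in LABOUR_ONSETS


# ---------------------------------------------------------------------------
# Aggregation

def _outcome_event(record: BirthRecord, outcome_name: str) -> bool | None:
    """Event indicator for one record; None means the record lacks the data
    required by this outcome and must be dropped from its denominator."""
    if outcome_name == "undiagnosed_breech":
        if record.presentation_at_birth != "breech":
            return False  # whole-population denominators: non-breech, non-event
        return classify_undiagnosed_breech(record)
    if outcome_name == "apgar_lt7":
        if record.apgar5 is None:
            return None
        return record.apgar5 < 7
    if outcome_name == "nnu_admission":
        return record.nnu_admission
    if outcome_name == "hie":
        return record.hie
    if outcome_name == "perinatal_death":
        return record.perinatal_death
    if outcome_name == "emergency_cesarean":
        return record.mode_of_birth == "emergency_cesarean"
    if outcome_name == "elective_cesarean":
        return record.mode_of_birth == "elective_cesarean"
    if outcome_name == "vaginal_breech":
        return record.mode_of_birth in {
            "vaginal_breech_spontaneous",
            "vaginal_breech_extraction",
            "vaginal_breech_forceps",
        }
    raise KeyError(f"unknown outcome {outcome_name!r}")


def summarise(
    records: Sequence[BirthRecord],
    epoch: EpochSpec,
    outcome_name: str,
    denominator: str = "breech_births",
) -> CohortSummary:
    """Aggregate records into the 2x2 epoch-by-event table for one outcome.

    ``denominator`` selects who is at risk: ``"all_births"`` or
    ``"breech_births"``.  Records missing a field the outcome requires
    (e.g. Apgar) are dropped from that outcome's denominator, with the count
    logged.  Callers are expected to have applied :func:`apply_exclusions`
    and :func:`apply_planned_cs_rule` already.
    """
    if denominator not in {"all_births", "breech_births"}:
        raise ValueError(f"unknown denominator {denominator!r}")
    if outcome_name not in KNOWN_OUTCOMES:
        raise KeyError(f"unknown outcome {outcome_name!r}")

    if denominator == "breech_births":
        pool = [r for r in records if r.presentation_at_birth == "breech"]
    else:
        pool = list(records)

    counts = {epoch.label_before: [0, 0], epoch.label_after: [0, 0]}
    dropped = 0
    for r in pool:
        event = _outcome_event(r, outcome_name)
        if event is None:
            dropped += 1
            continue
        bucket = counts[epoch.label(r.birth_date)]
        bucket[1] += 1
        if event:
            bucket[0] += 1
    if dropped:
        logger.info(
            "summarise(%s): dropped %d record(s) missing required fields",
            outcome_name,
            dropped,
        )

    for label in (epoch.label_before, epoch.label_after):
        if counts[label][1] == 0:
            raise ValueError(f"epoch {label!r} contains no records")

    a, n1 = counts[epoch.label_before]
    c, n2 = counts[epoch.label_after]
    return CohortSummary(
        outcome_name=outcome_name,
        epoch_labels=(epoch.label_before, epoch.label_after),
        events=(a, c),
        totals=(n1, n2),
    )
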