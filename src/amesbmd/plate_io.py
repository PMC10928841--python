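"""Replicate-level Ames plate-count records: data model, CSV dialect, validation.

The canonical storage is a long (tidy) CSV with one agar plate per row and
the exact header::

    compound, method, s9, vehicle, strain, role, conc_ug_per_plate, count, toxicity_note

Concentration 0 is reserved for vehicle controls; treated rows must have a
positive concentration, which makes concurrent-control matching mechanical.
Toxicity is an explicit annotation column (the assay criterion is visual);
the pipeline never infers lawn thinning from counts alone.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "METHODS",
    "S9_SOURCES",
    "STRAINS",
    "ROLES",
    "TOXICITY_NOTES",
    "PREINCUBATION_TIME_MIN",
    "CSV_COLUMNS",
    "Design",
    "PlateRecord",
    "DoseResponseArm",
    "ValidationReport",
    "PlateTableError",
    "parse_plate_table",
    "write_plate_table",
    "build_arms",
    "validate_study",
]

METHODS = ("plate_incorporation", "pre_incubation")
S9_SOURCES = ("none", "rat", "hamster")
STRAINS = ("TA98", "TA100", "TA1535", "TA1537", "WP2uvrA_pKM101")
ROLES = ("treated", "vehicle_control", "positive_control")
TOXICITY_NOTES = ("none", "thinning", "absent_lawn")

#: pre-incubation time is a design constant of the Yahagi method
PREINCUBATION_TIME_MIN = 30.0

CSV_COLUMNS = (
    "compound",
    "method",
    "s9",
    "vehicle",
    "strain",
    "role",
    "conc_ug_per_plate",
    "count",
    "toxicity_note",
)


class PlateTableError(ValueError):
    """Schema or row-level problems in a plate-count table.

    ``errors`` is a list of ``(row_index_or_None, message)`` pairs; a
    ``None`` row index marks a table-level (schema) problem.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = [
            f"row {row}: {msg}" if row is not None else msg
            for row, msg in self.errors
        ]
        super().__init__("invalid plate table:\n  " + "\n  ".join(lines))


class Design(NamedTuple):
    """The 5-tuple identifying one dose-response study arm."""

    compound: str
    method: str
    s9: str
    vehicle: str
    strain: str


def _canon(token: str, options: tuple, what: str) -> str:
    """Case-insensitive, trimmed matching against canonical enum tokens."""
    key = str(token).strip().lower().replace(" ", "_").replace("-", "_")
    for opt in options:
        if key == opt.lower():
            return opt
    raise ValueError(f"unknown {what} {token!r} (expected one of {options})")


_STRAIN_ALIASES = {
    "wp2": "WP2uvrA_pKM101",
    "wp2uvra": "WP2uvrA_pKM101",
    "wp2uvra(pkm101)": "WP2uvrA_pKM101",
    "wp2uvra_pkm101": "WP2uvrA_pKM101",
    "wp2_uvra_pkm101": "WP2uvrA_pKM101",
}


def normalize_strain(token: str) -> str:
    key = str(token).strip().lower().replace(" ", "").replace("-", "")
    key_us = str(token).strip().lower().replace(" ", "_").replace("-", "_")
    for opt in STRAINS:
        if key_us == opt.lower() or key == opt.lower().replace("_", ""):
            return opt
    if key in _STRAIN_ALIASES:
        return _STRAIN_ALIASES[key]
    if key.replace("_", "") in _STRAIN_ALIASES:
        return _STRAIN_ALIASES[key.replace("_", "")]
    raise ValueError(f"unknown strain {token!r} (expected one of {STRAINS})")


@dataclass(frozen=True)
class PlateRecord:
    """One agar plate's revertant count plus its full design annotation."""

    compound: str
    method: str
    s9: str
    vehicle: str
    strain: str
    role: str
    concentration: float  # ug/plate
    count: int  # revertant colonies
    toxicity_note: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", _canon(self.method, METHODS, "method"))
        object.__setattr__(self, "s9", _canon(self.s9, S9_SOURCES, "s9"))
        object.__setattr__(self, "strain", normalize_strain(self.strain))
        object.__setattr__(self, "role", _canon(self.role, ROLES, "role"))
        note = self.toxicity_note if self.toxicity_note is not None else "none"
        object.__setattr__(
            self, "toxicity_note", _canon(note, TOXICITY_NOTES, "toxicity_note")
        )
        object.__setattr__(self, "vehicle", str(self.vehicle).strip().lower())
        object.__setattr__(self, "compound", str(self.compound).strip())
        conc = float(self.concentration)
        if not math.isfinite(conc) or conc < 0:
            raise ValueError("concentration must be a non-negative real")
        object.__setattr__(self, "concentration", conc)
        if self.role == "vehicle_control" and conc != 0:
            raise ValueError("vehicle_control rows must have concentration 0")
        if self.role == "treated" and conc <= 0:
            raise ValueError("treated rows must have concentration > 0")
        cnt = self.count
        if isinstance(cnt, float) and not float(cnt).is_integer():
            raise ValueError("count must be an integer")
        cnt = int(cnt)
        if cnt < 0:
            raise ValueError("count must be >= 0")
        object.__setattr__(self, "count", cnt)

    @property
    def design(self) -> Design:
        return Design(self.compound, self.method, self.s9, self.vehicle, self.strain)


@dataclass(frozen=True)
class DoseResponseArm:
    """All plates for one design 5-tuple with its concurrent vehicle controls."""

    design: Design
    doses: tuple  # strictly increasing concentrations, ug/plate
    treated_counts: dict  # dose -> tuple of plate counts
    control_counts: tuple  # concurrent vehicle-control plate counts
    toxicity_notes: dict = field(default_factory=dict)  # dose -> frozenset of notes
    positive_control_counts: tuple = ()

    def __post_init__(self) -> None:
        if len(self.doses) < 1:
            raise ValueError("arm needs at least one dose")
        if list(self.doses) != sorted(set(self.doses)):
            raise ValueError("doses must be strictly increasing")
        if not self.control_counts:
            raise ValueError("arm needs concurrent vehicle controls")
        for dose in self.doses:
            if not self.treated_counts.get(dose):
                raise ValueError(f"dose {dose} has no plates")

    @property
    def n_plates(self) -> int:
        return sum(len(v) for v in self.treated_counts.values()) + len(
            self.control_counts
        )


@dataclass
class ValidationReport:
    """Findings from validating a plate table; errors empty iff parseable into arms."""

    errors: list = field(default_factory=list)  # (row or None, message)
    warnings: list = field(default_factory=list)
    n_arms: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_rows(df: pd.DataFrame):
    records, errors = [], []
    for i, row in df.iterrows():
        raw_count = row["count"]
        try:
            count_str = str(raw_count).strip()
            count = int(count_str)
        except (TypeError, ValueError):
            errors.append((i, f"count {raw_count!r} is not an integer"))
            continue
        try:
            rec = PlateRecord(
                compound=row["compound"],
                method=row["method"],
                s9=row["s9"],
                vehicle=row["vehicle"],
                strain=row["strain"],
                role=row["role"],
                concentration=float(row["conc_ug_per_plate"]),
                count=count,
                toxicity_note=row.get("toxicity_note", "none"),
            )
        except (TypeError, ValueError) as exc:
            errors.append((i, str(exc)))
            continue
        records.append(rec)
    return records, errors


def parse_plate_table(source) -> list:
    """Parse a canonical plate-count CSV into a list of :class:`PlateRecord`.

    ``source`` is a path, a file object, or a CSV string.  Row order is
    preserved.  Raises :class:`PlateTableError` naming the missing column
    on schema problems, or listing the offending row indices on row-level
    problems (non-integer counts, negative concentrations, unknown enum
    tokens).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise PlateTableError(
            [(None, f"missing required column {c!r}") for c in missing]
        )
    df = df.reset_index(drop=True)
    df.loc[df["toxicity_note"].str.strip() == "", "toxicity_note"] = "none"
    records, errors = _parse_rows(df)
    if errors:
        raise PlateTableError(errors)
    return records


def write_plate_table(records: Iterable[PlateRecord], target) -> None:
    """Write records to the canonical CSV layout (inverse of parse)."""
    df = pd.DataFrame(
        [
            {
                "compound": r.compound,
                "method": r.method,
                "s9": r.s9,
                "vehicle": r.vehicle,
                "strain": r.strain,
                "role": r.role,
                "conc_ug_per_plate": r.concentration,
                "count": r.count,
                "toxicity_note": r.toxicity_note,
            }
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )
    df.to_csv(target, index=False)


def build_arms(records: Iterable[PlateRecord]) -> list:
    """Partition validated records into dose-response arms by design 5-tuple.

    Concurrent vehicle controls (same design, role ``vehicle_control``) are
    attached to each arm; positive controls are excluded from the dose
    series but retained on the arm for validity checks.  Raises
    :class:`PlateTableError` for treated plates without concurrent
    controls.
    """
    treated: dict = {}
    controls: dict = {}
    positives: dict = {}
    for rec in records:
        key = rec.design
        if rec.role == "treated":
            treated.setdefault(key, []).append(rec)
        elif rec.role == "vehicle_control":
            controls.setdefault(key, []).append(rec)
        else:
            positives.setdefault(key, []).append(rec)

    arms = []
    missing = []
    for key in treated:
        if key not in controls:
            missing.append(
                (None, f"treated plates with no concurrent vehicle control: {key}")
            )
            continue
        by_dose: dict = {}
        notes: dict = {}
        for rec in treated[key]:
            by_dose.setdefault(rec.concentration, []).append(rec.count)
            if rec.toxicity_note != "none":
                notes.setdefault(rec.concentration, set()).add(rec.toxicity_note)
        doses = tuple(sorted(by_dose))
        arms.append(
            DoseResponseArm(
                design=key,
                doses=doses,
                treated_counts={d: tuple(by_dose[d]) for d in doses},
                control_counts=tuple(r.count for r in controls[key]),
                toxicity_notes={d: frozenset(s) for d, s in notes.items()},
                positive_control_counts=tuple(
                    r.count for r in positives.get(key, [])
                ),
            )
        )
    if missing:
        raise PlateTableError(missing)
    arms.sort(key=lambda a: a.design)
    return arms


def validate_study(records: Iterable[PlateRecord]) -> ValidationReport:
    """Check a record list against the study's 3/6/2 replicate scheme.

    Structural problems (arms without controls) are errors; deviations from
    three treated replicates per concentration, six vehicle-control
    replicates, and two positive-control replicates are warnings, as are
    exactly duplicated rows.
    """
    records = list(records)
    report = ValidationReport()

    seen: dict = {}
    for i, rec in enumerate(records):
        if rec in seen:
            report.warnings.append(
                (i, f"exact duplicate of row {seen[rec]}")
            )
        else:
            seen[rec] = i

    try:
        arms = build_arms(records)
    except PlateTableError as exc:
        report.errors.extend(exc.errors)
        return report

    report.n_arms = len(arms)
    for arm in arms:
        for dose, counts in arm.treated_counts.items():
            if len(counts) != 3:
                report.warnings.append(
                    (
                        None,
                        f"{arm.design} dose {dose}: {len(counts)} treated "
                        "replicates (expected three replicates)",
                    )
                )
        if len(arm.control_counts) != 6:
            report.warnings.append(
                (
                    None,
                    f"{arm.design}: {len(arm.control_counts)} vehicle-control "
                    "replicates (expected six)",
                )
            )
        if arm.positive_control_counts and len(arm.positive_control_counts) != 2:
            report.warnings.append(
                (
                    None,
                    f"{arm.design}: {len(arm.positive_control_counts)} "
                    "positive-control replicates (expected two)",
                )
            )
    return report
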