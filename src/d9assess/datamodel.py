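"""Domain types and CSV ingestion for annual-pool biota monitoring records.

The unit of observation is one analyte measured in one annual pool sample
(all specimens of one type collected at one site in one year, homogenised
into a single analytical sample).  Records carry their concentration basis
(wet, dry or lipid weight) and a censoring flag: a censored value stores the
limit of quantification (LOQ) and means "measurement at or below LOQ".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import DuplicateError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: multiplicative factor taking one unit of each kind to µg/kg.
#: pg/g is numerically identical to ng/kg (1 pg/g = 1 ng/kg).
UNIT_TO_UG_PER_KG = {
    "mg/kg": 1e3,
    "µg/kg": 1.0,
    "ng/kg": 1e-3,
    "pg/g": 1e-3,
}

_UNIT_ALIASES = {
    "ug/kg": "µg/kg",
    "μg/kg": "µg/kg",  # greek mu vs micro sign
    "mg/kg": "mg/kg",
    "µg/kg": "µg/kg",
    "ng/kg": "ng/kg",
    "pg/g": "pg/g",
    "ng/g": "µg/kg",  # ng/g == µg/kg
}

VALID_BASES = ("wet", "dry", "lipid")

CSV_COLUMNS = [
    "site",
    "species",
    "tissue",
    "year",
    "analyte",
    "value",
    "unit",
    "basis",
    "censored",
    "water_fraction",
    "lipid_fraction",
    "breathing_water_fraction",
]


def normalize_unit(unit: str) -> str:
    """Return the canonical spelling of a concentration unit string."""
    u = unit.strip()
    if u in _UNIT_ALIASES:
        return _UNIT_ALIASES[u]
    raise ValidationError(f"unknown unit {unit!r}; expected one of {sorted(set(_UNIT_ALIASES))}")


def unit_factor(from_unit: str, to_unit: str) -> float:
    """Multiplicative factor converting a value in *from_unit* to *to_unit*."""
    f = normalize_unit(from_unit)
    t = normalize_unit(to_unit)
    return UNIT_TO_UG_PER_KG[f] / UNIT_TO_UG_PER_KG[t]


@dataclass(frozen=True)
class SampleRecord:
    """One analyte measurement in one annual pool sample.

    ``censored=True`` means the stored ``value`` is the LOQ and the true
    concentration is at or below it.  The three optional fractions describe
    the sample matrix: water content of the tissue, lipid content, and the
    share of the pooled wet weight contributed by retained breathing water
    (mussel soft-body pools only).
    """

    site: str
    species: str
    tissue: str
    year: int
    analyte: str
    value: float
    unit: str
    basis: str
    censored: bool = False
    water_fraction: Optional[float] = None
    lipid_fraction: Optional[float] = None
    breathing_water_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(
                f"negative concentration {self.value} for {self.analyte} at {self.site}/{self.year}"
            )
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        if self.basis not in VALID_BASES:
            raise ValidationError(f"basis must be one of {VALID_BASES}, got {self.basis!r}")
        if self.water_fraction is not None and not (0 <= self.water_fraction < 1):
            raise ValidationError(f"water_fraction {self.water_fraction} outside [0, 1)")
        if self.lipid_fraction is not None and not (0 < self.lipid_fraction < 1):
            raise ValidationError(f"lipid_fraction {self.lipid_fraction} outside (0, 1)")
        if self.breathing_water_fraction is not None and not (
            0 <= self.breathing_water_fraction < 1
        ):
            raise ValidationError(
                f"breathing_water_fraction {self.breathing_water_fraction} outside [0, 1)"
            )

    @property
    def series_key(self) -> "SeriesKey":
        return SeriesKey(self.site, self.species, self.tissue, self.analyte, self.basis, self.unit)


@dataclass(frozen=True, order=True)
class SeriesKey:
    """Identity of one monitoring time series."""

    site: str
    species: str
    tissue: str
    analyte: str
    basis: str
    unit: str


@dataclass
class TimeSeries:
    """Ordered year -> concentration sequence for one series key.

    Years are strictly increasing with at most one annual pool per year;
    gaps (e.g. biennial sampling) are permitted and never imputed.
    """

    key: SeriesKey
    points: list[tuple[int, float, bool]]  # (year, value, censored)

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError(f"time series {self.key} has no points")
        years = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError(f"years not strictly increasing in series {self.key}: {years}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def years(self) -> list[int]:
        return [p[0] for p in self.points]

    @property
    def values(self) -> list[float]:
        return [p[1] for p in self.points]

    @property
    def censored(self) -> list[bool]:
        return [p[2] for p in self.points]

    def fit_values(self, censored_substitution: str = "loq") -> list[float]:
        """Values entering a trend fit.

        Censored points enter at their LOQ (``"loq"``, the upper-bound
        convention used throughout) or at LOQ/2 (``"half"``).
        """
        if censored_substitution == "loq":
            return self.values
        if censored_substitution == "half":
            return [v / 2 if c else v for _, v, c in self.points]
        raise ValueError(f"unknown censored_substitution {censored_substitution!r}")


def _parse_bool(text: str, row_no: int) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"row {row_no}: cannot parse boolean {text!r}")


def _parse_optional_fraction(text: str, row_no: int, col: str) -> Optional[float]:
    t = text.strip()
    if t == "":
        return None
    try:
        return float(t)
    except ValueError as exc:
        raise ValidationError(f"row {row_no}: column {col}: not a number: {text!r}") from exc


def read_samples(path, dialect: Optional[dict] = None) -> list[SampleRecord]:
    """Read monitoring records from a headered CSV file.

    Every row is validated; rows violating an invariant are rejected with a
    row-numbered message (the whole read fails, so a file is either fully
    accepted or diagnosed).  An empty data section yields an empty list.
    """
    opts = dict(dialect or {})
    records: list[SampleRecord] = []
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, **opts)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: no header row")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            try:
                rec = SampleRecord(
                    site=row["site"].strip(),
                    species=row["species"].strip(),
                    tissue=row["tissue"].strip(),
                    year=int(row["year"]),
                    analyte=row["analyte"].strip(),
                    value=float(row["value"]),
                    unit=row["unit"],
                    basis=row["basis"].strip(),
                    censored=_parse_bool(row["censored"], row_no),
                    water_fraction=_parse_optional_fraction(
                        row["water_fraction"], row_no, "water_fraction"
                    ),
                    lipid_fraction=_parse_optional_fraction(
                        row["lipid_fraction"], row_no, "lipid_fraction"
                    ),
                    breathing_water_fraction=_parse_optional_fraction(
                        row["breathing_water_fraction"], row_no, "breathing_water_fraction"
                    ),
                )
            except (ValidationError, ValueError) as exc:
                errors.append(f"row {row_no}: {exc}")
                continue
            records.append(rec)
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    if not records:
        logger.warning("%s: no data rows", path)
    seen: dict[tuple, float] = {}
    for rec in records:
        k = (rec.series_key, rec.year)
        if k in seen and seen[k] != rec.value:
            raise DuplicateError(
                f"duplicate measurement for {rec.series_key} year {rec.year}: "
                f"{seen[k]} vs {rec.value}"
            )
        seen[k] = rec.value
    return records


def write_samples(records: Iterable[SampleRecord], path) -> None:
    """Write records to the CSV dialect that :func:`read_samples` reads."""

    def fmt_frac(x: Optional[float]) -> str:
        return "" if x is None else repr(x)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.site,
                    r.species,
                    r.tissue,
                    r.year,
                    r.analyte,
                    repr(r.value),
                    r.unit,
                    r.basis,
                    "true" if r.censored else "false",
                    fmt_frac(r.water_fraction),
                    fmt_frac(r.lipid_fraction),
                    fmt_frac(r.breathing_water_fraction),
                ]
            )


def build_time_series(records: Sequence[SampleRecord]) -> list[TimeSeries]:
    """Group validated records into time series.

    Grouping key is (site, species, tissue, analyte, basis); records in a
    unit other than the group's first-seen unit are converted into it before
    assembly, so one series never mixes scales.  Conflicting duplicate
    (key, year) pairs raise; exact duplicates collapse to one point.
    """
    groups: dict[tuple, list[SampleRecord]] = {}
    first_unit: dict[tuple, str] = {}
    for rec in records:
        gk = (rec.site, rec.species, rec.tissue, rec.analyte, rec.basis)
        if gk not in groups:
            groups[gk] = []
            first_unit[gk] = rec.unit
        if rec.unit != first_unit[gk]:
            f = unit_factor(rec.unit, first_unit[gk])
            rec = replace(rec, value=rec.value * f, unit=first_unit[gk])
        groups[gk].append(rec)

    out: list[TimeSeries] = []
    for gk in sorted(groups):
        recs = groups[gk]
        by_year: dict[int, tuple[float, bool]] = {}
        for r in sorted(recs, key=lambda r: r.year):
            pt = (r.value, r.censored)
            if r.year in by_year and by_year[r.year] != pt:
                raise DuplicateError(
                    f"conflicting values for {r.series_key} year {r.year}: "
                    f"{by_year[r.year][0]} vs {r.value}"
                )
            by_year[r.year] = pt
        key = SeriesKey(*gk[:4], basis=gk[4], unit=first_unit[gk])
        points = [(y, v, c) for y, (v, c) in sorted(by_year.items())]
        out.append(TimeSeries(key=key, points=points))
    return out
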