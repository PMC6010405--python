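"""Long-format field records: dated visitation events and flowering censuses.

The two record types mirror the field protocol of alpine pollination
surveys: transect walks yield one row per (census day, plant, visitor)
with the number of visits observed, and a weekly flowering census yields
one row per (census day, plant) with the number of flowering individuals.
All downstream objects (daily sub-networks, cumulative networks,
phenology tables) are built from these records.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "InteractionRecord",
    "FloweringCensusRecord",
    "FUNCTIONAL_GROUPS",
    "SchemaError",
    "RecordError",
    "read_interactions",
    "read_flowering",
    "read_records",
    "write_interactions",
    "write_flowering",
    "read_mapped",
]

#: The eleven coarse visitor categories used in Mediterranean alpine surveys.
FUNCTIONAL_GROUPS = (
    "Bees",
    "Small Bees",
    "Bumblebees",
    "Butterflies",
    "Hoverflies",
    "Flies",
    "Small flies",
    "Bee Flies",
    "Beetles",
    "Wasps",
    "Others",
)


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unusable."""


class RecordError(ValueError):
    """A single row violates the record contract (bad date, zero visits...)."""


@dataclass(frozen=True, slots=True)
class InteractionRecord:
    """One dated, weighted plant x visitor visitation event batch."""

    census_date: _dt.date
    site: str
    plant: str
    visitor: str
    functional_group: str
    visits: int

    def __post_init__(self) -> None:
        if self.visits < 1:
            raise RecordError(f"visits must be >= 1, got {self.visits}")
        for field in ("site", "plant", "visitor"):
            if not getattr(self, field):
                raise RecordError(f"empty {field!r} label")

    @property
    def day_of_year(self) -> int:
        """Days since 1 January (1 Jan = day 1)."""
        return self.census_date.timetuple().tm_yday


@dataclass(frozen=True, slots=True)
class FloweringCensusRecord:
    """One weekly flowering-census row: flowering individuals of one plant."""

    census_date: _dt.date
    site: str
    plant: str
    n_flowering: int

    def __post_init__(self) -> None:
        if self.n_flowering < 0:
            raise RecordError(f"n_flowering must be >= 0, got {self.n_flowering}")
        if not self.site or not self.plant:
            raise RecordError("empty site or plant label")

    @property
    def day_of_year(self) -> int:
        return self.census_date.timetuple().tm_yday


_INTERACTION_COLS = ("date", "site", "plant", "visitor", "functional_group", "visits")
_FLOWERING_COLS = ("date", "site", "plant", "n_flowering")


def _parse_date(value: str, row_no: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise RecordError(f"row {row_no}: unparseable date {value!r}") from exc


def _sniff_reader(path: Path):
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise SchemaError(f"{path}: empty file")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    return csv.DictReader(text.splitlines(), delimiter=delimiter)


def _check_header(reader: csv.DictReader, required: Sequence[str], path: Path) -> None:
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a delimited interaction file (comma default, tab accepted).

    Rows with zero, missing, or non-integer visit counts are rejected with
    a :class:`RecordError` naming the row.
    """
    path = Path(path)
    reader = _sniff_reader(path)
    _check_header(reader, _INTERACTION_COLS, path)
    out: list[InteractionRecord] = []
    for row_no, row in enumerate(reader, start=2):
        raw = (row.get("visits") or "").strip()
        try:
            visits = int(raw)
        except ValueError as exc:
            raise RecordError(f"{path}: row {row_no}: bad visit count {raw!r}") from exc
        if visits < 1:
            raise RecordError(f"{path}: row {row_no}: visits must be >= 1, got {visits}")
        out.append(
            InteractionRecord(
                census_date=_parse_date(row["date"], row_no),
                site=row["site"].strip(),
                plant=row["plant"].strip(),
                visitor=row["visitor"].strip(),
                functional_group=(row.get("functional_group") or "").strip(),
                visits=visits,
            )
        )
    if not out:
        raise SchemaError(f"{path}: no data rows")
    return out


def read_flowering(path: str | Path) -> list[FloweringCensusRecord]:
    """Read a delimited flowering-census file."""
    path = Path(path)
    reader = _sniff_reader(path)
    _check_header(reader, _FLOWERING_COLS, path)
    out: list[FloweringCensusRecord] = []
    for row_no, row in enumerate(reader, start=2):
        try:
            n = int((row.get("n_flowering") or "").strip())
        except ValueError as exc:
            raise RecordError(f"{path}: row {row_no}: bad count") from exc
        out.append(
            FloweringCensusRecord(
                census_date=_parse_date(row["date"], row_no),
                site=row["site"].strip(),
                plant=row["plant"].strip(),
                n_flowering=n,
            )
        )
    if not out:
        raise SchemaError(f"{path}: no data rows")
    return out


def read_records(path: str | Path, schema: str = "interaction"):
    """Dispatching reader; ``schema`` is 'interaction' or 'flowering'."""
    if schema == "interaction":
        return read_interactions(path)
    if schema == "flowering":
        return read_flowering(path)
    raise ValueError(f"unknown schema {schema!r}")


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_INTERACTION_COLS)
        for r in records:
            writer.writerow(
                [r.census_date.isoformat(), r.site, r.plant, r.visitor, r.functional_group, r.visits]
            )


def write_flowering(records: Iterable[FloweringCensusRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FLOWERING_COLS)
        for r in records:
            writer.writerow([r.census_date.isoformat(), r.site, r.plant, r.n_flowering])


def read_mapped(path: str | Path, mapping: dict[str, str] | str | Path, schema: str = "interaction"):
    """Loader shim for externally deposited data with non-canonical headers.

    ``mapping`` maps canonical column names to the file's own header names,
    either as a dict or as a two-column ``canonical,actual`` CSV file that
    the user can edit to fit a given deposit.
    """
    if not isinstance(mapping, dict):
        mapping = {
            row[0].strip(): row[1].strip()
            for row in csv.reader(Path(mapping).read_text(encoding="utf-8").splitlines())
            if len(row) >= 2 and row[0].strip() and not row[0].startswith("#")
        }
    path = Path(path)
    reader = _sniff_reader(path)
    header = reader.fieldnames or []
    import io
    import tempfile

    required = _INTERACTION_COLS if schema == "interaction" else _FLOWERING_COLS
    rename = {mapping.get(c, c): c for c in required}
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow([rename.get(h.strip(), h.strip()) for h in header])
    for row in reader:
        writer.writerow([row[h] for h in header])
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False, encoding="utf-8") as fh:
        fh.write(buf.getvalue())
        tmp = fh.name
    try:
        return read_records(tmp, schema)
    finally:
        Path(tmp).unlink(missing_ok=True)
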