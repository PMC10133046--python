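"""Record schemas for the device registry and the safety-notice set, plus CSV I/O.

Two tabular inputs are handled: the registry of devices on the market (one
row per registration, keyed by a progressive registration number) and the
set of scraped safety notices (one row per notice, keyed by a reference
number, with an optional device-directory identifier in the ``bdrmd``
column).  Identifiers printed with thousands separators ("1,678,555") are
canonicalized to plain digit strings at ingest so that registry matching is
locale-independent.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "DeviceRecord",
    "NoticeRecord",
    "LinkResult",
    "SchemaError",
    "RowError",
    "DEVICE_COLUMNS",
    "NOTICE_COLUMNS",
    "LINK_COLUMNS",
    "read_devices",
    "read_notices",
    "write_devices",
    "write_notices",
    "write_links",
    "read_links",
    "strip_separators",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from a CSV header."""


class RowError(ValueError):
    """A row could not be parsed; carries the 1-based row number."""

    def __init__(self, row_number: int, message: str):
        super().__init__(f"row {row_number}: {message}")
        self.row_number = row_number


#: Default (English) column names; the real sources are Italian, so the
#: mapping is configuration.
DEVICE_COLUMNS: dict[str, str] = {
    "device_type": "Type",
    "progressive_id": "Progressive DM/ASS",
    "manufacturer": "Manufacturer/assembler",
    "catalogue_code": "Catalogue code",
    "commercial_name": "Commercial name",
    "emdn_code": "Classification CND/EMDN",
}

NOTICE_COLUMNS: dict[str, str] = {
    "manufacturer": "Manufacturer",
    "device": "Device",
    "commercial_name": "Commercial name",
    "notice_type": "Type",
    "action": "Action",
    "reference_number": "Reference number",
    "date": "Date",
    "bdrmd": "BD/RMD",
}

LINK_COLUMNS = (
    "reference_number",
    "matched_progressive_id",
    "provenance",
    "score",
    "accepted_threshold",
    "emdn_code",
)


@dataclass
class DeviceRecord:
    """One registry entry (a registration, not necessarily a unique device)."""

    progressive_id: str
    manufacturer: str
    catalogue_code: str
    commercial_name: str
    device_type: str = ""
    emdn_code: str = ""


@dataclass
class NoticeRecord:
    """One safety notice scraped from the vigilance website."""

    reference_number: str
    manufacturer: str
    device: str
    commercial_name: str
    notice_type: str = ""
    action: str = ""
    date: Optional[_dt.date] = None
    bdrmd: Optional[str] = None


@dataclass
class LinkResult:
    """Outcome of resolving one notice against the registry.

    ``provenance`` is ``direct`` (identifier lookup), ``er`` (two-phase
    entity resolution) or ``unmatched``; direct links carry no similarity
    score, ER links satisfy ``score >= accepted_threshold``, and unmatched
    results carry a ``failure_reason``.
    """

    reference_number: str
    provenance: str
    device_id: Optional[str] = None
    emdn_code: Optional[str] = None
    score: Optional[int] = None
    accepted_threshold: Optional[int] = None
    failure_reason: Optional[str] = None
    matched_manufacturer: Optional[str] = field(default=None, repr=False)


def strip_separators(identifier: str) -> str:
    """Remove thousands separators ("." and ",") and whitespace from an id."""
    return identifier.replace(",", "").replace(".", "").replace(" ", "").strip()


def _resolve_header(
    header: Sequence[str], columns: dict[str, str], what: str
) -> dict[str, int]:
    index = {}
    for field_name, col_name in columns.items():
        try:
            index[field_name] = header.index(col_name)
        except ValueError:
            raise SchemaError(f"{what} file is missing required column {col_name!r}") from None
    return index


def read_devices(
    path: str,
    columns: Optional[dict[str, str]] = None,
    delimiter: str = ",",
) -> list[DeviceRecord]:
    """Read registry rows from *path*.

    Thousands separators are stripped from ``progressive_id``.  Duplicate
    progressive ids are retained (re-registration of the same device under a
    new number is a real phenomenon) but logged.
    """
    columns = DEVICE_COLUMNS if columns is None else columns
    records: list[DeviceRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("device file is empty") from None
        idx = _resolve_header(header, columns, "device")
        for row_number, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rec = DeviceRecord(
                    progressive_id=strip_separators(row[idx["progressive_id"]]),
                    manufacturer=row[idx["manufacturer"]].strip(),
                    catalogue_code=row[idx["catalogue_code"]].strip(),
                    commercial_name=row[idx["commercial_name"]].strip(),
                    device_type=row[idx["device_type"]].strip(),
                    emdn_code=row[idx["emdn_code"]].strip(),
                )
            except IndexError:
                raise RowError(row_number, f"expected {len(header)} fields, got {len(row)}")
            if not rec.progressive_id:
                raise RowError(row_number, "empty progressive id")
            if rec.progressive_id in seen:
                logger.warning("duplicate progressive id %s at row %d (retained)",
                               rec.progressive_id, row_number)
            seen.add(rec.progressive_id)
            records.append(rec)
    return records


def read_notices(
    path: str,
    columns: Optional[dict[str, str]] = None,
    delimiter: str = ",",
    date_format: str = "%Y-%m-%d",
) -> list[NoticeRecord]:
    """Read notice rows from *path* in file order.

    Empty ``bdrmd`` cells become ``None``; populated ones are stripped of
    separators.  A duplicate reference number triggers a warning and the
    first occurrence is kept.
    """
    columns = NOTICE_COLUMNS if columns is None else columns
    records: list[NoticeRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("notice file is empty") from None
        idx = _resolve_header(header, columns, "notice")
        for row_number, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                raw_date = row[idx["date"]].strip()
                raw_bdrmd = strip_separators(row[idx["bdrmd"]])
                rec = NoticeRecord(
                    reference_number=row[idx["reference_number"]].strip(),
                    manufacturer=row[idx["manufacturer"]].strip(),
                    device=row[idx["device"]].strip(),
                    commercial_name=row[idx["commercial_name"]].strip(),
                    notice_type=row[idx["notice_type"]].strip(),
                    action=row[idx["action"]].strip(),
                    bdrmd=raw_bdrmd or None,
                )
            except IndexError:
                raise RowError(row_number, f"expected {len(header)} fields, got {len(row)}")
            if raw_date:
                try:
                    rec.date = _dt.datetime.strptime(raw_date, date_format).date()
                except ValueError:
                    raise RowError(row_number, f"malformed date {raw_date!r}") from None
            if rec.bdrmd is not None and not rec.bdrmd.isdigit():
                raise RowError(row_number, f"non-numeric BD/RMD {row[idx['bdrmd']]!r}")
            if rec.reference_number in seen:
                logger.warning("duplicate reference number %s at row %d (keeping first)",
                               rec.reference_number, row_number)
                continue
            seen.add(rec.reference_number)
            records.append(rec)
    return records


def write_devices(records: Iterable[DeviceRecord], path: str,
                  columns: Optional[dict[str, str]] = None) -> None:
    columns = DEVICE_COLUMNS if columns is None else columns
    fields = list(columns)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([columns[f] for f in fields])
        for rec in records:
            writer.writerow([getattr(rec, f) for f in fields])


def write_notices(records: Iterable[NoticeRecord], path: str,
                  columns: Optional[dict[str, str]] = None,
                  date_format: str = "%Y-%m-%d") -> None:
    columns = NOTICE_COLUMNS if columns is None else columns
    fields = list(columns)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([columns[f] for f in fields])
        for rec in records:
            row = []
            for f in fields:
                value = getattr(rec, f)
                if f == "date":
                    value = value.strftime(date_format) if value else ""
                elif value is None:
                    value = ""
                row.append(value)
            writer.writerow(row)


def write_links(links: Sequence[LinkResult], path: str) -> None:
    """Write the link table in input order with the fixed column set."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LINK_COLUMNS)
        for link in links:
            writer.writerow([
                link.reference_number,
                link.device_id or "",
                link.provenance,
                "" if link.score is None else link.score,
                "" if link.accepted_threshold is None else link.accepted_threshold,
                link.emdn_code or "",
            ])


def read_links(path: str) -> list[LinkResult]:
    """Read a link table written by :func:`write_links`."""
    links: list[LinkResult] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(LINK_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"link file is missing columns: {sorted(missing)}")
        for row in reader:
            links.append(LinkResult(
                reference_number=row["reference_number"],
                provenance=row["provenance"],
                device_id=row["matched_progressive_id"] or None,
                emdn_code=row["emdn_code"] or None,
                score=int(row["score"]) if row["score"] else None,
                accepted_threshold=(int(row["accepted_threshold"])
                                    if row["accepted_threshold"] else None),
            ))
    return links
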