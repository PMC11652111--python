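"""Reading, standardising and cleaning occurrence records.

Occurrence data for elevational-gradient studies typically mix herbarium
specimens, plot surveys and literature records. Before any diversity index
can be computed the records must (a) carry a usable elevation, (b) be
deduplicated, and (c) have their taxon names resolved against an accepted
backbone. Name resolution here goes through a local, user-supplied synonym
table rather than online services, so runs are reproducible offline.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord",
    "TaxonRecord",
    "CleaningReport",
    "read_occurrences",
    "read_synonym_table",
    "read_taxonomy",
    "read_alien_list",
    "clean_occurrences",
    "tag_native_status",
]


@dataclass
class OccurrenceRecord:
    """One specimen / plot / literature observation of a taxon on a mountain.

    ``elevation_m`` is ``None`` when the source row had no parseable
    elevation; such records survive reading (missingness is data, not an
    error) and are removed, and counted, during cleaning.
    """

    taxon_name: str
    mountain_id: str
    elevation_m: float | None
    source: str | None = None
    out_of_span: bool = False


@dataclass(frozen=True)
class TaxonRecord:
    """Accepted name with its genus/family placement and native status."""

    accepted_name: str
    genus: str
    family: str
    native_status: str = "native"


@dataclass
class CleaningReport:
    """Counts of every removal class applied by :func:`clean_occurrences`.

    Satisfies the exact identity::

        kept = input - no_elevation - out_of_span_dropped
                     - duplicates - unresolved_dropped
    """

    input: int = 0
    no_elevation: int = 0
    out_of_span_dropped: int = 0
    duplicates: int = 0
    unresolved: int = 0
    unresolved_dropped: int = 0
    kept: int = 0
    unresolved_names: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _parse_elevation(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        e = float(s)
    except ValueError:
        return None
    if not math.isfinite(e):
        return None
    return e


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    spans: Mapping[str, tuple[float, float]] | None = None,
) -> list[OccurrenceRecord]:
    """Read delimited-text occurrence records.

    Parameters
    ----------
    path:
        UTF-8 delimited text file with a header row. Comma or tab delimited;
        auto-detected unless ``sep`` is given.
    column_map:
        Maps the logical columns ``taxon``, ``mountain``, ``elevation``
        (required) and ``source`` (optional) to header names in the file.
        Defaults to identity names ``taxon, mountain, elevation, source``.
    spans:
        Optional declared elevation span per mountain, ``{mountain_id:
        (lo, hi)}``. Records falling outside their mountain's span are
        flagged ``out_of_span`` (not dropped here).

    Unparseable elevations are kept with ``elevation_m=None`` rather than
    silently dropped; cleaning accounts for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {"taxon": "taxon", "mountain": "mountain", "elevation": "elevation", "source": "source"}
    if column_map:
        cmap.update(column_map)

    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            head = fh.readline()
            while head.startswith("#"):
                head = fh.readline()
        sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","

    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("occurrence file %s is empty", path)
        return []
    if df.empty and df.columns.size == 0:
        logger.warning("occurrence file %s is empty", path)
        return []
    for logical in ("taxon", "mountain", "elevation"):
        if cmap[logical] not in df.columns:
            raise KeyError(
                f"required column {logical!r} (mapped to {cmap[logical]!r}) "
                f"not found in {path.name}; columns present: {list(df.columns)}"
            )
    has_source = cmap.get("source") in df.columns

    records: list[OccurrenceRecord] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        elev = _parse_elevation(row[cmap["elevation"]])
        rec = OccurrenceRecord(
            taxon_name=str(row[cmap["taxon"]]).strip(),
            mountain_id=str(row[cmap["mountain"]]).strip(),
            elevation_m=elev,
            source=str(row[cmap["source"]]).strip() if has_source else None,
        )
        if spans is not None and elev is not None and rec.mountain_id in spans:
            lo, hi = spans[rec.mountain_id]
            if not (lo <= elev <= hi):
                rec.out_of_span = True
        records.append(rec)
    if not records:
        logger.warning("occurrence file %s contained a header but no rows", path)
    return records


def read_synonym_table(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Load a two-column raw-name -> accepted-name table.

    The mapping must be acyclic in the trivial sense used here: an accepted
    name either maps to itself or does not appear as a key.
    """
    path = Path(path)
    table: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = sep or ("\t" if "\t" in sample else ",")
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None:
            return table
        for row in reader:
            if len(row) < 2:
                continue
            raw, acc = row[0].strip(), row[1].strip()
            if raw and acc:
                table[raw] = acc
    for raw, acc in table.items():
        if acc in table and table[acc] != acc:
            raise ValueError(f"synonym chain detected: {raw!r} -> {acc!r} -> {table[acc]!r}")
    return table


def read_taxonomy(path: str | Path, sep: str | None = None) -> list[TaxonRecord]:
    """Load an accepted-name backbone (accepted_name, genus, family[, native_status])."""
    df = pd.read_csv(path, sep=sep or ",", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            TaxonRecord(
                accepted_name=d["accepted_name"].strip(),
                genus=d["genus"].strip(),
                family=d["family"].strip(),
                native_status=d.get("native_status", "native").strip() or "native",
            )
        )
    names = [t.accepted_name for t in out]
    if len(names) != len(set(names)):
        raise ValueError("duplicate accepted_name entries in taxonomy table")
    return out


def read_alien_list(path: str | Path) -> set[str]:
    """Load a one-column list of non-native (alien) accepted names."""
    with open(path, "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def clean_occurrences(
    records: Sequence[OccurrenceRecord],
    synonyms: Mapping[str, str] | None = None,
    taxonomy: Sequence[TaxonRecord] | None = None,
    drop_unresolved: bool = False,
    keep_out_of_span: bool = False,
) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Standardise names and remove unusable and duplicate records.

    Pipeline order:

    1. map raw names through the synonym table (never touches mountain or
       elevation);
    2. drop records lacking an elevation;
    3. drop records flagged outside their mountain's declared span (unless
       ``keep_out_of_span``);
    4. collapse exact duplicates — identical (accepted name, mountain,
       elevation rounded to 1 m) — keeping the first;
    5. report names absent from ``taxonomy`` and drop them only when
       ``drop_unresolved`` is requested.

    The operation is idempotent and the report counts satisfy an exact
    bookkeeping identity (see :class:`CleaningReport`).
    """
    report = CleaningReport(input=len(records))
    synonyms = synonyms or {}
    known = {t.accepted_name for t in taxonomy} if taxonomy else None

    mapped: list[OccurrenceRecord] = []
    for r in records:
        name = synonyms.get(r.taxon_name, r.taxon_name)
        mapped.append(
            OccurrenceRecord(name, r.mountain_id, r.elevation_m, r.source, r.out_of_span)
        )

    kept: list[OccurrenceRecord] = []
    seen: set[tuple[str, str, int]] = set()
    unresolved_names: set[str] = set()
    for r in mapped:
        if r.elevation_m is None:
            report.no_elevation += 1
            continue
        if r.out_of_span and not keep_out_of_span:
            report.out_of_span_dropped += 1
            continue
        key = (r.taxon_name, r.mountain_id, int(math.floor(r.elevation_m + 0.5)))
        if key in seen:
            report.duplicates += 1
            continue
        seen.add(key)
        if known is not None and r.taxon_name not in known:
            unresolved_names.add(r.taxon_name)
            if drop_unresolved:
                report.unresolved_dropped += 1
                continue
        kept.append(r)

    report.unresolved = len(unresolved_names)
    report.unresolved_names = sorted(unresolved_names)
    report.kept = len(kept)
    if unresolved_names:
        logger.info("%d names unresolved against taxonomy", len(unresolved_names))
    logger.info("cleaning report: %s", report.to_json())
    if not kept:
        raise ValueError("no usable records after cleaning")
    return kept, report


def tag_native_status(
    records: Iterable[OccurrenceRecord], alien_list: set[str]
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Partition records into (native, non_native) by accepted name.

    The label is a pure function of the accepted name: a record is
    non-native iff its taxon appears in ``alien_list``.
    """
    native, non_native = [], []
    for r in records:
        (non_native if r.taxon_name in alien_list else native).append(r)
    return native, non_native
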