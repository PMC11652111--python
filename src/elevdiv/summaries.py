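"""Per-mountain taxonomic summaries and cross-mountain statistics."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ingest import OccurrenceRecord, TaxonRecord

logger = logging.getLogger(__name__)

__all__ = ["MountainSummary", "summarize_mountain", "cross_mountain_stats", "summary_table"]


@dataclass(frozen=True)
class MountainSummary:
    mountain_id: str
    n_species: int
    n_genera: int
    n_families: int
    n_records: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_mountain(
    records: Sequence[OccurrenceRecord],
    taxonomy: Sequence[TaxonRecord] | Mapping[str, TaxonRecord] | None = None,
    mountain_id: str | None = None,
) -> MountainSummary:
    """Count distinct species, genera and families among cleaned records.

    Species lacking a taxonomy entry are still counted as species; their
    genus/family contribute only when known (a warning notes how many were
    unplaced).
    """
    if not records:
        raise ValueError("no records to summarize")
    if mountain_id is None:
        ids = {r.mountain_id for r in records}
        if len(ids) != 1:
            raise ValueError(f"records span multiple mountains {sorted(ids)}; pass mountain_id")
        mountain_id = ids.pop()
    if taxonomy is None:
        tax: Mapping[str, TaxonRecord] = {}
    elif isinstance(taxonomy, Mapping):
        tax = taxonomy
    else:
        tax = {t.accepted_name: t for t in taxonomy}

    species = {r.taxon_name for r in records}
    genera, families, unplaced = set(), set(), 0
    for s in species:
        t = tax.get(s)
        if t is None:
            unplaced += 1
            continue
        if t.genus:
            genera.add(t.genus)
        if t.family:
            families.add(t.family)
    if unplaced:
        logger.warning(
            "%d species on %s have no genus/family placement; counted as species only",
            unplaced, mountain_id,
        )
    return MountainSummary(mountain_id, len(species), len(genera), len(families), len(records))


def cross_mountain_stats(summaries: Sequence[MountainSummary]) -> dict[str, dict[str, int]]:
    """Min / max / mean (rounded half-up to integer) of each taxonomic rank.

    Half-up rounding is used for the means so that e.g. 1977.5 -> 1978.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    out = {}
    for rank, attr in (
        ("species", "n_species"),
        ("genus", "n_genera"),
        ("family", "n_families"),
    ):
        vals = [getattr(s, attr) for s in summaries]
        out[rank] = {
            "min": min(vals),
            "max": max(vals),
            "mean": _round_half_up(sum(vals) / len(vals)),
        }
    return out


def summary_table(summaries: Sequence[MountainSummary]) -> pd.DataFrame:
    """Per-mountain counts plus a min/max/mean footer, as one tidy table."""
    df = pd.DataFrame(
        {
            "mountain_id": [s.mountain_id for s in summaries],
            "n_species": [s.n_species for s in summaries],
            "n_genera": [s.n_genera for s in summaries],
            "n_families": [s.n_families for s in summaries],
            "n_records": [s.n_records for s in summaries],
        }
    )
    stats = cross_mountain_stats(summaries)
    for stat in ("min", "max", "mean"):
        df.loc[len(df)] = {
            "mountain_id": stat,
            "n_species": stats["species"][stat],
            "n_genera": stats["genus"][stat],
            "n_families": stats["family"][stat],
            "n_records": pd.NA,
        }
    return df
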