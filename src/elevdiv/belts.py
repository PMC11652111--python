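"""Elevational belt construction and the belt x taxon presence matrix.

A mountain's gradient is partitioned into fixed-width belts (100 m by
default, the convention in elevational-gradient studies) and each belt is
treated as one community sample. Belts are half-open intervals ``[lo, hi)``
with the summit belt closed at the top, so a record at an exact belt
boundary is counted once.

Two occupancy rules are supported:

``record``
    a species occupies exactly the belts that contain at least one of its
    records — faithful to the specimen evidence;
``range_through``
    a species occupies every belt intersecting the interval between its
    lowest and highest record — the interpolation convention common in
    elevational-gradient work.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import OccurrenceRecord

logger = logging.getLogger(__name__)

__all__ = ["BeltGrid", "BeltMatrix", "build_grid", "assign_belts", "attach_areas"]


@dataclass(frozen=True)
class BeltGrid:
    mountain_id: str
    min_elev_m: float
    max_elev_m: float
    belt_width_m: float = 100.0
    # (lo, hi) pairs tiling [min, max]; the last belt may be narrower
    belts: tuple[tuple[float, float], ...] = field(default=(), compare=False)

    @property
    def n_belts(self) -> int:
        return len(self.belts)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.belts])

    @property
    def lower_bounds(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.belts])

    def belt_index(self, elevation_m: float) -> int:
        """Index of the belt containing an elevation; half-open convention,
        summit belt closed. Raises ``ValueError`` outside the span."""
        if not (self.min_elev_m <= elevation_m <= self.max_elev_m):
            raise ValueError(
                f"elevation {elevation_m} m outside span "
                f"[{self.min_elev_m}, {self.max_elev_m}] of {self.mountain_id}"
            )
        if elevation_m == self.max_elev_m:
            return self.n_belts - 1
        return int((elevation_m - self.min_elev_m) // self.belt_width_m)


def build_grid(
    mountain_id: str,
    min_elev_m: float,
    max_elev_m: float,
    belt_width_m: float = 100.0,
) -> BeltGrid:
    """Tile ``[min_elev_m, max_elev_m]`` with ``ceil(span/width)`` belts.

    The grid is anchored at the mountain's declared minimum, and the topmost
    belt is truncated at ``max_elev_m`` (e.g. a 0-1480 m span at 100 m width
    yields 15 belts, the last being [1400, 1480]).
    """
    if max_elev_m <= min_elev_m:
        raise ValueError(f"degenerate span: max {max_elev_m} <= min {min_elev_m}")
    if belt_width_m <= 0:
        raise ValueError("belt width must be positive")
    n = math.ceil((max_elev_m - min_elev_m) / belt_width_m)
    belts = tuple(
        (min_elev_m + i * belt_width_m, min(min_elev_m + (i + 1) * belt_width_m, max_elev_m))
        for i in range(n)
    )
    return BeltGrid(mountain_id, min_elev_m, max_elev_m, belt_width_m, belts)


@dataclass
class BeltMatrix:
    """Presence/absence of taxa across the ordered belts of one mountain.

    ``presence`` is a 0/1 DataFrame; rows are belts in ascending elevation
    (indexed by belt lower bound), columns are accepted taxon names. Every
    taxon column has at least one presence. ``occupancy_mode`` records which
    rule produced the matrix so downstream outputs can echo it.
    """

    grid: BeltGrid
    presence: pd.DataFrame
    occupancy_mode: str = "record"
    belt_area_km2: pd.Series | None = None

    @property
    def taxa(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def richness(self) -> pd.Series:
        """Species richness (SR) per belt."""
        return self.presence.sum(axis=1).astype(int)

    def belt_taxa(self, i: int) -> set[str]:
        row = self.presence.iloc[i]
        return set(row.index[row.to_numpy(dtype=bool)])

    def restrict_taxa(self, taxa: Iterable[str]) -> "BeltMatrix":
        cols = [t for t in self.presence.columns if t in set(taxa)]
        sub = self.presence[cols]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        return BeltMatrix(self.grid, sub, self.occupancy_mode, self.belt_area_km2)

    def to_wide_csv(self, path: str | Path) -> None:
        meta = pd.DataFrame(
            {
                "belt_lo": [lo for lo, _ in self.grid.belts],
                "belt_hi": [hi for _, hi in self.grid.belts],
                "midpoint": self.grid.midpoints,
            },
            index=self.presence.index,
        )
        if self.belt_area_km2 is not None:
            meta["area_km2"] = self.belt_area_km2.to_numpy()
        pd.concat([meta, self.presence], axis=1).to_csv(path, index=False)

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        for i, (lo, _hi) in enumerate(self.grid.belts):
            for t in sorted(self.belt_taxa(i)):
                rows.append((lo, t))
        pd.DataFrame(rows, columns=["belt_lo", "taxon"]).to_csv(path, sep="\t", index=False)


def assign_belts(
    records: Sequence[OccurrenceRecord],
    grid: BeltGrid,
    mode: str = "record",
    keep_out_of_span: bool = False,
) -> BeltMatrix:
    """Build the belt x taxon presence matrix from cleaned records.

    ``keep_out_of_span`` skips (with a warning) records whose elevation
    falls outside the grid instead of raising.
    """
    if mode not in ("record", "range_through"):
        raise ValueError(f"unknown occupancy mode {mode!r}")
    by_taxon: dict[str, list[int]] = {}
    skipped = 0
    for r in records:
        if r.elevation_m is None:
            raise ValueError(f"record of {r.taxon_name!r} lacks elevation; clean first")
        try:
            idx = grid.belt_index(r.elevation_m)
        except ValueError:
            if keep_out_of_span:
                skipped += 1
                continue
            raise
        by_taxon.setdefault(r.taxon_name, []).append(idx)
    if skipped:
        logger.warning("%d records outside the %s grid span were skipped", skipped, grid.mountain_id)
    if not by_taxon:
        raise ValueError("no records fall within the belt grid")

    taxa = sorted(by_taxon)
    presence = np.zeros((grid.n_belts, len(taxa)), dtype=np.int8)
    for j, t in enumerate(taxa):
        idxs = by_taxon[t]
        if mode == "record":
            presence[idxs, j] = 1
        else:
            presence[min(idxs) : max(idxs) + 1, j] = 1
    df = pd.DataFrame(presence, index=grid.lower_bounds, columns=taxa)
    df.index.name = "belt_lo"
    return BeltMatrix(grid, df, occupancy_mode=mode)


def attach_areas(matrix: BeltMatrix, area_table: pd.DataFrame) -> BeltMatrix:
    """Attach per-belt areas (km^2) from a table keyed by (mountain_id, belt_lo).

    Every belt of the grid must be present with a strictly positive area.
    """
    sub = area_table[area_table["mountain_id"] == matrix.grid.mountain_id]
    areas = dict(zip(sub["belt_lo"].astype(float), sub["area_km2"].astype(float)))
    missing = [lo for lo in matrix.grid.lower_bounds if lo not in areas]
    if missing:
        raise ValueError(
            f"area table missing belts {missing} for mountain {matrix.grid.mountain_id!r}"
        )
    vals = np.array([areas[lo] for lo in matrix.grid.lower_bounds])
    if np.any(vals <= 0):
        bad = [lo for lo, v in zip(matrix.grid.lower_bounds, vals) if v <= 0]
        raise ValueError(f"non-positive belt areas at belt_lo={bad}")
    series = pd.Series(vals, index=matrix.presence.index, name="area_km2")
    return BeltMatrix(matrix.grid, matrix.presence, matrix.occupancy_mode, series)
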