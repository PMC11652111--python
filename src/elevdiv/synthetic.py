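"""Synthetic mountains: phylogenies, elevational ranges and occurrence files.

The generator produces everything one mountain's analysis consumes — a
Yule phylogeny, per-species elevational ranges, record-level occurrence
data with the cleaning hazards real herbarium data show (duplicate rows,
missing elevations), belt-area profiles and a non-native species subset —
plus a truth record so recovery can be tested end to end.

Range scenarios encode the assembly processes the analysis is meant to
detect:

``neutral``
    range midpoints uniform on the span, widths lognormal, clipped to the
    span (the clipping alone induces a mid-domain richness hump);
``filter_low`` / ``filter_high``
    one clade (>= 20% of tips) confined to the bottom / top third of the
    span — habitat filtering, which should surface as phylogenetic
    clustering (NRI > 0) in the corresponding belts;
``mid_peak`` / ``monotonic_decrease``
    midpoint densities shaped so expected belt richness is hump-shaped /
    monotone decreasing, the two gradient forms subtropical mountains show.

Defaults emulate a mid-sized subtropical mountain at herbarium sampling
intensity: 200 species over a 0-2000 m span, ~12 records per species
(real mountains of this kind yield roughly 5-17 records per species),
a 10% duplicate rate and 5% missing elevations.

All randomness in a run flows from one seed through
``numpy.random.SeedSequence``-derived child streams, and the seed is
echoed in every emitted file header.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .belts import BeltGrid, build_grid

__all__ = [
    "ScenarioConfig",
    "SyntheticMountain",
    "simulate_tree",
    "simulate_ranges",
    "simulate_occurrences",
    "simulate_belt_areas",
    "assign_nonnatives",
    "simulate_mountain",
    "write_mountain",
]

SCENARIOS = ("neutral", "filter_low", "filter_high", "mid_peak", "monotonic_decrease")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic mountain."""

    n_species: int = 200
    min_elev: float = 0.0
    max_elev: float = 2000.0
    scenario: str = "neutral"
    records_per_species: float = 12.0
    elevation_noise_sd_m: float = 0.0
    duplicate_rate: float = 0.10
    missing_elevation_rate: float = 0.05
    nonnative_fraction: float = 0.05
    nonnative_coupling: float = 0.8
    belt_width_m: float = 100.0
    mountain_id: str = "synthetic"
    # lognormal range widths: median fraction of the span, log-sd
    range_width_frac: float = 0.25
    range_width_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.max_elev <= self.min_elev:
            raise ValueError("span must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for name in ("duplicate_rate", "missing_elevation_rate", "nonnative_fraction",
                     "nonnative_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def span(self) -> float:
        return self.max_elev - self.min_elev


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` extant tips.

    Tips are relabelled ``sp0001 ...`` in a deterministic traversal order,
    so identical seeds give identical Newick strings.
    """
    if n_species < 2:
        raise ValueError("need >= 2 species for a tree")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=random.Random(seed),
    )
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(label=f"sp{i:04d}")
    tree.taxon_namespace = ns
    return tree


def _clade_tip_sets(tree: dendropy.Tree) -> list[list[str]]:
    out = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        out.append([l.taxon.label for l in node.leaf_iter()])
    return out


def _draw_width(rng: np.random.Generator, span: float, cfg: ScenarioConfig) -> float:
    w = float(np.exp(rng.normal(math.log(cfg.range_width_frac * span), cfg.range_width_log_sd)))
    return min(w, span)


def _clip_range(mid: float, width: float, lo_bound: float, hi_bound: float) -> tuple[float, float]:
    lo = max(lo_bound, mid - width / 2.0)
    hi = min(hi_bound, mid + width / 2.0)
    if hi <= lo:  # degenerate after clipping; give a sliver
        lo = max(lo_bound, min(mid, hi_bound - 1e-6))
        hi = min(hi_bound, lo + 1e-6)
    return lo, hi


def simulate_ranges(
    tree: dendropy.Tree, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> dict[str, tuple[float, float]]:
    """Per-species elevational ranges ``{label: (lo, hi)}`` under a scenario."""
    rng = rng if rng is not None else np.random.default_rng(_child_seeds(config.seed, 2)[1])
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    n = len(labels)
    lo_b, hi_b, span = config.min_elev, config.max_elev, config.span

    confined: set[str] = set()
    if config.scenario in ("filter_low", "filter_high"):
        candidates = [
            tips for tips in _clade_tip_sets(tree) if 0.2 * n <= len(tips) <= 0.5 * n
        ]
        if not candidates:
            raise ValueError(
                "no clade with 20-50% of tips available for the filtering scenario"
            )
        confined = set(candidates[rng.integers(len(candidates))])

    third = span / 3.0
    ranges: dict[str, tuple[float, float]] = {}
    for lab in labels:
        if lab in confined:
            if config.scenario == "filter_high":
                b_lo, b_hi = hi_b - third, hi_b
            else:
                b_lo, b_hi = lo_b, lo_b + third
            mid = rng.uniform(b_lo, b_hi)
            width = min(_draw_width(rng, third, config), third)
            ranges[lab] = _clip_range(mid, width, b_lo, b_hi)
            continue
        if config.scenario == "mid_peak":
            mid = lo_b + span * rng.beta(2.5, 2.5)
        elif config.scenario == "monotonic_decrease":
            # Monotone decline is nested attrition: most species reach the
            # base and their upper limits thin out with elevation; a minority
            # are narrow lowland specialists. (A pure midpoint-density model
            # cannot put the richness peak in the bottom belt: geometric
            # range overlap always depresses the domain edge.)
            if rng.random() < 0.8:
                hi = lo_b + span * float(rng.beta(1.0, 2.5))
                ranges[lab] = (lo_b, max(hi, lo_b + 1e-6))
            else:
                mid = lo_b + span * float(rng.beta(1.0, 8.0))
                width = float(
                    np.exp(rng.normal(math.log(0.1 * span), config.range_width_log_sd))
                )
                ranges[lab] = _clip_range(mid, width, lo_b, hi_b)
            continue
        else:  # neutral and the unconfined part of filter scenarios
            mid = rng.uniform(lo_b, hi_b)
        width = _draw_width(rng, span, config)
        ranges[lab] = _clip_range(mid, width, lo_b, hi_b)
    return ranges


def simulate_occurrences(
    ranges: dict[str, tuple[float, float]],
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Raw occurrence table plus a truth record.

    Per species the record count is Poisson(``records_per_species``) with
    elevations uniform within the range plus optional Gaussian noise,
    clipped to the span. Each base record is then duplicated (an exact
    copy appended) with probability ``duplicate_rate`` and elevations are
    blanked with probability ``missing_elevation_rate``.

    The truth record stores, per species, the intended range and the belt
    occupancy implied by the records whose elevations survive blanking —
    the information content cleaning can actually recover. With zero
    sampling noise the pipeline (range_through occupancy) must reproduce
    it exactly, whatever the duplicate/missing rates.
    """
    rng = rng if rng is not None else np.random.default_rng(_child_seeds(config.seed, 3)[2])
    rows: list[tuple[str, float | None]] = []
    for lab in sorted(ranges):
        lo, hi = ranges[lab]
        k = int(rng.poisson(config.records_per_species))
        if k == 0:
            continue
        elevs = rng.uniform(lo, hi, size=k)
        if config.elevation_noise_sd_m > 0:
            elevs = elevs + rng.normal(0.0, config.elevation_noise_sd_m, size=k)
        elevs = np.clip(elevs, config.min_elev, config.max_elev)
        for e in elevs:
            rows.append((lab, float(e)))

    # duplicate injection: exact copies of base records
    n_base = len(rows)
    dup_mask = rng.random(n_base) < config.duplicate_rate
    rows.extend(rows[i] for i in np.flatnonzero(dup_mask))
    # blanking: elevations lost at missing_elevation_rate
    miss_mask = rng.random(len(rows)) < config.missing_elevation_rate
    rows = [(lab, None if m else e) for (lab, e), m in zip(rows, miss_mask)]

    grid = build_grid(config.mountain_id, config.min_elev, config.max_elev, config.belt_width_m)
    surviving: dict[str, list[float]] = {}
    for lab, e in rows:
        if e is not None:
            surviving.setdefault(lab, []).append(e)
    truth_species = {}
    for lab in sorted(ranges):
        entry: dict = {
            "intended_lo": ranges[lab][0],
            "intended_hi": ranges[lab][1],
        }
        elevs = surviving.get(lab)
        if elevs:
            a_lo, a_hi = min(elevs), max(elevs)
            entry["achieved_lo"] = a_lo
            entry["achieved_hi"] = a_hi
            entry["belts"] = list(range(grid.belt_index(a_lo), grid.belt_index(a_hi) + 1))
        else:
            entry["achieved_lo"] = entry["achieved_hi"] = None
            entry["belts"] = []
        truth_species[lab] = entry
    truth = {
        "mountain_id": config.mountain_id,
        "seed": config.seed,
        "scenario": config.scenario,
        "grid": {
            "min_elev": config.min_elev,
            "max_elev": config.max_elev,
            "belt_width_m": config.belt_width_m,
            "n_belts": grid.n_belts,
        },
        "n_base_records": n_base,
        "n_injected_duplicates": int(dup_mask.sum()),
        "species": truth_species,
    }
    df = pd.DataFrame(
        {
            "taxon": [lab for lab, _ in rows],
            "mountain": config.mountain_id,
            "elevation": [e for _, e in rows],
            "source": "synthetic",
        }
    )
    return df, truth


def simulate_belt_areas(
    grid: BeltGrid, shape: str = "hump", rng: np.random.Generator | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-belt area table (km^2); ``hump`` peaks in the middle third,
    ``monotone`` decreases strictly with elevation."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = grid.n_belts
    idx = np.arange(n)
    if shape == "hump":
        peak = int(rng.integers(n // 3, max(n // 3 + 1, 2 * n // 3)))
        scale = rng.uniform(0.8, 1.2)
        areas = scale * (20.0 + 80.0 * np.exp(-((idx - peak) ** 2) / (2 * (n / 5.0) ** 2)))
    elif shape == "monotone":
        a0 = rng.uniform(80.0, 120.0)
        q = rng.uniform(0.75, 0.92)
        areas = a0 * q**idx
    else:
        raise ValueError(f"unknown area shape {shape!r}")
    return pd.DataFrame(
        {
            "mountain_id": grid.mountain_id,
            "belt_lo": grid.lower_bounds,
            "area_km2": areas,
        }
    )


def assign_nonnatives(
    tree: dendropy.Tree,
    ranges: dict[str, tuple[float, float]],
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> tuple[set[str], dict[str, tuple[float, float]]]:
    """Pick a non-native subset and redraw its ranges.

    With ``nonnative_coupling`` -> 1 the non-native midpoints are drawn
    from belts in proportion to native belt richness (invaders follow the
    resource-rich, species-dense elevations); with coupling 0 they are
    uniform on the span. Returns the alien label set and the updated range
    map.
    """
    if config.nonnative_fraction >= 0.5:
        raise ValueError("nonnative_fraction must be < 0.5")
    rng = rng if rng is not None else np.random.default_rng(_child_seeds(config.seed, 5)[4])
    labels = sorted(ranges)
    k = int(round(config.nonnative_fraction * len(labels)))
    if k == 0:
        return set(), dict(ranges)
    aliens = set(rng.choice(labels, size=k, replace=False).tolist())

    grid = build_grid(config.mountain_id, config.min_elev, config.max_elev, config.belt_width_m)
    richness = np.zeros(grid.n_belts)
    for lab in labels:
        if lab in aliens:
            continue
        lo, hi = ranges[lab]
        richness[grid.belt_index(lo) : grid.belt_index(hi) + 1] += 1
    weights = richness / richness.sum() if richness.sum() > 0 else None

    new_ranges = dict(ranges)
    for lab in sorted(aliens):
        if weights is not None and rng.random() < config.nonnative_coupling:
            b = int(rng.choice(grid.n_belts, p=weights))
            b_lo, b_hi = grid.belts[b]
            mid = rng.uniform(b_lo, b_hi)
        else:
            mid = rng.uniform(config.min_elev, config.max_elev)
        width = _draw_width(rng, config.span, config)
        new_ranges[lab] = _clip_range(mid, width, config.min_elev, config.max_elev)
    return aliens, new_ranges


@dataclass
class SyntheticMountain:
    config: ScenarioConfig
    tree: dendropy.Tree
    ranges: dict[str, tuple[float, float]]
    occurrences: pd.DataFrame
    truth: dict
    areas: pd.DataFrame
    aliens: set[str]
    grid: BeltGrid


def simulate_mountain(config: ScenarioConfig) -> SyntheticMountain:
    """Generate one complete synthetic mountain from a single seed."""
    seeds = _child_seeds(config.seed, 5)
    tree = simulate_tree(config.n_species, seeds[0])
    ranges = simulate_ranges(tree, config, np.random.default_rng(seeds[1]))
    aliens, ranges = assign_nonnatives(tree, ranges, config, np.random.default_rng(seeds[4]))
    occ, truth = simulate_occurrences(ranges, config, np.random.default_rng(seeds[2]))
    grid = build_grid(config.mountain_id, config.min_elev, config.max_elev, config.belt_width_m)
    shape = "monotone" if config.scenario == "monotonic_decrease" else "hump"
    areas = simulate_belt_areas(grid, shape=shape, rng=np.random.default_rng(seeds[3]))
    truth["aliens"] = sorted(aliens)
    return SyntheticMountain(config, tree, ranges, occ, truth, areas, aliens, grid)


def write_mountain(sim: SyntheticMountain, out_dir: str | Path) -> dict[str, Path]:
    """Emit the exact file formats the ingest/belt/phylogeny stages consume.

    Returns a name -> path map: occurrences.csv, tree.nwk, areas.csv,
    aliens.txt, truth.json. Every file records the generating seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": out / "occurrences.csv",
        "tree": out / "tree.nwk",
        "areas": out / "areas.csv",
        "aliens": out / "aliens.txt",
        "truth": out / "truth.json",
    }
    with open(paths["occurrences"], "w", encoding="utf-8") as fh:
        fh.write(f"# seed={sim.config.seed} scenario={sim.config.scenario}\n")
        sim.occurrences.to_csv(fh, index=False)
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(f"[&seed={sim.config.seed}]\n")
        fh.write(sim.tree.as_string(schema="newick", suppress_rooting=True))
    with open(paths["areas"], "w", encoding="utf-8") as fh:
        fh.write(f"# seed={sim.config.seed}\n")
        sim.areas.to_csv(fh, index=False)
    with open(paths["aliens"], "w", encoding="utf-8") as fh:
        for lab in sorted(sim.aliens):
            fh.write(lab + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(sim.truth, fh, indent=1, sort_keys=True)
    return paths
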